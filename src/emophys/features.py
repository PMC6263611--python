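"""Per-segment feature catalog: 136 named columns across four channels.

ECG contributes 81 features built from 13 underlying series — eight
inter-event interval series (RR, PP, QQ, SS, TT and the within-beat PQ, QS,
ST), three wave-amplitude series (P, R, S), the HRV tachogram and the HRV
histogram distribution. GSR and EMG each contribute 21 features (raw signal,
first and second difference, seven statistics each). PPG contributes 13
(pulse-peak amplitudes, pulse-rate-variability intervals, spectral mean).
Feature names follow ``<SIGNAL>_<underlying>_<stat>``, e.g. ``ECG_RR_mean``.

HRV summary statistics include pNN50 (fraction of adjacent RR pairs
differing by more than 50 ms) and the triangular index (total interval count
over the mode height of the RR histogram at 7.8125 ms bins).

A ``FeatureTable`` is a pandas DataFrame indexed by segment id with the 136
feature columns plus an ``emotion`` label column. ``variance_filter`` drops
quasi-constant columns (variance below 0.8 x (1 - 0.8)) and returns the
boolean keep-mask so a held-out set can reuse the training mask.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .wavedet import FiducialSeries

logger = logging.getLogger(__name__)

STATS6 = ("mean", "median", "std", "min", "max", "range")
STATS7 = ("mean", "median", "std", "min", "max", "minRatio", "maxRatio")
ECG_INTERVAL_NAMES = ("RR", "PP", "QQ", "SS", "TT", "PQ", "QS", "ST")
VARIANCE_THRESHOLD = 0.8 * (1 - 0.8)

_ECG_COLUMNS = (
    [f"ECG_{s}_{st}" for s in ECG_INTERVAL_NAMES for st in STATS6]
    + [f"ECG_{w}amp_{st}" for w in ("P", "R", "S") for st in STATS6]
    + [f"ECG_HRV_{st}" for st in STATS6] + ["ECG_HRV_pNN50", "ECG_HRV_freqmean"]
    + [f"ECG_HRVdist_{st}" for st in STATS6] + ["ECG_HRVdist_Triind"]
)
_PPG_COLUMNS = (
    [f"PPG_Pamp_{st}" for st in STATS6]
    + [f"PPG_PRV_{st}" for st in STATS6] + ["PPG_PRV_freqmean"]
)


def feature_columns() -> list[str]:
    """The fixed 136-column catalog order: ECG, GSR, EMG, PPG."""
    cols = list(_ECG_COLUMNS)
    for sig in ("GSR", "EMG"):
        for underlying in ("Raw", "1Diff", "2Diff"):
            cols += [f"{sig}_{underlying}_{st}" for st in STATS7]
    cols += _PPG_COLUMNS
    return cols


def stats6(x) -> dict[str, float]:
    """Mean, median, sample std, min, max, range of a series (length >= 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("series must be non-empty")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": std,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "range": float(np.max(x) - np.min(x)),
    }


def stats7(x, band_fraction: float = 0.1) -> dict[str, float]:
    """Mean, median, std, min, max plus min/max occupancy ratios.

    ``minRatio`` is the fraction of samples within ``band_fraction`` of the
    range above the minimum (closed band); ``maxRatio`` symmetrically below
    the maximum. A constant series has both ratios equal to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    band = band_fraction * (hi - lo)
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": float(np.std(x, ddof=1)),
        "min": lo,
        "max": hi,
        "minRatio": float(np.mean(x <= lo + band)),
        "maxRatio": float(np.mean(x >= hi - band)),
    }


def intervals_from_fiducials(fiducials: FiducialSeries, fs: float) -> dict[str, np.ndarray]:
    """The eight ECG interval series in ms from beat-aligned fiducials.

    XX intervals are successive same-wave differences; PQ, QS and ST are
    within-beat differences.
    """
    if fiducials.kind != "ecg":
        raise ValueError("expected ECG fiducials")
    idx = fiducials.indices
    if idx["R"].size < 2:
        raise ValueError("need at least 2 beats")
    to_ms = 1000.0 / fs
    out: dict[str, np.ndarray] = {}
    for wave in ("R", "P", "Q", "S", "T"):
        out[wave * 2] = np.diff(idx[wave]) * to_ms
    out["PQ"] = (idx["Q"] - idx["P"]) * to_ms
    out["QS"] = (idx["S"] - idx["Q"]) * to_ms
    out["ST"] = (idx["T"] - idx["S"]) * to_ms
    return out


def pnn50(rr, threshold_ms: float = 50.0) -> float:
    """Fraction of adjacent interval pairs differing by strictly more than 50 ms."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.abs(np.diff(rr))
    return float(np.mean(diffs > threshold_ms))


def _rr_histogram(rr, bin_ms: float) -> np.ndarray:
    """Counts of intervals per bin on a discrete scale anchored at 0 ms."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("intervals must be positive")
    return np.bincount((rr // bin_ms).astype(int))


def triangular_index(rr, bin_ms: float = 7.8125) -> float:
    """Total interval count divided by the mode height of the RR histogram."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 1:
        raise ValueError("need at least 1 interval")
    counts = _rr_histogram(rr, bin_ms)
    return float(rr.size / counts.max())


def spectral_mean(intervals_ms, resample_hz: float = 4.0) -> float:
    """Mean magnitude spectrum of the mean-removed, resampled tachogram.

    The interval series is placed at its cumulative event times, linearly
    interpolated onto a uniform grid at ``resample_hz``, mean-removed, and
    the mean of the magnitude of its discrete Fourier transform returned.
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    t = np.cumsum(x) / 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if grid.size < 2:
        return 0.0
    resampled = np.interp(grid, t, x)
    resampled = resampled - resampled.mean()
    return float(np.mean(np.abs(np.fft.rfft(resampled))))


def hrv_features(rr, resample_hz: float = 4.0) -> dict[str, float]:
    """stats6 of the tachogram plus pNN50 and spectral mean (8 values)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 intervals")
    out = stats6(rr)
    out["pNN50"] = pnn50(rr)
    out["freqmean"] = spectral_mean(rr, resample_hz)
    return out


def hrv_distribution_features(rr, bin_ms: float = 7.8125) -> dict[str, float]:
    """stats6 over the nonzero RR-histogram bin counts plus Triind (7 values)."""
    counts = _rr_histogram(rr, bin_ms)
    nonzero = counts[counts > 0].astype(float)
    out = stats6(nonzero)
    out["Triind"] = triangular_index(rr, bin_ms)
    return out


def ecg_features(fiducials: FiducialSeries, fs: float) -> dict[str, float]:
    """The 81 ECG features from beat-aligned fiducials (13 underlying groups)."""
    intervals = intervals_from_fiducials(fiducials, fs)
    out: dict[str, float] = {}
    for name in ECG_INTERVAL_NAMES:
        for st, v in stats6(intervals[name]).items():
            out[f"ECG_{name}_{st}"] = v
    for wave in ("P", "R", "S"):
        for st, v in stats6(fiducials.amplitudes[wave]).items():
            out[f"ECG_{wave}amp_{st}"] = v
    rr = intervals["RR"]
    for st, v in hrv_features(rr).items():
        out[f"ECG_HRV_{st}"] = v
    for st, v in hrv_distribution_features(rr).items():
        out[f"ECG_HRVdist_{st}"] = v
    return out


def diff_stack_features(x, prefix: str) -> dict[str, float]:
    """stats7 of a waveform, its first and its second difference (21 values)."""
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    for underlying, series in (("Raw", x), ("1Diff", np.diff(x)), ("2Diff", np.diff(x, 2))):
        for st, v in stats7(series).items():
            out[f"{prefix}_{underlying}_{st}"] = v
    return out


def ppg_features(fiducials: FiducialSeries, fs: float) -> dict[str, float]:
    """The 13 PPG features: peak-amplitude stats, PRV stats, PRV spectral mean."""
    if fiducials.kind != "ppg":
        raise ValueError("expected PPG fiducials")
    peaks = fiducials.indices["peak"]
    if peaks.size < 4:
        raise ValueError("need at least 4 pulse peaks")
    prv = np.diff(peaks) * 1000.0 / fs
    out: dict[str, float] = {}
    for st, v in stats6(fiducials.amplitudes["peak"]).items():
        out[f"PPG_Pamp_{st}"] = v
    for st, v in stats6(prv).items():
        out[f"PPG_PRV_{st}"] = v
    out["PPG_PRV_freqmean"] = spectral_mean(prv)
    return out


def fuse(segment_features: dict[str, dict[str, float]],
         labels: dict[str, str]) -> pd.DataFrame:
    """Assemble per-segment feature maps into a FeatureTable.

    ``segment_features`` maps segment id to its 136-entry feature dict
    (ECG + GSR + EMG + PPG); rows with missing or non-finite entries are
    dropped with a logged reason. Columns are in fixed catalog order with an
    ``emotion`` label column appended.
    """
    cols = feature_columns()
    rows, index = [], []
    for seg_id, feats in segment_features.items():
        missing = [c for c in cols if c not in feats]
        if missing:
            raise ValueError(f"segment {seg_id}: missing features (all four "
                             f"channels required), e.g. {missing[:3]}")
        values = np.array([feats[c] for c in cols], dtype=float)
        if not np.all(np.isfinite(values)):
            logger.warning("segment %s dropped: non-finite feature values", seg_id)
            continue
        rows.append(values)
        index.append(seg_id)
    table = pd.DataFrame(rows, index=index, columns=cols)
    table.index.name = "segment_id"
    table["emotion"] = [labels[i] for i in index]
    return table


def variance_filter(table: pd.DataFrame,
                    threshold: float = VARIANCE_THRESHOLD) -> tuple[pd.DataFrame, pd.Series]:
    """Drop feature columns whose population variance is below ``threshold``.

    Returns the filtered table and the boolean keep-mask over feature
    columns; apply the mask (not a re-fit) to held-out data.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    feats = table.drop(columns=["emotion"], errors="ignore")
    variances = feats.var(ddof=0)
    mask = variances >= threshold
    kept = table[list(feats.columns[mask]) + (["emotion"] if "emotion" in table else [])]
    dropped = list(feats.columns[~mask])
    if dropped:
        logger.info("variance filter dropped %d columns: %s%s", len(dropped),
                    ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "")
    return kept, mask


def apply_mask(table: pd.DataFrame, mask: pd.Series) -> pd.DataFrame:
    """Apply a previously fitted variance-filter mask to another table."""
    cols = list(mask.index[mask])
    if "emotion" in table.columns:
        cols = cols + ["emotion"]
    return table[cols]
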