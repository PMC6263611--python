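"""Wavelet baseline-wander removal and characteristic-wave detection.

ECG R waves and PPG pulse peaks are located with the classic modulus-maxima
scheme: a sharp peak in the signal produces a pair of opposite-sign local
extrema in the undecimated wavelet detail at the matching dyadic scale, and
the peak time corresponds to the zero crossing of the detail between the
pair. QRS energy concentrates at dyadic scale 8 (detail level 3 at 200 Hz,
pass band roughly 12.5-25 Hz); the broader PPG pulse at scale 4.

Baseline wander is removed by subtracting the level-``n`` approximation of an
undecimated (a-trous) decomposition — i.e., the signal is rebuilt from its
detail content only. Defaults: db5 with 7 levels for ECG, sym8 with 5 levels
for PPG; at 200 Hz the level-7 approximation covers content below ~0.8 Hz.

The a-trous transform is computed directly (filters upsampled by zero
insertion, no decimation) so details are shift-equivariant and every level
has the input's length. Boundaries use reflection padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import fftconvolve

__all__ = [
    "FiducialSeries", "remove_baseline", "wavelet_detail",
    "detect_modulus_maxima_peaks", "detect_ecg_fiducials", "detect_ppg_peaks",
]

ECG_WAVES = ("P", "Q", "R", "S", "T")

# per-beat search windows relative to R, in seconds: (lo, hi, kind)
_ECG_WINDOWS = {
    "P": (-0.200, -0.060, "max"),
    "Q": (-0.060, 0.000, "min"),
    "S": (0.000, 0.060, "min"),
    "T": (0.080, 0.350, "max"),
}


@dataclass
class FiducialSeries:
    """Detected characteristic-wave locations for one channel segment.

    ``indices`` maps wave name (P/Q/R/S/T for ECG, "peak" for PPG) to sample
    indices; ``amplitudes`` to the signal values at those indices. For ECG
    the arrays are beat-aligned: entry ``i`` of every wave belongs to beat
    ``i``, and within a beat P < Q < R < S < T.
    """

    kind: str  # "ecg" | "ppg"
    indices: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    fs: float = 200.0
    usable: bool = True

    def __post_init__(self) -> None:
        for wave, idx in self.indices.items():
            idx = np.asarray(idx, dtype=int)
            self.indices[wave] = idx
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{wave} indices must be strictly increasing")

    def times(self, wave: str) -> np.ndarray:
        return self.indices[wave] / self.fs

    @property
    def n_beats(self) -> int:
        key = "R" if self.kind == "ecg" else "peak"
        return int(self.indices[key].size)


def _wavelet_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        w = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    # unit-sum low-pass so the approximation has DC gain 1 at every level
    lo = np.asarray(w.dec_lo, dtype=float)
    hi = np.asarray(w.dec_hi, dtype=float)
    return lo / lo.sum(), hi / np.sqrt(2.0)


def _upsample(h: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return h
    out = np.zeros((len(h) - 1) * factor + 1)
    out[::factor] = h
    return out


@lru_cache(maxsize=32)
def _combined_kernels(wavelet_name: str, n_levels: int):
    """Equivalent single-stage filters of the a-trous cascade.

    Returns ``(approx_kernel, [detail kernel for level 1..n])`` where the
    detail kernel for level j is ``lo_1 * ... * lo_{j-1} * hi_j`` (filters
    upsampled by zero insertion, ``*`` denoting convolution) and the approx
    kernel is ``lo_1 * ... * lo_n``.
    """
    lo, hi = _wavelet_filters(wavelet_name)
    combined_lo = np.array([1.0])
    detail_kernels = []
    for level in range(1, n_levels + 1):
        up = 2 ** (level - 1)
        detail_kernels.append(np.convolve(combined_lo, _upsample(hi, up)))
        combined_lo = np.convolve(combined_lo, _upsample(lo, up))
    return combined_lo, detail_kernels


def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Anti-symmetric (odd) reflection padding.

    Odd reflection about each endpoint keeps both the value and the slope
    continuous, so the extension introduces no kink for the band-pass
    kernels to react to (plain even reflection leaves a derivative
    discontinuity that shows up as a spurious detail extremum at segment
    boundaries). Falls back to even-reflection tiling when the pad exceeds
    the signal length.
    """
    n = x.size
    if pad < n:
        left = 2 * x[0] - x[pad:0:-1]
        right = 2 * x[-1] - x[-2:-pad - 2:-1]
        return np.concatenate([left, x, right])
    reps = -(-pad // n)  # ceil
    left_tiles = [x[::-1] if i % 2 == 1 else x for i in range(reps, 0, -1)]
    right_tiles = [x[::-1] if i % 2 == 1 else x for i in range(1, reps + 1)]
    ext = np.concatenate(left_tiles + [x] + right_tiles)
    return ext[reps * n - pad: reps * n + n + pad]


def _apply_kernel(x: np.ndarray, h: np.ndarray, centroid: int) -> np.ndarray:
    """Convolve with h, aligned so tap ``centroid`` sits at zero lag.

    Asymmetric wavelet filters (db, sym families) accumulate a large group
    delay through the cascade; anchoring the kernel at its centroid keeps
    details and the baseline estimate time-aligned with the input.
    """
    n = x.size
    pad = h.size
    xp = _reflect_pad(x, pad)
    return fftconvolve(xp, h)[pad + centroid: pad + centroid + n]


def _lowpass_centroid(h: np.ndarray) -> int:
    return int(round(np.sum(np.arange(h.size) * h) / np.sum(h)))


def _bandpass_centroid(h: np.ndarray) -> int:
    e = h * h
    return int(round(np.sum(np.arange(h.size) * e) / np.sum(e)))


def _atrous(x: np.ndarray, wavelet_name: str, n_levels: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Undecimated decomposition; returns (approximation, [detail level 1..n])."""
    x = np.asarray(x, dtype=float)
    lo_kernel, detail_kernels = _combined_kernels(wavelet_name, n_levels)
    approx = _apply_kernel(x, lo_kernel, _lowpass_centroid(lo_kernel))
    details = [_apply_kernel(x, h, _bandpass_centroid(h)) for h in detail_kernels]
    return approx, details


def remove_baseline(x: np.ndarray, wavelet_name: str = "db5", n_levels: int = 7) -> np.ndarray:
    """Subtract the level-``n_levels`` approximation (the baseline estimate).

    Equivalent to reconstructing the signal from its detail content only;
    output has the input's length.
    """
    x = np.asarray(x, dtype=float)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    lo_kernel, _ = _combined_kernels(wavelet_name, n_levels)
    approx = _apply_kernel(x, lo_kernel, _lowpass_centroid(lo_kernel))
    return x - approx


def wavelet_detail(x: np.ndarray, wavelet_name: str, dyadic_scale: int) -> np.ndarray:
    """Undecimated detail coefficients at scale ``2^j`` (same length as x).

    Shift-equivariant away from the boundaries: the detail of a time-shifted
    signal is the shifted detail.
    """
    x = np.asarray(x, dtype=float)
    if dyadic_scale not in (2, 4, 8, 16):
        raise ValueError("dyadic_scale must be one of {2, 4, 8, 16}")
    level = int(np.log2(dyadic_scale))
    _, detail_kernels = _combined_kernels(wavelet_name, level)
    h = detail_kernels[-1]
    return _apply_kernel(x, h, _bandpass_centroid(h))


def _local_extrema(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of d."""
    interior = np.arange(1, d.size - 1)
    left, mid, right = d[:-2], d[1:-1], d[2:]
    maxima = interior[(mid > left) & (mid >= right)]
    minima = interior[(mid < left) & (mid <= right)]
    return maxima, minima


def detect_modulus_maxima_peaks(x: np.ndarray, wavelet_name: str = "db5",
                                dyadic_scale: int = 8, thresh_k: float = 2.0,
                                pair_window_s: float = 0.12,
                                refractory_s: float = 0.2, fs: float = 200.0,
                                refine_window_s: float = 0.05,
                                refine_polarity: str = "max") -> np.ndarray:
    """Locate sharp peaks via opposite-sign modulus-maxima pairs.

    The detail at the given dyadic scale is computed; local extrema whose
    magnitude exceeds ``thresh_k x RMS(detail)`` are paired (opposite signs,
    within ``pair_window_s`` of each other); each pair's peak candidate is
    the zero crossing of the detail between the pair, refined to the local
    extremum of the signal within ``refine_window_s`` (absorbs the residual
    phase of asymmetric wavelet filters). ``refine_polarity`` selects the
    extremum: "max" for positive-going peaks (R waves, pulse apices), "min",
    or "absmax". Candidates within ``refractory_s`` of an accepted peak are
    rejected. Returns sorted unique sample indices.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    d = wavelet_detail(x, wavelet_name, dyadic_scale)
    rms = float(np.sqrt(np.mean(d * d)))
    if rms == 0.0:
        return np.array([], dtype=int)
    thresh = thresh_k * rms
    maxima, minima = _local_extrema(d)
    maxima = maxima[d[maxima] > thresh]
    minima = minima[d[minima] < -thresh]
    if maxima.size == 0 or minima.size == 0:
        return np.array([], dtype=int)
    extrema = np.sort(np.concatenate([maxima, minima]))
    signs = np.sign(d[extrema])
    pair_window = int(round(pair_window_s * fs))
    refine = int(round(refine_window_s * fs))
    candidates = []
    for a, b, sa, sb in zip(extrema[:-1], extrema[1:], signs[:-1], signs[1:]):
        if sa * sb >= 0 or (b - a) > pair_window:
            continue
        seg = d[a:b + 1]
        crossings = np.nonzero(np.diff(np.sign(seg)) != 0)[0]
        if crossings.size == 0:
            continue
        zc = a + int(crossings[0]) + 1
        lo, hi = max(0, zc - refine), min(x.size, zc + refine + 1)
        win = x[lo:hi]
        if refine_polarity == "max":
            peak = lo + int(np.argmax(win))
        elif refine_polarity == "min":
            peak = lo + int(np.argmin(win))
        elif refine_polarity == "absmax":
            peak = lo + int(np.argmax(np.abs(win)))
        else:
            raise ValueError("refine_polarity must be 'max', 'min' or 'absmax'")
        candidates.append(peak)
    refractory = int(round(refractory_s * fs))
    accepted: list[int] = []
    for c in sorted(set(candidates)):
        if not accepted or c - accepted[-1] > refractory:
            accepted.append(c)
    return np.asarray(accepted, dtype=int)


def detect_ecg_fiducials(ecg_segment: np.ndarray, fs: float = 200.0,
                         wavelet_name: str = "db5", dyadic_scale: int = 8,
                         thresh_k: float = 2.0, pair_window_s: float = 0.12,
                         refractory_s: float = 0.2) -> FiducialSeries:
    """Detect P, Q, R, S, T per beat on a baseline-removed ECG segment.

    R waves come from the modulus-maxima detector; the remaining waves are
    located as local extrema of the signal inside fixed per-beat windows
    (P: max in [R-200, R-60] ms; Q: min in [R-60, R) ms; S: min in
    (R, R+60] ms; T: max in (R+80, R+350] ms). Beats whose windows fall
    outside the segment are dropped so all five index arrays stay
    beat-aligned. Segments with fewer than two detected R waves are returned
    with ``usable=False``.
    """
    x = np.asarray(ecg_segment, dtype=float)
    r_idx = detect_modulus_maxima_peaks(x, wavelet_name, dyadic_scale, thresh_k,
                                        pair_window_s, refractory_s, fs)
    indices: dict[str, list[int]] = {w: [] for w in ECG_WAVES}
    for r in r_idx:
        beat: dict[str, int] = {"R": int(r)}
        ok = True
        for wave, (lo_s, hi_s, kind) in _ECG_WINDOWS.items():
            lo = r + int(round(lo_s * fs))
            hi = r + int(round(hi_s * fs))
            if lo < 0 or hi >= x.size or hi <= lo:
                ok = False
                break
            win = x[lo:hi + 1]
            off = int(np.argmax(win) if kind == "max" else np.argmin(win))
            beat[wave] = lo + off
        if ok and beat["P"] < beat["Q"] < beat["R"] < beat["S"] < beat["T"]:
            for wave in ECG_WAVES:
                indices[wave].append(beat[wave])
    arrays = {w: np.asarray(v, dtype=int) for w, v in indices.items()}
    usable = arrays["R"].size >= 2
    amplitudes = {w: x[idx] if idx.size else np.array([]) for w, idx in arrays.items()}
    return FiducialSeries(kind="ecg", indices=arrays, amplitudes=amplitudes,
                          fs=fs, usable=usable)


def detect_ppg_peaks(ppg_segment: np.ndarray, fs: float = 200.0,
                     wavelet_name: str = "sym8", dyadic_scale: int = 4,
                     thresh_k: float = 2.0, pair_window_s: float = 0.25,
                     refractory_s: float = 0.3) -> FiducialSeries:
    """Detect pulse peaks on a baseline-removed PPG segment (sym8, scale 4)."""
    x = np.asarray(ppg_segment, dtype=float)
    idx = detect_modulus_maxima_peaks(x, wavelet_name, dyadic_scale, thresh_k,
                                      pair_window_s, refractory_s, fs,
                                      refine_window_s=0.08)
    usable = idx.size >= 2
    return FiducialSeries(kind="ppg", indices={"peak": idx},
                          amplitudes={"peak": x[idx] if idx.size else np.array([])},
                          fs=fs, usable=usable)
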