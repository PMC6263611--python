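"""Preprocessing: LMS interference cancellation, segmentation, smoothing.

The cleaning chain mirrors a standard multichannel biosignal workflow: an
adaptive FIR filter cancels cross-channel interference (least-mean-squares
weight updates), records are cut into fixed-length labelled segments, and the
slow channels (GSR, EMG envelope) are smoothed with zero-phase Butterworth
low-pass filters; a centred moving average is available for light smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthgen import EMOTIONS, SignalRecord

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """One fixed-length labelled window of a multichannel record."""

    fs: float
    channels: dict[str, np.ndarray]
    emotion: str
    record_id: str
    start_s: float
    length_s: float = 20.0
    segment_id: str = ""

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        want = int(round(self.length_s * self.fs))
        for ch, x in self.channels.items():
            if len(x) != want:
                raise ValueError(f"channel {ch!r} has {len(x)} samples, expected {want}")
        if not self.segment_id:
            self.segment_id = f"{self.record_id}_{self.start_s:08.1f}"


def lms_adaptive_filter(target: np.ndarray, reference: np.ndarray,
                        n_taps: int = 5, mu: float = 1e-6) -> np.ndarray:
    """Cancel the component of ``target`` correlated with ``reference``.

    A length-``n_taps`` FIR filter estimates the interference from the
    reference channel; its weights are updated per sample by the LMS rule
    ``w <- w + mu * e[n] * x[n]``. Returns the error signal ``target - y``,
    which is the cleaned target. The first ``n_taps - 1`` outputs use a
    zero-padded reference history. ``mu`` must be small relative to the
    reference power for stability (default 1e-6 matches tap count 5).
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape or target.ndim != 1:
        raise ValueError("target and reference must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(target)) and np.all(np.isfinite(reference))):
        raise ValueError("inputs must be finite")
    if n_taps < 1:
        raise ValueError("n_taps must be >= 1")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    n = target.size
    w = np.zeros(n_taps)
    out = np.empty(n)
    padded = np.concatenate([np.zeros(n_taps - 1), reference])
    for i in range(n):
        x = padded[i:i + n_taps][::-1]  # x[n], x[n-1], ..., x[n-n_taps+1]
        e = target[i] - w @ x
        out[i] = e
        w += mu * e * x
    return out


def segment_record(record: SignalRecord, length_s: float = 20.0) -> list[Segment]:
    """Cut a record into non-overlapping labelled windows.

    Windows are placed fully inside a single label interval; partial trailing
    windows are discarded. Each segment inherits its interval's emotion.
    """
    if not record.label_intervals:
        raise ValueError("record has no label intervals")
    if record.duration_s < length_s:
        raise ValueError(f"record duration {record.duration_s:.1f}s shorter than "
                         f"segment length {length_s}s")
    n_win = int(round(length_s * record.fs))
    segments: list[Segment] = []
    for start, end, emotion in record.label_intervals:
        t = start
        while t + length_s <= end + 1e-9:
            i0 = int(round(t * record.fs))
            segments.append(Segment(
                fs=record.fs,
                channels={ch: x[i0:i0 + n_win].copy() for ch, x in record.channels.items()},
                emotion=emotion,
                record_id=record.record_id,
                start_s=t,
                length_s=length_s,
            ))
            t += length_s
        if t < end - 1e-9:
            logger.info("record %s: discarding %.1fs partial window in interval (%s, %s)",
                        record.record_id, end - t, start, end)
    if not segments:
        logger.warning("record %s produced no segments at length %.1fs",
                       record.record_id, length_s)
    return segments


def butterworth_lowpass(x: np.ndarray, cutoff_hz: float, fs: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter; DC gain 1."""
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff_hz must lie in (0, fs/2) = (0, {fs / 2})")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def moving_average(x: np.ndarray, window_samples: int = 5) -> np.ndarray:
    """Centred moving average with reflected edges; window 1 is the identity."""
    x = np.asarray(x, dtype=float)
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window_samples must be an odd integer >= 1")
    if window_samples == 1:
        return x.copy()
    half = window_samples // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.full(window_samples, 1.0 / window_samples)
    return np.convolve(padded, kernel, mode="valid")


def preprocess_record(record: SignalRecord, n_taps: int = 5, mu: float = 1e-6,
                      lms_pairs: tuple[tuple[str, str], ...] = (("ecg", "emg"),),
                      emg_cutoff_hz: float = 0.4, gsr_cutoff_hz: float = 0.3,
                      ppg_cutoff_hz: float = 15.0,
                      smooth_window: int = 5) -> SignalRecord:
    """Apply the default cleaning chain to a whole record.

    LMS cancellation runs on each (target, reference) channel pair (default:
    EMG is the interference reference for ECG); the EMG channel is rectified
    and low-passed at 0.4 Hz (a 0.4 Hz low-pass on the raw zero-mean EMG
    would null the channel, so the filter acts on the activity envelope);
    GSR is low-passed at 0.3 Hz; ECG and PPG get a light moving-average
    smoothing.
    """
    channels = {ch: np.asarray(x, dtype=float).copy() for ch, x in record.channels.items()}
    for tgt, ref in lms_pairs:
        channels[tgt] = lms_adaptive_filter(channels[tgt], record.channels[ref],
                                            n_taps=n_taps, mu=mu)
    channels["ecg"] = moving_average(channels["ecg"], smooth_window)
    # pulse band ends well below 15 Hz; a zero-phase low-pass there removes
    # broadband noise without distorting the systolic apex
    channels["ppg"] = butterworth_lowpass(channels["ppg"], ppg_cutoff_hz, record.fs)
    channels["emg"] = butterworth_lowpass(np.abs(channels["emg"]),
                                          emg_cutoff_hz, record.fs)
    channels["gsr"] = butterworth_lowpass(channels["gsr"], gsr_cutoff_hz, record.fs)
    return SignalRecord(fs=record.fs, channels=channels,
                        label_intervals=list(record.label_intervals),
                        truth=dict(record.truth), seed=record.seed,
                        record_id=record.record_id)
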