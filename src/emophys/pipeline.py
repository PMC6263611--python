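"""End-to-end glue: records -> segments -> fiducials -> FeatureTable.

Chains the per-module operations with their defaults: LMS interference
cancellation and channel smoothing, 20 s segmentation, wavelet baseline
removal (db5/7 for ECG, sym8/5 for PPG), modulus-maxima fiducial detection
and the 136-column feature catalog.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import features as feat
from . import preprocess as prep
from . import wavedet
from .synthgen import SignalRecord

logger = logging.getLogger(__name__)


def segment_features(segment: prep.Segment) -> dict[str, float] | None:
    """The 136 features of one preprocessed segment, or None if unusable."""
    ecg = wavedet.remove_baseline(segment.channels["ecg"], "db5", 7)
    ppg = wavedet.remove_baseline(segment.channels["ppg"], "sym8", 5)
    ecg_fid = wavedet.detect_ecg_fiducials(ecg, segment.fs)
    ppg_fid = wavedet.detect_ppg_peaks(ppg, segment.fs)
    if not ecg_fid.usable or ecg_fid.n_beats < 4:
        logger.warning("segment %s dropped: too few ECG beats (%d)",
                       segment.segment_id, ecg_fid.n_beats)
        return None
    if not ppg_fid.usable or ppg_fid.n_beats < 4:
        logger.warning("segment %s dropped: too few PPG pulses (%d)",
                       segment.segment_id, ppg_fid.n_beats)
        return None
    out = feat.ecg_features(ecg_fid, segment.fs)
    out.update(feat.diff_stack_features(segment.channels["gsr"], "GSR"))
    out.update(feat.diff_stack_features(segment.channels["emg"], "EMG"))
    out.update(feat.ppg_features(ppg_fid, segment.fs))
    return out


def records_to_segments(records: list[SignalRecord],
                        length_s: float = 20.0,
                        preprocess: bool = True) -> list[prep.Segment]:
    """Preprocess and segment a list of records."""
    segments: list[prep.Segment] = []
    for record in records:
        cleaned = prep.preprocess_record(record) if preprocess else record
        segments.extend(prep.segment_record(cleaned, length_s))
    return segments


def extract_features(segments: list[prep.Segment]) -> pd.DataFrame:
    """Fuse per-segment features into a FeatureTable (dropped rows logged)."""
    maps: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for seg in segments:
        values = segment_features(seg)
        if values is None:
            continue
        maps[seg.segment_id] = values
        labels[seg.segment_id] = seg.emotion
    return feat.fuse(maps, labels)


def records_to_features(records: list[SignalRecord],
                        length_s: float = 20.0) -> pd.DataFrame:
    return extract_features(records_to_segments(records, length_s))
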