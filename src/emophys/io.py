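"""File formats: signal CSVs with JSON sidecars, feature CSVs, model JSON.

A SignalRecord is stored as ``<name>.csv`` (columns ``time_s, ecg, gsr, emg,
ppg``) plus ``<name>.json`` holding sampling rate, seed, label intervals and
ground-truth fiducial times. FeatureTables are plain CSVs with a header row,
indexed by segment id. Fitted models serialise to JSON with a ``kind`` tag.
Column dictionaries live in docs/FORMATS.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gbdt import GBDTModel
from .kpca import KPCAModel
from .synthgen import SignalRecord

CHANNELS = ("ecg", "gsr", "emg", "ppg")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal_csv(record: SignalRecord, path: str | Path) -> None:
    path = Path(path)
    n = record.n_samples
    frame = pd.DataFrame({"time_s": np.arange(n) / record.fs})
    for ch in CHANNELS:
        frame[ch] = record.channels[ch]
    frame.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "fs": record.fs,
        "seed": record.seed,
        "record_id": record.record_id,
        "label_intervals": [[s, e, emo] for s, e, emo in record.label_intervals],
        "truth": {ch: np.asarray(t).tolist() for ch, t in record.truth.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_signal_csv(path: str | Path) -> SignalRecord:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt metadata JSON in {sidecar}: {exc}") from exc
    frame = pd.read_csv(path)
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    return SignalRecord(
        fs=float(meta["fs"]),
        channels={ch: frame[ch].to_numpy(dtype=float) for ch in CHANNELS},
        label_intervals=[(float(s), float(e), emo)
                         for s, e, emo in meta.get("label_intervals", [])],
        truth={ch: np.asarray(t, dtype=float)
               for ch, t in meta.get("truth", {}).items()},
        seed=int(meta.get("seed", 0)),
        record_id=str(meta.get("record_id", path.stem)),
    )


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=True)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col=0)


def write_model(model: KPCAModel | GBDTModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def read_model(path: str | Path) -> KPCAModel | GBDTModel:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model JSON in {path}: {exc}") from exc
    kind = d.get("kind")
    if kind == "kpca":
        return KPCAModel.from_dict(d)
    if kind == "gbdt":
        return GBDTModel.from_dict(d)
    raise ValueError(f"{path}: unknown model kind {kind!r}")


def read_config(path: str | Path) -> dict:
    """YAML or JSON configuration file as a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
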