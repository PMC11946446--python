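"""CSV readers/writers for recordings and feature tables.

Recordings use an EmotivPRO-like dialect: one row per sample, a ``Timestamp``
column (seconds from recording start) followed by one ``EEG.<channel>``
column per electrode, in microvolts.  Each recording carries a JSON sidecar
(``<stem>.meta.json``) with subject, LED condition, trajectory, repetition
and seed.  Feature tables are plain CSV with ``feature_0001..`` columns plus
labels, and a JSON sidecar mapping feature ids to (channel, band, statistic).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS
from .features import feature_index_map
from .simulate import Recording, RecordingMeta

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_feature_table",
    "read_feature_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Write one recording plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    n = recording.n_samples
    df = pd.DataFrame(
        recording.samples,
        columns=[f"EEG.{c}" for c in recording.channel_names],
    )
    df.insert(0, "Timestamp", np.arange(n) / recording.sampling_rate_hz)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "subject_id": recording.meta.subject_id,
        "led_on": recording.meta.led_on,
        "trajectory": recording.meta.trajectory,
        "repetition": recording.meta.repetition,
        "seed": recording.meta.seed,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_names": list(recording.channel_names),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording_csv(path: str | Path, sampling_rate_hz: float | None = None) -> Recording:
    """Read a recording CSV (and its sidecar when present).

    Raises a parse error naming the first offending row for non-numeric
    cells, and a clear error for missing channel columns.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar(path)
    meta_raw: dict = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    channel_names = tuple(meta_raw.get("channel_names", CHANNELS))

    cols = [f"EEG.{c}" for c in channel_names]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing channel columns {missing}")
    block = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path.name}: non-numeric sample value at data row {row}")

    fs = sampling_rate_hz or meta_raw.get("sampling_rate_hz")
    if fs is None:
        ts = pd.to_numeric(df["Timestamp"], errors="coerce")
        fs = float(round(1.0 / np.median(np.diff(ts))))
    meta = RecordingMeta(
        subject_id=int(meta_raw.get("subject_id", 0)),
        led_on=bool(meta_raw.get("led_on", False)),
        trajectory=str(meta_raw.get("trajectory", "unknown")),
        repetition=int(meta_raw.get("repetition", 0)),
        seed=meta_raw.get("seed"),
    )
    return Recording(block.to_numpy(dtype=float), float(fs), channel_names, meta)


def write_feature_table(df: pd.DataFrame, path: str | Path,
                        channels: tuple[str, ...] | None = None) -> Path:
    """Write a feature table CSV with a JSON id-map sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    if channels is not None:
        idmap = {str(k): v for k, v in feature_index_map(channels).items()}
        _sidecar(path).write_text(json.dumps(idmap, indent=2))
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
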