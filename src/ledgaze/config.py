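"""Run configuration: one structured document governs an end-to-end run.

Defaults equal the acquisition/processing settings the pipeline is built
around: 256 Hz sampling, fifth-order Butterworth filters (1-15 Hz causal for
the gate, 1-45 Hz zero-phase for trajectories), Welch window 637 with
overlap 636, 75/25 holdout repeated 10 times, and a 3 s selection time for
ITR.  The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    out_dir: str = "ledgaze_run"
    seed: int = 0

    # cohort
    n_subjects: int = 10
    reps_per_class: int = 10
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    # preprocessing / spectra
    sampling_rate_hz: float = 256.0
    beep_pad_s: float = 3.0
    filter_stage1: dict = field(
        default_factory=lambda: {"low_hz": 1.0, "high_hz": 15.0, "order": 5, "mode": "causal"}
    )
    filter_stage2: dict = field(
        default_factory=lambda: {"low_hz": 1.0, "high_hz": 45.0, "order": 5, "mode": "zero_phase"}
    )
    welch_window_len: int = 637
    welch_noverlap: int = 636

    # evaluation
    gate_classifier: str = "rf"
    stage2_classifier: str = "rf"
    feature_set: str = "consensus16"  # or "all160"
    split: float = 0.75
    repeats: int = 10
    selection_time_s: float = 3.0

    def __post_init__(self) -> None:
        if self.feature_set not in ("consensus16", "all160"):
            raise ValueError("feature_set must be 'consensus16' or 'all160'")
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
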