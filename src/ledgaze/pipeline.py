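"""End-to-end orchestration: simulate -> preprocess -> featurize -> cascade.

The control flow mirrors the deployed system: every 3 s segment first meets
the LED gate on the causally filtered 1-15 Hz path; segments the gate
declares non-illuminated produce no trajectory output (the system does not
activate), and gate-passed segments flow to the zero-phase 1-45 Hz
trajectory path.  Stage boundaries are logged with segment counts so the
cascade's test-set filtering is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .channels import ACTIVE_CHANNELS
from .config import RunConfig
from .features import WelchConfig, feature_vector
from .gate import stage1_features
from .preprocess import (
    STAGE1_FILTER,
    STAGE2_FILTER,
    FilterSpec,
    Segment,
    bandpass,
    segment_recording,
    trim_beeps,
)
from .simulate import Recording, SimulationConfig, iter_cohort
from .trajectory import CONSENSUS_FEATURE_IDS, CascadeResult, run_cascade

log = logging.getLogger("ledgaze")

__all__ = [
    "recording_segments",
    "featurize_stage1",
    "featurize_bank",
    "evaluate_cohort",
    "cohort_table",
    "run_pipeline",
]


def recording_segments(recording: Recording, pad_s: float = 3.0) -> list[Segment]:
    """Trim beep pads and cut the task block into analysis windows."""
    return segment_recording(trim_beeps(recording, pad_s))


def _label_row(seg: Segment) -> dict:
    return dict(
        subject=seg.meta.subject_id,
        led_on=seg.meta.led_on,
        trajectory=seg.meta.trajectory,
        repetition=seg.meta.repetition,
        window_index=seg.window_index,
    )


def featurize_stage1(
    recordings: Iterable[Recording],
    active_channels: tuple[str, ...] = ACTIVE_CHANNELS,
    welch: WelchConfig | None = None,
    filter_spec: FilterSpec = STAGE1_FILTER,
    pad_s: float = 3.0,
) -> pd.DataFrame:
    """Gate feature table: one z' ratio per active channel per segment."""
    frames = []
    cfg = welch or WelchConfig()
    for rec in recordings:
        segs = [bandpass(s, filter_spec) for s in recording_segments(rec, pad_s)]
        frames.append(stage1_features(segs, active_channels, cfg, prefiltered=True))
    df = pd.concat(frames, ignore_index=True)
    log.info("stage-1 featurization: %d segments, %d channels", len(df), len(active_channels))
    return df


def featurize_bank(
    recordings: Iterable[Recording],
    channels: tuple[str, ...] = ACTIVE_CHANNELS,
    welch: WelchConfig | None = None,
    filter_spec: FilterSpec = STAGE2_FILTER,
    pad_s: float = 3.0,
) -> pd.DataFrame:
    """Full feature-bank table (40 features per channel) per segment."""
    cfg = welch or WelchConfig()
    rows = []
    labels = []
    for rec in recordings:
        for seg in recording_segments(rec, pad_s):
            fseg = bandpass(seg, filter_spec)
            rows.append(feature_vector(fseg, channels, cfg))
            labels.append(_label_row(seg))
    feats = pd.DataFrame(
        np.vstack(rows),
        columns=[f"feature_{i:04d}" for i in range(1, 40 * len(channels) + 1)],
    )
    out = pd.concat([feats, pd.DataFrame(labels)], axis=1)
    log.info("feature bank: %d segments x %d features", len(out), 40 * len(channels))
    return out


def _feature_ids(feature_set: str) -> tuple[int, ...] | None:
    if feature_set == "consensus16":
        return CONSENSUS_FEATURE_IDS
    if feature_set == "all160":
        return None
    raise ValueError(f"unknown feature set {feature_set!r}")


def evaluate_cohort(
    stage1_df: pd.DataFrame,
    stage2_df: pd.DataFrame,
    *,
    gate_classifier: str = "rf",
    stage2_classifier: str = "rf",
    feature_set: str = "consensus16",
    split: float = 0.75,
    repeats: int = 10,
    seed: int = 0,
    selection_time_s: float = 3.0,
) -> dict[int, CascadeResult]:
    """Per-subject cascade evaluation from aligned stage-1/stage-2 tables.

    The two tables must describe the same segments in the same order (the
    featurizers guarantee this when fed the same recordings).
    """
    key_cols = ["subject", "led_on", "trajectory", "repetition", "window_index"]
    if not stage1_df[key_cols].equals(stage2_df[key_cols]):
        raise ValueError("stage-1 and stage-2 tables describe different segments")
    z_cols = [c for c in stage1_df.columns if c.startswith("zratio_")]
    f_cols = [c for c in stage2_df.columns if c.startswith("feature_")]
    results: dict[int, CascadeResult] = {}
    for subject, idx in stage1_df.groupby("subject").groups.items():
        s1 = stage1_df.loc[idx]
        s2 = stage2_df.loc[idx]
        results[int(subject)] = run_cascade(
            s1[z_cols].to_numpy(float),
            s2[f_cols].to_numpy(float),
            s1["led_on"].to_numpy(bool),
            s1["trajectory"].to_numpy(),
            gate_classifier=gate_classifier,
            stage2_classifier=stage2_classifier,
            feature_ids=_feature_ids(feature_set),
            split=split,
            repeats=repeats,
            seed=seed,
            selection_time_s=selection_time_s,
        )
        log.info(
            "subject %s: gate %.4f, stage-2 %.4f, overall %.4f",
            subject,
            results[int(subject)].stage1_overall,
            results[int(subject)].stage2_overall,
            results[int(subject)].overall_system,
        )
    return results


def cohort_table(results: dict[int, CascadeResult]) -> pd.DataFrame:
    """Per-subject rows plus an averaged row, mirroring the report layout."""
    rows = []
    for subject, res in sorted(results.items()):
        rows.append(
            {
                "subject": str(subject),
                "stage1_accuracy": res.stage1_overall,
                "stage2_accuracy": res.stage2_overall,
                "overall_accuracy": res.overall_system,
                "itr_bits_per_min": res.itr_bits_per_min,
            }
        )
    df = pd.DataFrame(rows)
    avg = df.drop(columns="subject").mean()
    avg["subject"] = "average"
    return pd.concat([df, avg.to_frame().T], ignore_index=True)[df.columns]


def fit_cascade_models(
    stage1_df: pd.DataFrame,
    stage2_df: pd.DataFrame,
    *,
    gate_classifier: str = "rf",
    stage2_classifier: str = "rf",
    feature_set: str = "consensus16",
    seed: int = 0,
):
    """Fit the gate and trajectory models on full labelled tables."""
    from .gate import make_classifier

    z_cols = [c for c in stage1_df.columns if c.startswith("zratio_")]
    f_cols = [c for c in stage2_df.columns if c.startswith("feature_")]
    ids = _feature_ids(feature_set)
    cols = np.asarray(ids, dtype=int) - 1 if ids is not None else np.arange(len(f_cols))
    gate = make_classifier(gate_classifier, seed=seed, n_train=len(stage1_df))
    gate.fit(stage1_df[z_cols].to_numpy(float), stage1_df["led_on"].to_numpy(bool))
    on = stage2_df["led_on"].to_numpy(bool)
    clf = make_classifier(stage2_classifier, seed=seed, n_train=int(on.sum()))
    clf.fit(
        stage2_df.loc[on, f_cols].to_numpy(float)[:, cols],
        stage2_df.loc[on, "trajectory"].to_numpy(),
    )
    return gate, clf, cols


def predict_cohort(
    stage1_df: pd.DataFrame,
    stage2_df: pd.DataFrame,
    gate_model,
    stage2_model,
    feature_cols: np.ndarray,
) -> pd.DataFrame:
    """Apply the trained cascade: gate first, trajectory only when it fires.

    Segments the gate declares non-illuminated get no trajectory prediction
    (the system does not activate for them).
    """
    z_cols = [c for c in stage1_df.columns if c.startswith("zratio_")]
    f_cols = [c for c in stage2_df.columns if c.startswith("feature_")]
    gate_pred = gate_model.predict(stage1_df[z_cols].to_numpy(float)).astype(bool)
    traj_pred = np.full(len(stage1_df), None, dtype=object)
    if gate_pred.any():
        traj_pred[gate_pred] = stage2_model.predict(
            stage2_df.loc[gate_pred, f_cols].to_numpy(float)[:, feature_cols]
        )
    out = stage1_df[["subject", "led_on", "trajectory", "repetition", "window_index"]].copy()
    out["gate_predicted_on"] = gate_pred
    out["trajectory_predicted"] = traj_pred
    log.info(
        "cascade applied: %d segments in = %d gate-passed + %d gate-rejected",
        len(out), int(gate_pred.sum()), int((~gate_pred).sum()),
    )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full cascade on a freshly simulated cohort.

    Writes feature tables and a JSON report under ``config.out_dir`` and
    returns the report dict.  Deterministic under a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(**config.simulation) if config.simulation else SimulationConfig()
    welch = WelchConfig(
        window_len=config.welch_window_len,
        noverlap=config.welch_noverlap,
        fs=config.sampling_rate_hz,
    )
    f1 = FilterSpec(**config.filter_stage1)
    f2 = FilterSpec(**config.filter_stage2)

    log.info(
        "simulating cohort: %d subjects x %d reps/class", config.n_subjects, config.reps_per_class
    )
    recs = list(
        iter_cohort(config.n_subjects, config.reps_per_class, sim, seed=config.seed)
    )
    stage1_df = featurize_stage1(recs, welch=welch, filter_spec=f1, pad_s=config.beep_pad_s)
    stage2_df = featurize_bank(recs, welch=welch, filter_spec=f2, pad_s=config.beep_pad_s)
    del recs

    from .io import write_feature_table

    write_feature_table(stage1_df, out / "stage1_features.csv")
    write_feature_table(stage2_df, out / "stage2_features.csv", channels=ACTIVE_CHANNELS)

    results = evaluate_cohort(
        stage1_df,
        stage2_df,
        gate_classifier=config.gate_classifier,
        stage2_classifier=config.stage2_classifier,
        feature_set=config.feature_set,
        split=config.split,
        repeats=config.repeats,
        seed=config.seed,
        selection_time_s=config.selection_time_s,
    )
    table = cohort_table(results)
    report = {
        "config": config.to_dict(),
        "per_subject": {
            str(s): {
                "stage1_accuracy": r.stage1_overall,
                "stage1_per_class": {str(k): v for k, v in r.stage1_per_class.items()},
                "stage2_accuracy": r.stage2_overall,
                "stage2_per_class": r.stage2_per_class,
                "overall_accuracy": r.overall_system,
                "itr_bits_per_min": r.itr_bits_per_min,
                "counts": r.counts,
            }
            for s, r in sorted(results.items())
        },
        "average": {
            "stage1_accuracy": table.iloc[-1]["stage1_accuracy"],
            "stage2_accuracy": table.iloc[-1]["stage2_accuracy"],
            "overall_accuracy": table.iloc[-1]["overall_accuracy"],
            "itr_bits_per_min": table.iloc[-1]["itr_bits_per_min"],
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    table.to_csv(out / "report_table.csv", index=False)
    log.info("report written to %s", out / "report.json")
    return report
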