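"""Stage 2: four-class gaze-trajectory classification on gated segments.

Only segments the LED gate declares illuminated reach this stage.  Features
are ranked with a one-way ANOVA F statistic; the packaged consensus set is
the 16 features (delta mean, delta skewness, theta trapz, theta entropy on
each of AF3, F7, F8, AF4) that dominate per-subject rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .channels import ACTIVE_CHANNELS
from .features import feature_id
from .gate import make_classifier
from .metrics import itr

__all__ = [
    "TRAJECTORY_CLASS_ORDER",
    "CONSENSUS_FEATURE_IDS",
    "anova_rank",
    "anova_f",
    "top_k_curve",
    "consensus_features",
    "CascadeResult",
    "run_cascade",
    "overall_system_accuracy",
]

#: Fixed class order used in per-class reporting.
TRAJECTORY_CLASS_ORDER: tuple[str, ...] = (
    "up_down", "right_left", "left_cross", "right_cross",
)

#: The packaged consensus feature set: {delta mean, delta skewness,
#: theta trapz, theta entropy} on each active channel (16 ids).
CONSENSUS_FEATURE_IDS: tuple[int, ...] = tuple(
    sorted(
        feature_id(ch, band, stat)
        for ch in ACTIVE_CHANNELS
        for band, stat in (
            ("delta", "mean"),
            ("delta", "skewness"),
            ("theta", "trapz"),
            ("theta", "entropy"),
        )
    )
)


def anova_f(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column of ``X`` grouped by ``y``.

    F = [SSB / (k - 1)] / [SSW / (N - k)] from the explicit between/within
    sum-of-squares decomposition of the total sum of squares.  Features with
    zero within-group variance get NaN (with a warning) rather than an
    infinite score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    k = groups.size
    n_total = X.shape[0]
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in groups:
        block = X[y == g]
        if block.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        gm = block.mean(axis=0)
        ssb += block.shape[0] * (gm - grand) ** 2
        ssw += ((block - gm) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n_total - k))
    degenerate = ssw == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero within-group variance "
            "skipped in ANOVA ranking",
            stacklevel=2,
        )
        F = np.where(degenerate, np.nan, F)
    return F


def anova_rank(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Rank features by descending one-way F statistic.

    Returns a DataFrame with 1-based ``feature_id``, ``F`` and ``rank``
    (1 = best); NaN scores sort last.
    """
    F = anova_f(X, y)
    order = np.argsort(-np.where(np.isnan(F), -np.inf, F), kind="stable")
    df = pd.DataFrame(
        {"feature_id": order + 1, "F": F[order]}
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_k_curve(
    X: np.ndarray,
    y: np.ndarray,
    ranked_ids: np.ndarray,
    classifier: str = "rf",
    k_max: int = 20,
    split: float = 0.75,
    repeats: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Holdout accuracy over nested feature sets of the top-k ranked features."""
    X = np.asarray(X, dtype=float)
    ids = np.asarray(ranked_ids, dtype=int)
    k_max = min(k_max, ids.size)
    accs = np.empty(k_max)
    for k in range(1, k_max + 1):
        cols = ids[:k] - 1
        per_repeat = []
        for r in range(repeats):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X[:, cols], y, train_size=split, stratify=y, random_state=seed + r
            )
            clf = make_classifier(classifier, seed=seed + r, n_train=len(y_tr))
            clf.fit(X_tr, y_tr)
            per_repeat.append(float((clf.predict(X_te) == y_te).mean()))
        accs[k - 1] = np.mean(per_repeat)
    return accs


def consensus_features(
    per_subject_rankings: list[pd.DataFrame] | list[np.ndarray],
    top_n: int = 20,
) -> pd.Series:
    """Occurrence counts of feature ids across subjects' top-n rankings.

    Accepts either :func:`anova_rank` frames or plain ordered id arrays.
    The packaged default consensus set itself is the fixed
    :data:`CONSENSUS_FEATURE_IDS`.
    """
    if not per_subject_rankings:
        raise ValueError("need at least one subject ranking")
    counts: dict[int, int] = {}
    for ranking in per_subject_rankings:
        if isinstance(ranking, pd.DataFrame):
            top = ranking["feature_id"].to_numpy()[:top_n]
        else:
            top = np.asarray(ranking, dtype=int)[:top_n]
        for fid in top:
            counts[int(fid)] = counts.get(int(fid), 0) + 1
    return pd.Series(counts, name="occurrences").sort_values(ascending=False)


# --------------------------------------------------------------------------
# the two-stage cascade
# --------------------------------------------------------------------------

def overall_system_accuracy(n_stage2_correct: int, n_stage1_detected: int) -> float:
    """Correct stage-2 predictions over segments the gate declared illuminated."""
    if n_stage1_detected == 0:
        raise ZeroDivisionError(
            "no segments were declared illuminated by the gate; "
            "overall system accuracy is undefined"
        )
    return n_stage2_correct / n_stage1_detected


@dataclass
class CascadeResult:
    """Averaged two-stage cascade evaluation for one feature table."""

    gate_classifier: str
    stage2_classifier: str
    stage1_overall: float
    stage1_per_class: dict
    stage2_overall: float
    stage2_per_class: dict
    overall_system: float
    itr_bits_per_min: float
    counts: dict = field(default_factory=dict)
    n_repeats: int = 0


def run_cascade(
    stage1_X: np.ndarray,
    stage2_X: np.ndarray,
    led_labels: np.ndarray,
    traj_labels: np.ndarray,
    *,
    gate_classifier: str = "rf",
    stage2_classifier: str = "rf",
    feature_ids: tuple[int, ...] | None = None,
    split: float = 0.75,
    repeats: int = 10,
    seed: int = 0,
    selection_time_s: float = 3.0,
) -> CascadeResult:
    """Linked two-stage evaluation with repeated stratified holdout.

    All arrays are aligned per segment.  Per repeat, one stratified 75/25
    split (stratified jointly on LED condition and trajectory) serves both
    stages: the gate trains on the training fold; the trajectory classifier
    trains on the illuminated part of the same fold, restricted to
    ``feature_ids`` (1-based; all columns when None).  On the test fold the
    gate fires first; stage-2 predicts only segments the gate declared
    illuminated, and is scored on the correctly gated (truly illuminated)
    ones.  The overall system accuracy divides stage-2 correct predictions
    by *all* segments the gate declared illuminated, so gate false alarms
    count against the system.
    """
    stage1_X = np.asarray(stage1_X, dtype=float)
    stage2_X = np.asarray(stage2_X, dtype=float)
    led = np.asarray(led_labels).astype(bool)
    traj = np.asarray(traj_labels)
    n = len(led)
    if not (len(stage1_X) == len(stage2_X) == len(traj) == n):
        raise ValueError("per-segment arrays must be aligned")
    cols = (
        np.asarray(feature_ids, dtype=int) - 1
        if feature_ids is not None
        else np.arange(stage2_X.shape[1])
    )
    strata = np.char.add(led.astype(str), np.char.add("|", traj.astype(str)))
    idx = np.arange(n)

    stage1_acc, stage2_acc, overall = [], [], []
    stage1_cls: dict[bool, list] = {True: [], False: []}
    stage2_cls: dict[str, list] = {c: [] for c in np.unique(traj)}
    counts = {"segments_in": [], "gate_passed": [], "gate_rejected": [], "true_positives": []}

    for r in range(repeats):
        tr, te = train_test_split(
            idx, train_size=split, stratify=strata, random_state=seed + r
        )
        gate = make_classifier(gate_classifier, seed=seed + r, n_train=len(tr))
        gate.fit(stage1_X[tr], led[tr])
        gate_pred = gate.predict(stage1_X[te]).astype(bool)
        stage1_acc.append(float((gate_pred == led[te]).mean()))
        for cond in (True, False):
            mask = led[te] == cond
            stage1_cls[cond].append(float((gate_pred[mask] == cond).mean()))

        tr_on = tr[led[tr]]
        clf = make_classifier(stage2_classifier, seed=seed + r, n_train=len(tr_on))
        clf.fit(stage2_X[np.ix_(tr_on, cols)], traj[tr_on])

        declared = te[gate_pred]  # all segments the gate declared illuminated
        tp = declared[led[declared]]  # correctly gated illuminated segments
        if tp.size == 0:
            raise RuntimeError(
                "the gate passed no illuminated segments to stage 2 in repeat "
                f"{r}; cascade evaluation is impossible"
            )
        pred_traj = clf.predict(stage2_X[np.ix_(tp, cols)])
        correct = int((pred_traj == traj[tp]).sum())
        stage2_acc.append(correct / tp.size)
        for c in stage2_cls:
            mask = traj[tp] == c
            if mask.any():
                stage2_cls[c].append(float((pred_traj[mask] == c).mean()))
        overall.append(overall_system_accuracy(correct, declared.size))
        counts["segments_in"].append(te.size)
        counts["gate_passed"].append(int(declared.size))
        counts["gate_rejected"].append(int(te.size - declared.size))
        counts["true_positives"].append(int(tp.size))

    stage2_mean = float(np.mean(stage2_acc))
    return CascadeResult(
        gate_classifier=gate_classifier,
        stage2_classifier=stage2_classifier,
        stage1_overall=float(np.mean(stage1_acc)),
        stage1_per_class={k: float(np.mean(v)) for k, v in stage1_cls.items()},
        stage2_overall=stage2_mean,
        stage2_per_class={k: float(np.mean(v)) for k, v in stage2_cls.items() if v},
        overall_system=float(np.mean(overall)),
        itr_bits_per_min=itr(stage2_mean, n_classes=4, selection_time_s=selection_time_s),
        counts={k: float(np.mean(v)) for k, v in counts.items()},
        n_repeats=repeats,
    )
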