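"""Accuracy, information transfer rate, channel ranking and robustness.

The information transfer rate (ITR) follows the Wolpaw/Shannon formulation:
with K choices, accuracy p and selection time T seconds,

    Bt  = log2 K + p log2 p + (1 - p) log2((1 - p) / (K - 1))   [bits/selection]
    ITR = 60 * Bt / T                                           [bits/min]

With K = 4 and T = 3 s (one analysis segment), perfect accuracy gives
exactly 60 * 2 / 3 = 40 bits/min, and chance accuracy (p = 1/4) gives 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "accuracy",
    "per_class_accuracy",
    "bits_per_selection",
    "itr",
    "channel_ranking",
    "robustness_report",
]


def accuracy(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Fraction of correct predictions."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    return float((pred == true).mean())


def per_class_accuracy(predictions: np.ndarray, truths: np.ndarray) -> dict:
    """Per-class recall: accuracy restricted to each true class."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    return {
        c: float((pred[true == c] == c).mean()) for c in np.unique(true)
    }


def bits_per_selection(p: float, n_classes: int = 4) -> float:
    """Bits conveyed per selection at accuracy ``p`` among ``n_classes``.

    The p = 1 and p = 0 endpoints are the analytic limits (x log x -> 0).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy p must lie in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least two choices")
    if p < 1.0 / n_classes:
        warnings.warn(
            f"accuracy {p:.3f} below chance 1/{n_classes}; "
            "ITR is in the negative-information regime",
            stacklevel=2,
        )
    bits = float(np.log2(n_classes))
    if p > 0.0:
        bits += p * np.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n_classes - 1))
    return float(bits)


def itr(p: float, n_classes: int = 4, selection_time_s: float = 3.0) -> float:
    """Information transfer rate in bits per minute."""
    if selection_time_s <= 0:
        raise ValueError("selection time must be positive")
    return 60.0 * bits_per_selection(p, n_classes) / selection_time_s


# --------------------------------------------------------------------------
# channel ranking
# --------------------------------------------------------------------------

def _holdout_accuracy(X, y, classifier, repeats, split, seed):
    from .gate import make_classifier

    accs = []
    for r in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=split, stratify=y, random_state=seed + r
        )
        clf = make_classifier(classifier, seed=seed + r, n_train=len(y_tr))
        clf.fit(X_tr, y_tr)
        accs.append(float((clf.predict(X_te) == y_te).mean()))
    return float(np.mean(accs))


def channel_ranking(
    feature_df: pd.DataFrame,
    channels: tuple[str, ...],
    classifier: str = "rf",
    repeats: int = 10,
    split: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank channels by single-channel classification accuracy.

    ``feature_df`` is a full-montage feature table (40 features per channel
    in channel-major order, columns ``feature_0001..``, plus ``led_on`` and
    ``trajectory`` label columns).  Each channel is scored on the two tasks
    the cascade needs it for — the binary LED gate (all segments) and the
    four-class trajectory discrimination (illuminated segments) — using that
    channel's 40 features alone; the ranking score is the mean of the two
    accuracies, averaged over holdout repeats.
    """
    feat_cols = [c for c in feature_df.columns if c.startswith("feature_")]
    if len(feat_cols) != 40 * len(channels):
        raise ValueError(
            f"expected {40 * len(channels)} feature columns for {len(channels)} "
            f"channels, found {len(feat_cols)}"
        )
    X = feature_df[feat_cols].to_numpy(dtype=float)
    led = feature_df["led_on"].to_numpy(dtype=bool)
    traj = feature_df["trajectory"].to_numpy()
    rows = []
    for i, ch in enumerate(channels):
        cols = slice(40 * i, 40 * (i + 1))
        gate_acc = _holdout_accuracy(X[:, cols], led, classifier, repeats, split, seed)
        traj_acc = _holdout_accuracy(
            X[led, cols], traj[led], classifier, repeats, split, seed
        )
        rows.append(
            {
                "channel": ch,
                "gate_accuracy": gate_acc,
                "trajectory_accuracy": traj_acc,
                "score": 0.5 * (gate_acc + traj_acc),
            }
        )
    out = pd.DataFrame(rows).sort_values("score", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def robustness_report(
    features: np.ndarray,
    labels: np.ndarray,
    classifiers: tuple[str, ...] = ("rf", "svm", "lda", "knn"),
    trials: int = 10,
    split: float = 0.75,
    seed: int = 0,
    overfit_gap: float = 0.10,
) -> pd.DataFrame:
    """Per-trial train/test accuracy for one subject's gate features.

    Flags a classifier when its average train-test gap exceeds
    ``overfit_gap`` (in accuracy points), the usual over-fitting symptom on
    small per-subject sets.
    """
    from .gate import make_classifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rows = []
    for name in classifiers:
        for t in range(trials):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=split, stratify=y, random_state=seed + t
            )
            clf = make_classifier(name, seed=seed + t, n_train=len(y_tr))
            clf.fit(X_tr, y_tr)
            rows.append(
                {
                    "classifier": name,
                    "trial": t + 1,
                    "train_accuracy": float((clf.predict(X_tr) == y_tr).mean()),
                    "test_accuracy": float((clf.predict(X_te) == y_te).mean()),
                }
            )
    df = pd.DataFrame(rows)
    gaps = df.groupby("classifier", sort=False).apply(
        lambda g: g["train_accuracy"].mean() - g["test_accuracy"].mean(),
        include_groups=False,
    )
    df["overfit_flag"] = df["classifier"].map(gaps > overfit_gap)
    return df
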