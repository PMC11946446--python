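"""Stage 1: LED-presence gate from the normalized trapezoidal band ratio.

When the 7 Hz LED is on, a spectral line appears inside 6-8 Hz.  The gate
feature is the ratio

    z' = trapz(PSD, 6-8 Hz) / trapz(PSD, 1-10 Hz)

computed per active channel on the causally 1-15 Hz filtered segment.  Since
6-8 Hz is a sub-band of 1-10 Hz, z' <= 1 for any non-negative spectrum and
is invariant under global amplitude scaling; LED-on segments shift it upward
and a binary classifier learns the separating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .channels import ACTIVE_CHANNELS
from .features import BandDefinition, DEFAULT_WELCH, WelchConfig, band_slice, band_trapz, welch_psd
from .preprocess import STAGE1_FILTER, Segment, bandpass

__all__ = [
    "CLASSIFIERS",
    "TrapzRatioFeature",
    "led_ratio",
    "stage1_features",
    "make_classifier",
    "knn_k",
    "HoldoutSummary",
    "train_gate",
]

#: Eq.-style band definitions of the gate ratio.
GATE_NUMERATOR_BAND = BandDefinition("gate_theta", 6.0, 8.0)
GATE_DENOMINATOR_BAND = BandDefinition("gate_rho", 1.0, 10.0)

CLASSIFIERS = ("rf", "svm", "lda", "knn")


@dataclass(frozen=True)
class TrapzRatioFeature:
    """Numerator/denominator band powers and their ratio z'."""

    theta_area: float  # 6-8 Hz
    rho_area: float  # 1-10 Hz

    @property
    def ratio(self) -> float:
        return self.theta_area / self.rho_area


def led_ratio(channel_samples: np.ndarray, cfg: WelchConfig = DEFAULT_WELCH) -> TrapzRatioFeature:
    """The normalized trapezoidal feature z' for one (filtered) channel."""
    psd = welch_psd(np.asarray(channel_samples, dtype=float), cfg)
    theta = band_trapz(band_slice(psd, GATE_NUMERATOR_BAND))
    rho = band_trapz(band_slice(psd, GATE_DENOMINATOR_BAND))
    if rho == 0.0:
        raise ZeroDivisionError("1-10 Hz band power is zero; z' is undefined")
    return TrapzRatioFeature(theta_area=theta, rho_area=rho)


def stage1_features(
    segments: list[Segment],
    active_channels: tuple[str, ...] = ACTIVE_CHANNELS,
    cfg: WelchConfig = DEFAULT_WELCH,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """One z' per active channel per segment, plus label columns.

    Applies the causal 1-15 Hz stage-1 filter first unless ``prefiltered``.
    """
    rows = []
    for seg in segments:
        fseg = seg if prefiltered else bandpass(seg, STAGE1_FILTER)
        row = {
            f"zratio_{ch}": led_ratio(fseg.channel(ch), cfg).ratio
            for ch in active_channels
        }
        row.update(
            subject=seg.meta.subject_id,
            led_on=seg.meta.led_on,
            trajectory=seg.meta.trajectory,
            repetition=seg.meta.repetition,
            window_index=seg.window_index,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# classifiers (library implementations, per configuration)
# --------------------------------------------------------------------------

def knn_k(n_train: int) -> int:
    """k for kNN: floor(sqrt(n_train)) rounded down to odd, at least 1."""
    k = max(int(np.sqrt(n_train)), 1)
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


def make_classifier(spec: str, seed: int | None = None, n_train: int | None = None):
    """Instantiate one of the four configured classifiers.

    Scale-sensitive learners (SVM, kNN, LDA) are wrapped with a z-score
    standardizer fit on the training fold; the random forest consumes raw
    features.
    """
    spec = spec.lower()
    if spec == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if spec == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if spec == "lda":
        return make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
    if spec == "knn":
        k = knn_k(n_train if n_train is not None else 25)
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    raise ValueError(f"unknown classifier {spec!r}; expected one of {CLASSIFIERS}")


@dataclass
class HoldoutSummary:
    """Averaged repeated-holdout accuracies."""

    classifier: str
    overall: float
    per_class: dict = field(default_factory=dict)
    per_repeat: list = field(default_factory=list)
    n_repeats: int = 0


def train_gate(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "rf",
    split: float = 0.75,
    repeats: int = 10,
    seed: int = 0,
) -> HoldoutSummary:
    """Repeated stratified holdout evaluation of the binary gate.

    Per repeat: a stratified ``split`` train fraction, library classifier,
    accuracy on the held-out segments.  Reports overall and per-class
    (recall) accuracy averaged over repeats.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("gate training needs both classes present")
    per_repeat = []
    per_class_acc = {c: [] for c in classes}
    for r in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=split, stratify=y, random_state=seed + r
        )
        clf = make_classifier(classifier, seed=seed + r, n_train=len(y_tr))
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        per_repeat.append(float((pred == y_te).mean()))
        for c in classes:
            mask = y_te == c
            per_class_acc[c].append(float((pred[mask] == c).mean()))
    return HoldoutSummary(
        classifier=classifier,
        overall=float(np.mean(per_repeat)),
        per_class={c: float(np.mean(v)) for c, v in per_class_acc.items()},
        per_repeat=per_repeat,
        n_repeats=repeats,
    )
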