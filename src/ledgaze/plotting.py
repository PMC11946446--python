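"""Report figures: accuracy-vs-k curves and channel-ranking bars.

Matplotlib is imported lazily so the analysis pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_top_k_curve", "plot_channel_ranking"]


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_top_k_curve(accuracies: np.ndarray, out_path: str | Path,
                     title: str = "Accuracy vs number of ranked features") -> Path:
    """Line plot of holdout accuracy over nested top-k feature sets."""
    plt = _agg_backend()
    k = np.arange(1, len(accuracies) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(k, np.asarray(accuracies) * 100.0, marker="o")
    ax.set_xlabel("number of features (ANOVA rank order)")
    ax.set_ylabel("accuracy (%)")
    ax.set_title(title)
    ax.set_xticks(k)
    ax.grid(True, alpha=0.3)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_channel_ranking(ranking: pd.DataFrame, out_path: str | Path,
                         title: str = "Single-channel classification accuracy") -> Path:
    """Bar chart of the per-channel ranking scores."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(ranking["channel"], ranking["score"] * 100.0)
    ax.set_ylabel("mean accuracy (%)")
    ax.set_title(title)
    ax.grid(True, axis="y", alpha=0.3)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
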