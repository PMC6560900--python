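"""Report figures: agreement heatmap, ROC-space scatter, KM curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import KMCurve


def plot_agreement_heatmap(matrix: pd.DataFrame, path=None):
    """Pairwise-kappa heatmap (red = moderate, toward green = very good)."""
    fig, ax = plt.subplots(figsize=(0.5 * len(matrix) + 2,) * 2)
    im = ax.imshow(matrix.to_numpy(float), vmin=0.4, vmax=1.0, cmap="RdYlGn")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Cohen's kappa")
    ax.set_title("Agreement")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_roc_space(points: dict[str, tuple[float, float]], path=None):
    """Classifiers in ROC space: false-positive rate vs true-positive rate."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (fpr, tpr) in sorted(points.items()):
        ax.scatter([fpr], [tpr], s=18)
        ax.annotate(name, (fpr, tpr), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlim(0, 1), ax.set_ylim(0, 1)
    ax.set_xlabel("false positive rate (1 - Spec)")
    ax.set_ylabel("true positive rate (Sens)")
    ax.set_title("ROC space")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_km(curves: dict[str, KMCurve], path=None, title="Overall survival"):
    """Step-function KM curves per predicted group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in sorted(curves.items()):
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{name} (n={curve.n})")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
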