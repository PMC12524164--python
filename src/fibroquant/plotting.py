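"""QC and report figures: qF-by-stage distribution, ROC curves, heatmap."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_qf_by_stage", "plot_roc_curves", "plot_correlation_heatmap"]


def plot_qf_by_stage(qf_values, stages, path) -> None:
    """Box plot of the continuous qF value per fibrosis stage."""
    qf_values = np.asarray(qf_values, dtype=float)
    stages = np.asarray(stages)
    groups = [qf_values[stages == s] for s in range(5)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(groups, tick_labels=[f"F{s}" for s in range(5)])
    ax.set_xlabel("fibrosis stage")
    ax.set_ylabel("qFibrosis value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _roc_points(scores, labels):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = np.r_[0, tps / max(tps[-1], 1)]
    fpr = np.r_[0, fps / max(fps[-1], 1)]
    return fpr, tpr


def plot_roc_curves(score_dict, labels, path, title="") -> None:
    """Overlayed ROC curves, one per named score."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, scores in score_dict.items():
        s = np.asarray(scores, dtype=float)
        ok = np.isfinite(s)
        fpr, tpr = _roc_points(s[ok], np.asarray(labels)[ok])
        ax.plot(fpr, tpr, label=name, lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(rho, path, title="Spearman rho") -> None:
    """Heatmap of a correlation matrix (DataFrame rows x cols)."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * rho.shape[1] + 2), max(3, 0.3 * rho.shape[0] + 1.5))
    )
    im = ax.imshow(rho.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="PuOr_r",
                   aspect="auto")
    ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(rho.shape[0]), rho.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
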