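"""Minimal figure exports: recurrence plots, landscape surfaces, ROC curves."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_recurrence(result, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(result.matrix, origin="lower", cmap="binary", interpolation="none")
    ax.set_xlabel("sample index")
    ax.set_ylabel("sample index")
    ax.set_title(f"recurrence plot (rate {result.recurrence_rate:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_landscape_surface(rolling, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    u = np.where(np.isfinite(rolling.potentials), rolling.potentials, np.nan)
    mesh = ax.pcolormesh(
        rolling.grid, rolling.window_centers, u, shading="auto", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label="potential U / sigma^2")
    ax.set_xlabel("standardized concentration")
    ax.set_ylabel("window centre (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(summary, path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if summary.band is not None:
        ax.fill_between(
            summary.band["fpr_grid"], summary.band["tpr_low"],
            summary.band["tpr_high"], alpha=0.25, label="95% bootstrap band",
        )
    ax.plot(summary.fpr, summary.tpr, lw=2, label=f"AUC = {summary.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
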