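"""Figure suite: learning-curve surfaces and metric-by-epoch trajectories."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES
from .probe import LearningCurveSurface

__all__ = ["surface_figure", "plot_surface", "plot_metric_by_epoch"]


def surface_figure(surface: LearningCurveSurface, n_classes: int = 2):
    """Build the learning-curve figure; returns (fig, ax).

    One polyline per epoch across time slices with an epoch-indexed color
    ramp; y-limits pinned to [0, 1]; a dashed line marks chance (1/n_classes).
    """
    if surface.n_epochs == 0 or surface.n_timesteps == 0:
        raise ValueError("empty surface")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("viridis")
    E = surface.n_epochs
    for e in range(E):
        color = cmap(e / max(E - 1, 1))
        ax.plot(surface.timesteps, surface.performance[e], color=color, lw=1.0)
    ax.axhline(1.0 / n_classes, color="grey", ls="--", lw=1.0, label="chance")
    ax.set_xlabel("time slice")
    ax.set_ylabel("probe accuracy")
    ax.set_ylim(0.0, 1.0)
    prov = surface.provenance
    title = "learning curves"
    if prov:
        title += f" — {prov.get('dataset', '')} {prov.get('label_pair', '')}".rstrip()
    ax.set_title(title)
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(surface.epochs.min(), surface.epochs.max()))
    fig.colorbar(sm, ax=ax, label="epoch")
    ax.legend(loc="lower right")
    return fig, ax


def plot_surface(surface: LearningCurveSurface, path: str | Path,
                 n_classes: int = 2) -> Path:
    """Render :func:`surface_figure` to a file."""
    fig, _ = surface_figure(surface, n_classes)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_metric_by_epoch(metric_table: pd.DataFrame, metric: str,
                         path: str | Path) -> Path:
    """Per class-pair trajectories of one metric across epochs, faceted by dataset."""
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    sub = metric_table[metric_table["metric"] == metric]
    if len(sub) == 0:
        raise ValueError(f"no rows for metric {metric!r}")
    datasets = sorted(sub["dataset"].unique())
    fig, axes = plt.subplots(
        1, len(datasets), figsize=(5.5 * len(datasets), 4), squeeze=False, sharey=True
    )
    ymin = min(0.0, float(sub["value"].min()))
    for ax, did in zip(axes[0], datasets):
        dsub = sub[sub["dataset"] == did]
        for pair, psub in dsub.groupby("label_pair"):
            mean = psub.groupby("epoch")["value"].mean()
            ax.plot(mean.index, mean.values, lw=1.2, label=str(pair))
        ax.set_title(str(did))
        ax.set_xlabel("epoch")
        ax.set_ylim(ymin, 1.0)
        if len(dsub["label_pair"].unique()) <= 15:
            ax.legend(fontsize=7, ncol=2)
    axes[0][0].set_ylabel(metric)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def _n_lines(ax) -> int:
    """Count data polylines on an axes (test hook; excludes the chance line)."""
    return sum(1 for ln in ax.get_lines() if ln.get_linestyle() == "-")
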