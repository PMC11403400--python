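"""Basic figure exports: correlation grid and medoid curves with regions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterModel
from .feature_stats import CorrelationGrid
from .interpretability import DistinctiveRegion


def plot_correlation_grid(grid: CorrelationGrid, path: str | Path) -> None:
    """Multipanel temporal cross-correlation grid over lags."""
    n = len(grid.channels)
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n), sharey=True)
    for a in range(n):
        for b in range(n):
            ax = axes[a, b]
            ax.plot(grid.lags, grid.grid[a, b], lw=0.8)
            ax.axhline(0, color="grey", lw=0.4)
            if a == 0:
                ax.set_title(grid.channels[b], fontsize=8)
            if b == 0:
                ax.set_ylabel(grid.channels[a], fontsize=8)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_medoids_with_regions(
    model: ClusterModel,
    regions: dict[int, DistinctiveRegion] | None,
    path: str | Path,
) -> None:
    """Medoid curves per channel, distinctive regions shaded."""
    n_ch = len(model.channels)
    fig, axes = plt.subplots(1, n_ch, figsize=(3.0 * n_ch, 3.0), sharex=True)
    for c, ch in enumerate(model.channels):
        ax = axes[c] if n_ch > 1 else axes
        for raw_idx, medoid in enumerate(model.medoids):
            pheno = int(model.label_order[raw_idx])
            u = np.linspace(0, 1, medoid.shape[0])
            ax.plot(u, medoid[:, c], lw=0.9, label=f"phenogroup {pheno}")
            if regions and pheno in regions:
                for s, e in regions[pheno].segments_normalized():
                    ax.axvspan(s, e, alpha=0.08)
        ax.set_title(ch, fontsize=9)
        ax.set_xlabel("normalized test time")
    (axes[0] if n_ch > 1 else axes).legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
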