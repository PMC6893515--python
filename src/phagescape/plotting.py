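"""Optional figure rendering: clustered motif-frequency heatmap and volcano plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .enrichment import ClusteredProfileMatrix


def plot_heatmap(clustered: ClusteredProfileMatrix, path: str | Path) -> Path:
    """Render the Ward-clustered motif x tissue percentage matrix."""
    grid = sns.clustermap(
        clustered.matrix,
        row_linkage=clustered.motif_linkage,
        col_linkage=clustered.tissue_linkage,
        cmap="YlOrRd",
        yticklabels=False,
    )
    path = Path(path)
    grid.savefig(path, dpi=150)
    plt.close(grid.fig)
    return path


def plot_volcano(volcano: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> Path:
    """One-sided volcano plot: log2 fold change vs -log2 adjusted p."""
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(volcano["selective"], "crimson", "grey")
    ax.scatter(
        volcano["log2_fold_change"],
        volcano["neg_log2_p_adjusted"],
        s=6,
        c=colors,
        alpha=0.6,
        linewidths=0,
    )
    ax.axvline(1.0, ls="--", c="grey", lw=0.8)
    ax.axhline(-np.log2(alpha), ls="--", c="grey", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log2 adjusted p")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
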