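"""Optional diagnostic plots (never load-bearing for the analysis)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .integrate import PCCorrelationTree
from .pca import PCDecomposition, embed2d
from .select import FeatureSelection

__all__ = ["plot_embedding", "plot_dendrogram"]


def plot_embedding(
    d: PCDecomposition,
    k1: int,
    k2: int,
    selection: FeatureSelection | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Scatter of the 2-D feature embedding, selected outliers in red."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coords = embed2d(d, k1, k2)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords[:, 0], coords[:, 1], s=8, c="0.6", label="features")
    if selection is not None:
        mask = np.isin(d.feature_ids, selection.selected)
        ax.scatter(
            coords[mask, 0], coords[mask, 1], s=14, c="red", label="selected"
        )
        ax.legend(frameon=False)
    ax.set_xlabel(f"PC{k1} score")
    ax.set_ylabel(f"PC{k2} score")
    ax.set_title(f"{d.layer}: PC{k1} vs PC{k2}")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_dendrogram(
    tree: PCCorrelationTree, path: str | Path | None = None, ax=None
):
    """UPGMA dendrogram of all pooled PCs (height = 1 - |r|)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, tree.n * 0.12), 4))
    dendrogram(
        tree.merges,
        labels=[str(lab) for lab in tree.labels],
        leaf_rotation=90,
        leaf_font_size=6,
        ax=ax,
    )
    ax.set_ylabel("1 - |r|")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
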