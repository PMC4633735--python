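"""Cross-layer integration of principal components.

All PCs from all layers are pooled and their sample-contribution vectors
are compared by Pearson correlation over the shared samples.  The
dissimilarity d(p, q) = 1 - |r(CX^p, CX^q)| treats anticorrelation as
proximity (a PC and its sign flip describe the same contrast) and is
clustered with UPGMA (average linkage).  A coherent cross-layer cluster
is then picked by two criteria: largest mean within-cluster |r|, ties
broken toward small component indices (small k = large variance
contribution).  Each chosen PC's class separation is validated by a
categorical regression of its contributions on the four class
indicators, which is algebraically one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist

from .matrices import SampleDesign
from .pca import PCDecomposition

__all__ = [
    "PCLabel",
    "PCCorrelationTree",
    "SelectedPCSet",
    "CategoricalFit",
    "build_tree",
    "select_pcs",
    "categorical_regression",
    "scatter_report",
]


class PCLabel(NamedTuple):
    """A principal component named by its layer and 1-based index."""

    layer: str
    k: int

    def __str__(self) -> str:  # matches labels like "PC3_compound"
        return f"PC{self.k}_{self.layer}"


@dataclass
class PCCorrelationTree:
    """Pooled PCs, their 1-|r| distance matrix and the UPGMA merge tree."""

    labels: list[PCLabel]
    distance: np.ndarray  # symmetric, zero diagonal, in [0, 1]
    merges: np.ndarray  # scipy linkage matrix (UPGMA on `distance`)

    @property
    def n(self) -> int:
        return len(self.labels)

    def abs_correlation(self, p: int, q: int) -> float:
        return 1.0 - float(self.distance[p, q])

    def to_newick(self) -> str:
        """Newick string with leaves labelled PC<k>_<layer>."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(
            self.merges, [str(lab) for lab in self.labels]
        )
        return str(tree).strip()


@dataclass
class SelectedPCSet:
    """The chosen coherent cross-layer cluster of PCs."""

    members: list[PCLabel]
    cluster_mean_abs_r: float
    cut_height: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("selected PC set must be non-empty")
        if not 0.0 <= self.cluster_mean_abs_r <= 1.0 + 1e-12:
            raise ValueError("cluster_mean_abs_r outside [0, 1]")

    def axes_for(self, layer: str) -> list[int]:
        """Sorted component indices selected within one layer."""
        return sorted(lab.k for lab in self.members if lab.layer == layer)

    @property
    def layers(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.members:
            seen.setdefault(lab.layer, None)
        return list(seen)


@dataclass
class CategoricalFit:
    """Least-squares fit of CX^k on the class indicators delta[a, i].

    Cell-means coding without intercept: the coefficient b_a is the mean
    contribution of class a, and the F test against the grand-mean-only
    model is identical to one-way ANOVA across the classes.
    """

    pc: PCLabel
    coefficients: dict[str, float]
    F_statistic: float
    p_value: float
    residual_df: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _stack_contributions(
    decomps: Sequence[PCDecomposition], max_k: int | None = None
) -> tuple[list[PCLabel], np.ndarray]:
    if not decomps:
        raise ValueError("no decompositions supplied")
    ref = decomps[0].sample_ids
    labels: list[PCLabel] = []
    rows: list[np.ndarray] = []
    for d in decomps:
        if d.sample_ids != ref:
            raise ValueError(
                f"layer {d.layer!r} sample order differs from {decomps[0].layer!r}; "
                "align layers first"
            )
        top = d.n_components if max_k is None else min(max_k, d.n_components)
        for k in range(1, top + 1):
            labels.append(PCLabel(d.layer, k))
            rows.append(d.contribution(k))
    if len(labels) < 2:
        raise ValueError("need at least 2 PCs to build a tree")
    return labels, np.vstack(rows)


def build_tree(
    decomps: Sequence[PCDecomposition],
    max_k: int | None = None,
    method: str = "pearson",
) -> PCCorrelationTree:
    """Pool all PCs, compute 1-|r| distances and the UPGMA merge sequence.

    ``method="pearson"`` (default) or ``"spearman"`` (rank correlation).

    Within a feature-centered layer, distinct PCs of non-negligible
    variance have exactly zero Pearson correlation (orthonormal,
    zero-mean contribution vectors), so only cross-layer correlation can
    glue PCs together; this is asserted on every call.  Degenerate
    components (zero variance across samples) get |r| = 0 against
    everything.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    labels, C = _stack_contributions(decomps, max_k=max_k)
    if method == "spearman":
        from scipy.stats import rankdata

        C = np.apply_along_axis(rankdata, 1, C)
    sd = C.std(axis=1)
    constant = sd <= 1e-15
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(C)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - np.abs(r)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)

    # orthonormality of same-layer PCs must survive into correlation space
    rank = {dec.layer: dec.effective_rank for dec in decomps}
    centered = {dec.layer: dec.centering == "feature_mean" for dec in decomps}
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lj = labels[j]
            if method != "pearson" or li.layer != lj.layer or not centered[li.layer]:
                continue
            if li.k <= rank[li.layer] and lj.k <= rank[lj.layer]:
                if abs(r[i, j]) > 1e-8:
                    raise AssertionError(
                        f"within-layer PCs {li} and {lj} correlate (r={r[i, j]:.2e}); "
                        "contribution vectors are not orthonormal"
                    )

    Z = linkage(squareform(d, checks=False), method="average")
    return PCCorrelationTree(labels=labels, distance=d, merges=Z)


def _cluster_stats(
    tree: PCCorrelationTree, members_idx: Sequence[int]
) -> tuple[float, int]:
    """(mean pairwise |r|, sum of component indices) for a candidate cluster."""
    idx = list(members_idx)
    pairs = [
        1.0 - tree.distance[p, q]
        for a, p in enumerate(idx)
        for q in idx[a + 1 :]
    ]
    mean_r = float(np.mean(pairs)) if pairs else 0.0
    return mean_r, sum(tree.labels[p].k for p in idx)


def _nearest_feasible_cut(
    tree: PCCorrelationTree, min_layers: int, max_k: int | None
) -> float | None:
    """Smallest merge height producing a cluster spanning >= min_layers layers."""
    n = tree.n
    sets: dict[int, set[int]] = {
        i: {i}
        for i in range(n)
        if max_k is None or tree.labels[i].k <= max_k
    }
    for row, (a, b, height, _count) in enumerate(tree.merges):
        merged = sets.get(int(a), set()) | sets.get(int(b), set())
        sets[n + row] = merged
        layers = {tree.labels[i].layer for i in merged}
        if len(merged) >= 2 and len(layers) >= min_layers:
            return float(height)
    return None


def select_pcs(
    tree: PCCorrelationTree,
    cut_height: float = 0.4,
    min_layers: int = 2,
    max_k: int | None = None,
) -> SelectedPCSet:
    """Cut the UPGMA tree and pick the tightest multi-layer cluster.

    Criterion 1: among flat clusters at ``cut_height`` that span at least
    ``min_layers`` distinct layers, maximize the mean pairwise |r|.
    Criterion 2: exact ties go to the cluster with the smallest sum of
    component indices (small k carries more variance).  ``max_k``
    discards members with k > max_k before scoring.
    """
    if not 0.0 < cut_height < 1.0:
        raise ValueError(f"cut_height must be in (0, 1), got {cut_height}")
    if min_layers < 1:
        raise ValueError("min_layers must be >= 1")
    flat = fcluster(tree.merges, t=cut_height, criterion="distance")
    candidates: list[tuple[float, int, list[int]]] = []
    for cid in np.unique(flat):
        idx = [int(i) for i in np.nonzero(flat == cid)[0]]
        if max_k is not None:
            idx = [i for i in idx if tree.labels[i].k <= max_k]
        if len(idx) < 2:
            continue
        layers = {tree.labels[i].layer for i in idx}
        if len(layers) < min_layers:
            continue
        mean_r, sum_k = _cluster_stats(tree, idx)
        candidates.append((mean_r, sum_k, idx))
    if not candidates:
        nearest = _nearest_feasible_cut(tree, min_layers, max_k)
        hint = (
            f"; nearest feasible cut_height is just above {nearest:.4f}"
            if nearest is not None
            else "; no cut produces such a cluster"
        )
        raise ValueError(
            f"no cluster at cut_height={cut_height} spans >= {min_layers} layers{hint}"
        )
    candidates.sort(key=lambda c: (-c[0], c[1], [str(tree.labels[i]) for i in c[2]]))
    mean_r, _sum_k, idx = candidates[0]
    members = sorted(
        (tree.labels[i] for i in idx), key=lambda lab: (lab.layer, lab.k)
    )
    return SelectedPCSet(
        members=members, cluster_mean_abs_r=mean_r, cut_height=cut_height
    )


def categorical_regression(
    d: PCDecomposition, k: int, design: SampleDesign
) -> CategoricalFit:
    """Regress the sample contributions CX^k on the class indicators.

    The model is CX_i^k = sum_a b_a delta[a, i] + eps_i (no intercept):
    ordinary least squares on the 0/1 design matrix, with the F statistic
    from the comparison against the grand-mean-only model.  Categorical
    coding is used because no ordering or spacing among the four groups
    is assumed.
    """
    y = d.contribution(k)
    delta = design.indicator_matrix(d.sample_ids)
    counts = delta.sum(axis=0)
    absent = [c for c in delta.columns if counts[c] == 0]
    if absent:
        raise ValueError(f"class(es) absent from design: {absent}")
    D = delta.to_numpy()
    n, g = D.shape
    if n - g < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, classes={g})")

    b, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss_full = float(np.sum((y - D @ b) ** 2))
    rss_restricted = float(np.sum((y - y.mean()) ** 2))
    df_num, df_den = g - 1, n - g

    if rss_restricted <= 1e-30:  # contributions constant across samples
        F, p = 0.0, 1.0
    elif rss_full <= 1e-30 * rss_restricted:
        warnings.warn(
            f"zero residual variance for {PCLabel(d.layer, k)}; p reported as 0-limit",
            stacklevel=2,
        )
        F, p = np.inf, 0.0
    else:
        F = ((rss_restricted - rss_full) / df_num) / (rss_full / df_den)
        p = float(f_dist.sf(F, df_num, df_den))

    return CategoricalFit(
        pc=PCLabel(d.layer, k),
        coefficients={c: float(v) for c, v in zip(delta.columns, b)},
        F_statistic=float(F),
        p_value=p,
        residual_df=df_den,
    )


def scatter_report(
    selected: SelectedPCSet, decomps: Sequence[PCDecomposition]
) -> pd.DataFrame:
    """Pairwise Pearson r and two-sided p for the selected PCs.

    p-values come from the t transform with M-2 degrees of freedom; the
    diagonal (a PC against itself) is included with r = 1, p = 0.
    """
    by_layer = {d.layer: d for d in decomps}
    vectors = {}
    for lab in selected.members:
        if lab.layer not in by_layer:
            raise KeyError(f"no decomposition for layer {lab.layer!r}")
        vectors[lab] = by_layer[lab.layer].contribution(lab.k)
    M = len(next(iter(vectors.values())))
    rows = []
    members = selected.members
    for i, p_lab in enumerate(members):
        for q_lab in members[i:]:
            if p_lab == q_lab:
                r_val, p_val = 1.0, 0.0
            else:
                r_val = float(np.corrcoef(vectors[p_lab], vectors[q_lab])[0, 1])
                if abs(r_val) >= 1.0:
                    p_val = 0.0
                else:
                    t = abs(r_val) * np.sqrt((M - 2) / (1.0 - r_val**2))
                    from scipy.stats import t as t_dist

                    p_val = float(2.0 * t_dist.sf(t, M - 2))
            rows.append(
                {"pc1": str(p_lab), "pc2": str(q_lab), "r": r_val, "p_value": p_val}
            )
    return pd.DataFrame(rows)
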