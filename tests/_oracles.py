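"""Independent oracles used by the test suite.

Each oracle is a deliberately naive re-derivation (brute force or closed
form) of a quantity the package computes by a different route.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f as f_dist


def upgma_cophenetic(d: np.ndarray) -> tuple[np.ndarray, list[float]]:
    """Brute-force average-linkage clustering of a full distance matrix.

    Returns the cophenetic distance matrix and the ordered merge heights.
    Average linkage distance between clusters is the plain mean of the
    original pairwise distances (the "unweighted" in UPGMA).
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    coph = np.zeros((n, n))
    heights: list[float] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                avg = float(
                    np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        height, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = height
        clusters[next_id] = clusters[a] + clusters[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        heights.append(height)
        next_id += 1
    return coph, heights


def anova_closed_form(y: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p from the explicit sum-of-squares decomposition."""
    y = np.asarray(y, dtype=float)
    groups = [y[labels == g] for g in np.unique(labels)]
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(y) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(f_dist.sf(F, df_b, df_w))


def gram_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature-space PCA via eigendecomposition of the sample-space Gram matrix.

    X must already be centered as desired.  Returns (variance_fraction,
    contributions, feature_scores) with components ordered by decreasing
    eigenvalue; signs are arbitrary.
    """
    G = X.T @ X
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    variance_fraction = w / w.sum()
    contributions = V.T  # rows are sample-space eigenvectors
    feature_scores = X @ V
    return variance_fraction, contributions, feature_scores
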