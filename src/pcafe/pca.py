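"""Feature-space principal component analysis of one omics layer.

The orientation is the transpose of the usual sample-space PCA: every
feature (probe or compound) is a point in M-dimensional *sample* space.
Each principal component k then carries two things:

* a sample-contribution vector ``CX^k`` — an M-vector, one entry per
  sample, describing how the samples span that component (the right
  singular vectors of the feature-centered matrix); and
* a per-feature score ``PCX_i^k`` — feature i's coordinate along the
  component (left singular vector times singular value).

Contribution vectors are the objects the integration stage correlates
across layers, and feature scores are what the outlier selection stage
thresholds.  At most one component per sample exists (K <= M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import OmicsMatrix

__all__ = ["PCDecomposition", "decompose", "embed2d"]

CENTER_MODES = ("feature_mean", "none")


@dataclass
class PCDecomposition:
    """Per-layer PCA output in the feature-space orientation.

    Attributes
    ----------
    contributions :
        K x M array; row k-1 is the sample-contribution vector CX^k,
        rows orthonormal.  Component indices are 1-based in all interfaces.
    feature_scores :
        N x K array; entry [i, k-1] is PCX_i^k.
    variance_fraction :
        Length-K, non-increasing, sums to <= 1.
    effective_rank :
        Number of components with non-negligible singular value; trailing
        degenerate components are kept (so K = min(N, M)) but flagged.
    """

    layer: str
    sample_ids: list[str]
    feature_ids: list[str]
    contributions: np.ndarray
    feature_scores: np.ndarray
    variance_fraction: np.ndarray
    singular_values: np.ndarray
    centering: str
    effective_rank: int

    @property
    def n_components(self) -> int:
        return self.contributions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.contributions.shape[1]

    @property
    def n_features(self) -> int:
        return self.feature_scores.shape[0]

    def _check_k(self, k: int) -> int:
        if not 1 <= k <= self.n_components:
            raise IndexError(
                f"component index {k} out of range 1..{self.n_components} "
                f"(layer {self.layer!r})"
            )
        return k - 1

    def contribution(self, k: int) -> np.ndarray:
        """Sample-contribution vector CX^k (1-based k)."""
        return self.contributions[self._check_k(k)]

    def scores(self, k: int) -> np.ndarray:
        """Per-feature scores PCX_i^k along component k (1-based)."""
        return self.feature_scores[:, self._check_k(k)]


def decompose(m: OmicsMatrix, center: str = "feature_mean") -> PCDecomposition:
    """SVD of the (optionally feature-centered) N x M layer matrix.

    ``center="feature_mean"`` (default) subtracts each feature's mean
    across samples, so components describe between-sample contrast;
    ``"none"`` decomposes the raw matrix.  The sign of each CX^k is fixed
    so that its largest-magnitude entry is positive, which makes runs
    reproducible despite the inherent sign ambiguity of the SVD.
    """
    if center not in CENTER_MODES:
        raise ValueError(f"center must be one of {CENTER_MODES}, got {center!r}")
    X = np.asarray(m.values, dtype=float)
    n, M = X.shape
    if n < 2 or M < 2:
        raise ValueError(
            f"layer {m.layer!r}: need >= 2 features and >= 2 samples, got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError(f"layer {m.layer!r}: non-finite values")
    if center == "feature_mean":
        X = X - X.mean(axis=1, keepdims=True)

    # thin SVD: X = U diag(s) Vt; rows of Vt live in sample space
    U, s, Vt = np.linalg.svd(X, full_matrices=False)

    # deterministic sign: orient each component so the largest-|.| sample
    # contribution is positive (first such entry wins on exact ties)
    for k in range(Vt.shape[0]):
        pivot = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, pivot] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]

    total = float(np.sum(s**2))
    if total > 0:
        variance_fraction = s**2 / total
    else:  # all-zero matrix after centering: no variance to attribute
        variance_fraction = np.zeros_like(s)
    tol = max(n, M) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    effective_rank = int(np.sum(s > tol))

    return PCDecomposition(
        layer=m.layer,
        sample_ids=m.sample_ids,
        feature_ids=m.feature_ids,
        contributions=Vt,
        feature_scores=U * s,
        variance_fraction=variance_fraction,
        singular_values=s,
        centering=center,
        effective_rank=effective_rank,
    )


def embed2d(d: PCDecomposition, k1: int, k2: int) -> np.ndarray:
    """Per-feature coordinate pairs (PCX_i^{k1}, PCX_i^{k2}).

    The 2-D embedding used both for diagnostics plots and for two-axis
    outlier selection (e.g. compounds in the PC2-PC3 plane).
    """
    if k1 == k2:
        raise ValueError(f"degenerate plane: k1 == k2 == {k1}")
    return np.column_stack([d.scores(k1), d.scores(k2)])
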