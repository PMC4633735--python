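"""PCA-based unsupervised feature extraction.

Features whose scores along the chosen principal components are outlying
are flagged, without ever consulting class labels.  The default rule
standardizes each axis's scores by their across-feature standard
deviation, sums the squared standardized scores (so a 2-axis criterion
is rotation-insensitive within its plane), converts to an upper-tail
chi-squared p-value with df = number of axes, and controls the FDR with
Benjamini-Hochberg at ``alpha``.  A model-free quantile threshold on the
same statistic is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .matrices import OmicsMatrix, SampleDesign
from .pca import PCDecomposition

__all__ = [
    "SelectionCriterion",
    "FeatureSelection",
    "select_features",
    "collapse_probes",
    "pattern_table",
]


@dataclass
class SelectionCriterion:
    """Which axes to scan for outliers and how to threshold them.

    axes :
        One or two 1-based component indices (e.g. compounds along PC3,
        miRNAs along PC1 and PC2).
    method :
        ``chi2_bh`` (default): chi-squared upper tail + Benjamini-Hochberg
        at ``alpha``.  ``score_quantile``: keep features whose statistic
        exceeds the given across-feature quantile.
    robust :
        Standardize by 1.4826*MAD instead of the standard deviation;
        guards heavy-tailed score distributions.
    """

    axes: tuple[int, ...]
    method: str = "chi2_bh"
    alpha: float = 0.01
    quantile: float = 0.99
    robust: bool = False

    def __post_init__(self) -> None:
        self.axes = tuple(int(a) for a in self.axes)
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("criterion takes one or two axes")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axes {self.axes}")
        if any(a < 1 for a in self.axes):
            raise ValueError("axes are 1-based component indices")
        if self.method not in ("chi2_bh", "score_quantile"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")


@dataclass
class FeatureSelection:
    """Outlier features of one layer, ordered by decreasing statistic."""

    layer: str
    selected: list[str]
    table: pd.DataFrame = field(repr=False)  # feature-indexed: statistic, p, adj p
    criterion: SelectionCriterion = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def statistic(self) -> pd.Series:
        return self.table["statistic"]


def select_features(
    d: PCDecomposition, crit: SelectionCriterion
) -> FeatureSelection:
    """Flag outlier features along the criterion axes of one layer."""
    scores = np.column_stack([d.scores(a) for a in crit.axes])
    if crit.robust:
        med = np.median(scores, axis=0)
        scale = 1.4826 * np.median(np.abs(scores - med), axis=0)
    else:
        scale = scores.std(axis=0, ddof=1)
    dead = [a for a, s in zip(crit.axes, scale) if s <= 0]
    if dead:
        raise ValueError(
            f"layer {d.layer!r}: zero score variance along axis/axes {dead}"
        )
    z = scores / scale
    stat = np.sum(z**2, axis=1)

    table = pd.DataFrame({"statistic": stat}, index=pd.Index(d.feature_ids))
    if crit.method == "chi2_bh":
        p = chi2.sf(stat, df=len(crit.axes))
        _, p_adj, _, _ = multipletests(p, alpha=crit.alpha, method="fdr_bh")
        table["p_value"] = p
        table["p_adjusted"] = p_adj
        keep = p_adj < crit.alpha
    else:
        threshold = float(np.quantile(stat, crit.quantile))
        keep = stat > threshold
    order = np.argsort(-stat, kind="stable")
    selected = [d.feature_ids[i] for i in order if keep[i]]
    return FeatureSelection(
        layer=d.layer, selected=selected, table=table, criterion=crit
    )


def collapse_probes(
    sel: FeatureSelection, mapping: Mapping[str, str] | None
) -> pd.DataFrame:
    """Collapse selected probe identifiers onto gene symbols.

    Multiple array probes may interrogate one gene; the symbol list keeps
    first-occurrence order (i.e. strongest probe first) with per-symbol
    probe counts.  Features without a mapping pass through under their
    own identifier.
    """
    mapping = mapping or {}
    symbols: list[str] = []
    counts: dict[str, int] = {}
    for feature in sel.selected:
        symbol = mapping.get(feature, feature)
        if symbol not in counts:
            symbols.append(symbol)
            counts[symbol] = 0
        counts[symbol] += 1
    return pd.DataFrame(
        {"symbol": symbols, "n_probes": [counts[s] for s in symbols]}
    )


def _contrast_effect(
    values: np.ndarray, in_group: np.ndarray
) -> float:
    """|mean difference| / pooled within-group SD for a two-group split."""
    a, b = values[in_group], values[~in_group]
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    dfa, dfb = max(a.size - 1, 0), max(b.size - 1, 0)
    pooled = np.sqrt((va * dfa + vb * dfb) / max(dfa + dfb, 1))
    if pooled <= 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def pattern_table(
    sel: FeatureSelection,
    m: OmicsMatrix,
    design: SampleDesign,
    tumor_classes: Sequence[str] = ("ICC", "HCC"),
    icc_class: str = "ICC",
) -> pd.DataFrame:
    """Class means and a pattern call for each selected feature.

    Two planned contrasts are compared on standardized effect size:
    tumor vs non-tumor, and the ICC class vs the three other groups; the
    larger one names the pattern.  A feature with no effect on either
    contrast (e.g. constant) is called ``mixed``.
    """
    labels = design.labels(m.sample_ids)
    missing = [f for f in sel.selected if f not in m.data.index]
    if missing:
        raise KeyError(f"selected features missing from matrix: {missing}")
    is_tumor = np.isin(labels, list(tumor_classes))
    is_icc = labels == icc_class
    columns = (
        [f"mean_{c}" for c in design.classes]
        + ["tumor_effect", "icc_effect", "pattern"]
    )
    if not sel.selected:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="feature"))
    rows = []
    for feature in sel.selected:
        v = m.data.loc[feature].to_numpy(dtype=float)
        class_means = {
            c: float(v[labels == c].mean()) for c in design.classes
        }
        t_eff = _contrast_effect(v, is_tumor)
        i_eff = _contrast_effect(v, is_icc)
        if max(t_eff, i_eff) <= 1e-12:
            call = "mixed"
        elif t_eff >= i_eff:
            call = "tumor_vs_nontumor"
        else:
            call = "icc_vs_rest"
        rows.append(
            {
                "feature": feature,
                **{f"mean_{c}": class_means[c] for c in design.classes},
                "tumor_effect": t_eff,
                "icc_effect": i_eff,
                "pattern": call,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
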