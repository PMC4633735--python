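"""Model/Results facade over the integration pipeline.

``MultiOmicsPCA`` is constructed from the data (layer matrices plus the
sample design); ``fit()`` runs per-layer feature-space PCA, pools the
PCs, clusters their sample-contribution vectors, selects the coherent
cross-layer PC set and validates each member by categorical regression.
The returned ``MultiOmicsPCAResults`` carries the estimates and
diagnostics, prints a ``summary()`` table, and exposes the downstream
stages — outlier feature selection and LOOCV diagnosis — as methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import classify as _classify
from . import integrate as _integrate
from . import select as _select
from .matrices import OmicsMatrix, SampleDesign, align_layers
from .pca import PCDecomposition, decompose

__all__ = ["MultiOmicsPCA", "MultiOmicsPCAResults"]


class MultiOmicsPCA:
    """Integrative feature-space PCA across omics layers.

    Parameters
    ----------
    layers :
        Mapping layer name -> OmicsMatrix, or a sequence of OmicsMatrix.
    design :
        Sample-to-class assignment shared by all layers.
    center :
        PCA centering convention, ``"feature_mean"`` (default) or ``"none"``.
    log_transform :
        Apply a natural-log transform to every layer before PCA.  Off by
        default (vendor-normalized array matrices are often already on a
        log scale); turn on for linear-scale data with multiplicative
        noise, e.g. the synthetic cohorts.
    """

    def __init__(
        self,
        layers: Mapping[str, OmicsMatrix] | Sequence[OmicsMatrix],
        design: SampleDesign,
        center: str = "feature_mean",
        log_transform: bool = False,
    ) -> None:
        if isinstance(layers, Mapping):
            layer_list = list(layers.values())
        else:
            layer_list = list(layers)
        if not layer_list:
            raise ValueError("at least one layer is required")
        layer_list = align_layers(layer_list, design)
        if log_transform:
            import numpy as np

            layer_list = [m.log_transformed(base=np.e) for m in layer_list]
        self.layers: dict[str, OmicsMatrix] = {m.layer: m for m in layer_list}
        if len(self.layers) != len(layer_list):
            raise ValueError("duplicate layer names")
        self.design = design
        self.center = center
        self.log_transform = log_transform

    @classmethod
    def from_dataframes(
        cls,
        frames: Mapping[str, pd.DataFrame],
        design: SampleDesign,
        **kwargs,
    ) -> "MultiOmicsPCA":
        layers = {
            name: OmicsMatrix(layer=name, data=df) for name, df in frames.items()
        }
        return cls(layers, design, **kwargs)

    def fit(
        self,
        cut_height: float = 0.4,
        min_layers: int = 2,
        max_k: int | None = None,
    ) -> "MultiOmicsPCAResults":
        """Run PCA, PC clustering, PC selection and the per-PC regressions."""
        decomps = {
            name: decompose(m, center=self.center) for name, m in self.layers.items()
        }
        tree = _integrate.build_tree(list(decomps.values()))
        selected = _integrate.select_pcs(
            tree, cut_height=cut_height, min_layers=min_layers, max_k=max_k
        )
        fits = {
            lab: _integrate.categorical_regression(
                decomps[lab.layer], lab.k, self.design
            )
            for lab in selected.members
        }
        return MultiOmicsPCAResults(
            model=self, decompositions=decomps, tree=tree,
            selected=selected, regressions=fits,
        )


@dataclass
class MultiOmicsPCAResults:
    """Fitted cross-layer PC structure with diagnostics."""

    model: MultiOmicsPCA
    decompositions: dict[str, PCDecomposition]
    tree: _integrate.PCCorrelationTree
    selected: _integrate.SelectedPCSet
    regressions: dict[_integrate.PCLabel, _integrate.CategoricalFit] = field(
        repr=False
    )

    # -- estimates ---------------------------------------------------------
    def selection_frame(self) -> pd.DataFrame:
        """One row per selected PC: variance share, ANOVA F/p, class means."""
        rows = []
        for lab in self.selected.members:
            fit = self.regressions[lab]
            d = self.decompositions[lab.layer]
            row = {
                "pc": str(lab),
                "layer": lab.layer,
                "k": lab.k,
                "variance_fraction": float(d.variance_fraction[lab.k - 1]),
                "F": fit.F_statistic,
                "p_value": fit.p_value,
            }
            row.update({f"b_{c}": v for c, v in fit.coefficients.items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("pc")

    def scatter_report(self) -> pd.DataFrame:
        return _integrate.scatter_report(
            self.selected, list(self.decompositions.values())
        )

    def to_newick(self) -> str:
        return self.tree.to_newick()

    # -- downstream stages -------------------------------------------------
    def select_features(
        self,
        layer: str,
        axes: Sequence[int] | None = None,
        **criterion_kwargs,
    ) -> _select.FeatureSelection:
        """Outlier feature extraction along the selected (or given) axes.

        With ``axes=None`` the axes are the selected PCs of that layer
        (at most two, smallest k first).
        """
        if layer not in self.decompositions:
            raise KeyError(f"unknown layer {layer!r}")
        if axes is None:
            axes = self.selected.axes_for(layer)[:2]
            if not axes:
                raise ValueError(
                    f"no selected PCs in layer {layer!r}; pass axes explicitly"
                )
        crit = _select.SelectionCriterion(axes=tuple(axes), **criterion_kwargs)
        return _select.select_features(self.decompositions[layer], crit)

    def pattern_table(
        self, selection: _select.FeatureSelection
    ) -> pd.DataFrame:
        return _select.pattern_table(
            selection, self.model.layers[selection.layer], self.model.design
        )

    def classify(
        self, layer: str, panel: Sequence[str], **task_kwargs
    ) -> _classify.ClassificationReport:
        """LOOCV three-class diagnosis from a feature panel of one layer."""
        task = _classify.DiagnosticTask(panel=list(panel), **task_kwargs)
        return _classify.loocv(self.model.layers[layer], self.model.design, task)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted cross-layer PC structure."""
        lines = []
        lines.append("Multi-omics feature-space PCA integration")
        lines.append("=" * 58)
        lines.append(
            f"Layers: "
            + ", ".join(
                f"{name} ({d.n_features} features)"
                for name, d in self.decompositions.items()
            )
        )
        counts = self.model.design.class_counts()
        lines.append(
            "Samples: "
            + ", ".join(f"{c}={n}" for c, n in counts.items())
            + f" (total {self.model.design.n_samples})"
        )
        lines.append(
            f"PCs pooled: {self.tree.n}; cut height: {self.selected.cut_height}; "
            f"cluster mean |r|: {self.selected.cluster_mean_abs_r:.3f}"
        )
        lines.append("")
        lines.append("Selected PCs (categorical regression on class indicators)")
        lines.append("-" * 58)
        frame = self.selection_frame()
        lines.append(
            frame[["variance_fraction", "F", "p_value"]].to_string(
                float_format=lambda v: f"{v:.4g}"
            )
        )
        return "\n".join(lines)
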