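"""Synthetic multi-layer cohorts with planted class structure.

The generator emulates the statistical shape of a paired liver-tumor
cohort profiled on three platforms: 32 samples in four groups (10 ICC,
10 matched ICC_NT, 6 HCC, 6 matched HCC_NT) measured as ~150 compounds,
5000 mRNA probes and 300 miRNA probes.  Values follow a log-normal
model — normal on the log scale, exponentiated on output — because
microarray intensities and metabolite abundances are positive and
right-skewed with multiplicative noise.

Two signal patterns are planted on the log scale into disjoint random
feature subsets of each layer:

* tumor features: ``+effect_size_tumor`` added to every tumor sample
  (ICC and HCC);
* ICC features: ``+effect_size_icc * icc_contrast_multiplier`` added to
  ICC samples only, so the ICC vs ICC_NT separation exceeds the
  HCC vs HCC_NT one (the multiplier is >= 1).

The planted feature identifiers are returned as per-layer truth lists,
which downstream parameter-recovery tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import json

import numpy as np
import pandas as pd

from .matrices import (
    DEFAULT_CLASSES,
    OmicsMatrix,
    SampleDesign,
    write_design,
    write_matrix,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "class_means"]

_DEFAULT_SAMPLES = {"ICC": 10, "ICC_NT": 10, "HCC": 6, "HCC_NT": 6}
_DEFAULT_FEATURES = {"compound": 150, "mRNA": 5000, "miRNA": 300}
# planted counts mirror the scale of the selected panels in the cohort the
# generator emulates (14 compounds, 67 mRNA probes, 17 miRNAs in total)
_DEFAULT_TUMOR = {"compound": 7, "mRNA": 34, "miRNA": 9}
_DEFAULT_ICC = {"compound": 7, "mRNA": 33, "miRNA": 8}
_TUMOR_CLASSES = ("ICC", "HCC")


def _as_layer_map(value, layers, name: str) -> dict[str, int]:
    if isinstance(value, Mapping):
        unknown = sorted(set(value) - set(layers))
        if unknown:
            raise ValueError(f"{name}: unknown layer(s) {unknown}")
        return {layer: int(value.get(layer, 0)) for layer in layers}
    return {layer: int(value) for layer in layers}


@dataclass
class SyntheticConfig:
    """Generative settings; identical seed + config give bit-identical data."""

    n_samples_per_class: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SAMPLES)
    )
    n_features: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_FEATURES))
    n_planted_tumor: Mapping[str, int] | int = field(
        default_factory=lambda: dict(_DEFAULT_TUMOR)
    )
    n_planted_icc: Mapping[str, int] | int = field(
        default_factory=lambda: dict(_DEFAULT_ICC)
    )
    effect_size_tumor: float = 2.5  # mean log-scale (ln) shift of tumor features
    effect_size_icc: float = 2.0  # base ln shift of ICC features
    icc_contrast_multiplier: float = 1.5  # scales the ICC shift; >= 1
    noise_sd: float = 0.4  # ln-scale SD shared by all features
    baseline_log_mean: float = 6.0  # ln baseline (~400 on the linear scale)
    variance_inflation_sd: float = 0.0  # >0: per-feature lognormal SD multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples_per_class or not self.n_features:
            raise ValueError("sample classes and layers must be non-empty")
        if any(c <= 0 for c in self.n_samples_per_class.values()):
            raise ValueError("all class sample counts must be positive")
        if any(c <= 0 for c in self.n_features.values()):
            raise ValueError("all layer feature counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.icc_contrast_multiplier < 1:
            raise ValueError("icc_contrast_multiplier must be >= 1")
        if self.variance_inflation_sd < 0:
            raise ValueError("variance_inflation_sd must be >= 0")
        layers = list(self.n_features)
        tumor = _as_layer_map(self.n_planted_tumor, layers, "n_planted_tumor")
        icc = _as_layer_map(self.n_planted_icc, layers, "n_planted_icc")
        for layer in layers:
            if tumor[layer] < 0 or icc[layer] < 0:
                raise ValueError("planted counts must be non-negative")
            if tumor[layer] + icc[layer] > self.n_features[layer]:
                raise ValueError(
                    f"layer {layer!r}: planted counts "
                    f"{tumor[layer]}+{icc[layer]} exceed {self.n_features[layer]} features"
                )
        self._tumor_counts = tumor
        self._icc_counts = icc

    @property
    def layers(self) -> list[str]:
        return list(self.n_features)

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_class.values())


@dataclass
class SyntheticDataset:
    """Generated layers, the sample design, and the planted-feature truth."""

    layers: dict[str, OmicsMatrix]
    design: SampleDesign
    truth: dict[str, dict[str, list[str]]]  # layer -> {"tumor": [...], "icc": [...]}
    config: SyntheticConfig

    def truth_union(self, layer: str) -> set[str]:
        t = self.truth[layer]
        return set(t["tumor"]) | set(t["icc"])

    def write(self, run_dir: str | Path, sep: str = "\t") -> Path:
        """Write layer matrices, the design table and the truth lists."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        for name, m in self.layers.items():
            write_matrix(m, run_dir / f"{name}.tsv", sep=sep)
        write_design(self.design, run_dir / "design.tsv", sep=sep)
        (run_dir / "truth.json").write_text(json.dumps(self.truth, indent=2))
        return run_dir


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic cohort from the planted log-normal model."""
    rng = np.random.default_rng(config.seed)

    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    for cls, count in config.n_samples_per_class.items():
        for i in range(1, count + 1):
            sid = f"{cls}_{i:02d}"
            sample_ids.append(sid)
            assignment[sid] = cls
    classes = tuple(config.n_samples_per_class)
    design = SampleDesign(assignment=assignment, classes=classes)
    labels = design.labels(sample_ids)
    is_tumor = np.isin(labels, _TUMOR_CLASSES)
    is_icc = labels == "ICC"
    M = len(sample_ids)

    layers: dict[str, OmicsMatrix] = {}
    truth: dict[str, dict[str, list[str]]] = {}
    for layer in config.layers:
        N = config.n_features[layer]
        width = len(str(N))
        feature_ids = [f"{layer}_{i:0{width}d}" for i in range(1, N + 1)]

        log_values = rng.normal(config.baseline_log_mean, config.noise_sd, (N, M))
        if config.variance_inflation_sd > 0:
            inflation = rng.lognormal(0.0, config.variance_inflation_sd, N)
            centered = log_values - config.baseline_log_mean
            log_values = config.baseline_log_mean + centered * inflation[:, None]

        n_tumor = config._tumor_counts[layer]
        n_icc = config._icc_counts[layer]
        planted = rng.choice(N, size=n_tumor + n_icc, replace=False)
        tumor_idx, icc_idx = planted[:n_tumor], planted[n_tumor:]
        log_values[np.ix_(tumor_idx, np.nonzero(is_tumor)[0])] += (
            config.effect_size_tumor
        )
        log_values[np.ix_(icc_idx, np.nonzero(is_icc)[0])] += (
            config.effect_size_icc * config.icc_contrast_multiplier
        )

        data = pd.DataFrame(
            np.exp(log_values), index=feature_ids, columns=sample_ids
        )
        layers[layer] = OmicsMatrix(layer=layer, data=data)
        truth[layer] = {
            "tumor": sorted(feature_ids[i] for i in tumor_idx),
            "icc": sorted(feature_ids[i] for i in icc_idx),
        }

    return SyntheticDataset(layers=layers, design=design, truth=truth, config=config)


def class_means(
    ds: SyntheticDataset, layer: str, feature: str
) -> dict[str, float]:
    """Arithmetic mean of a feature's linear-scale values per class."""
    if layer not in ds.layers:
        raise KeyError(f"unknown layer {layer!r}; have {list(ds.layers)}")
    m = ds.layers[layer]
    if feature not in m.data.index:
        raise KeyError(f"unknown feature {feature!r} in layer {layer!r}")
    v = m.data.loc[feature]
    labels = ds.design.labels(m.sample_ids)
    return {
        c: float(v.to_numpy()[labels == c].mean()) for c in ds.design.classes
    }
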