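"""Containers and plain-text I/O for omics matrices and sample designs.

A matrix is a feature-by-sample table of positive, vendor-normalized
intensities (mRNA or miRNA probes) or metabolite abundances (compounds).
The canonical on-disk form is tab-delimited text with a header row of
sample identifiers and a first column of feature identifiers; comma is
accepted via ``sep=","``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SampleDesign",
    "DEFAULT_CLASSES",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "align_layers",
    "write_manifest",
]

#: Four-group design of the liver cohort: intrahepatic cholangiocarcinoma,
#: hepatocellular carcinoma, and their matched surrounding non-tumor tissues.
DEFAULT_CLASSES = ("ICC", "ICC_NT", "HCC", "HCC_NT")


@dataclass
class OmicsMatrix:
    """One omics layer: features in rows, samples in columns, linear scale.

    Parameters
    ----------
    layer :
        Layer tag, conventionally ``compound``, ``mRNA`` or ``miRNA``.
    data :
        Feature-by-sample DataFrame; index = feature ids, columns = sample ids.
    symbols :
        Optional feature→gene-symbol mapping. Multiple probes may map to one
        symbol; identifiers stay at the probe/compound level.
    """

    layer: str
    data: pd.DataFrame
    symbols: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError(f"layer {self.layer!r}: empty matrix")
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(
                f"layer {self.layer!r}: duplicate feature identifiers {dup_f}"
            )
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(
                f"layer {self.layer!r}: duplicate sample identifiers {dup_s}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"layer {self.layer!r}: non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = int(np.size(values) - np.sum(np.isfinite(values)))
            raise ValueError(f"layer {self.layer!r}: {bad} non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Feature-by-sample value array (no copy guarantees)."""
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log_transformed(self, base: float = 2.0) -> "OmicsMatrix":
        """Return a log-transformed copy (values must be strictly positive)."""
        if (self.data.to_numpy() <= 0).any():
            raise ValueError(
                f"layer {self.layer!r}: non-positive values cannot be log-transformed"
            )
        return OmicsMatrix(
            layer=self.layer,
            data=np.log(self.data) / np.log(base),
            symbols=self.symbols,
        )

    def subset(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"layer {self.layer!r}: unknown features {missing}")
        return OmicsMatrix(self.layer, self.data.loc[list(feature_ids)], self.symbols)


@dataclass
class SampleDesign:
    """Assignment of each sample to exactly one class.

    The design provides the class indicator delta[a, i] used by the
    categorical regression: 1 if sample i belongs to category a, else 0.
    Every sample has exactly one class, so the indicators sum to one
    per sample by construction.
    """

    assignment: dict[str, str]
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        if not self.assignment:
            raise ValueError("empty sample design")
        unknown = sorted({c for c in self.assignment.values()} - set(self.classes))
        if unknown:
            raise ValueError(
                f"unknown class label(s) {unknown}; expected one of {list(self.classes)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for c in self.assignment.values():
            counts[c] += 1
        return counts

    def labels(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        missing = [s for s in ids if s not in self.assignment]
        if missing:
            raise KeyError(f"samples missing from design: {missing}")
        return np.asarray([self.assignment[s] for s in ids], dtype=object)

    def indicator_matrix(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples-by-classes 0/1 indicator matrix (rows sum to one)."""
        labels = self.labels(sample_ids)
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        delta = pd.DataFrame(0, index=ids, columns=list(self.classes), dtype=float)
        for s, c in zip(ids, labels):
            delta.loc[s, c] = 1.0
        return delta

    def validate_against(self, matrix: OmicsMatrix) -> None:
        """Require the design and a matrix to cover exactly the same samples."""
        design_set = set(self.assignment)
        matrix_set = set(matrix.sample_ids)
        if design_set != matrix_set:
            only_design = sorted(design_set - matrix_set)
            only_matrix = sorted(matrix_set - design_set)
            raise ValueError(
                f"sample mismatch for layer {matrix.layer!r}: "
                f"design-only={only_design}, matrix-only={only_matrix}"
            )


def read_matrix(
    path: str | Path,
    layer: str,
    sep: str = "\t",
    log2: bool = False,
) -> OmicsMatrix:
    """Read a delimited feature-by-sample matrix.

    First row holds sample identifiers, first column feature identifiers,
    the body is numeric. ``log2=True`` applies a log2 transform on read
    (values must be positive); the flag is recorded by the caller's manifest.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty matrix file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric cells in columns {non_numeric}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    m = OmicsMatrix(layer=layer, data=df)
    return m.log_transformed(2.0) if log2 else m


def write_matrix(m: OmicsMatrix, path: str | Path, sep: str = "\t") -> Path:
    """Write a matrix; full float repr so read_matrix round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.data.to_csv(path, sep=sep, index_label="feature_id")
    return path


def read_design(
    path: str | Path,
    sep: str = "\t",
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> SampleDesign:
    """Read a two-column (sample_id, class) design table."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class)")
    sample_col, class_col = df.columns[:2]
    dup = df[sample_col][df[sample_col].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample identifiers {dup}")
    assignment = dict(zip(df[sample_col], df[class_col]))
    return SampleDesign(assignment=assignment, classes=tuple(classes))


def write_design(design: SampleDesign, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"sample_id": design.sample_ids, "class": list(design.assignment.values())}
    ).to_csv(path, sep=sep, index=False)
    return path


def align_layers(
    layers: Sequence[OmicsMatrix], design: SampleDesign
) -> list[OmicsMatrix]:
    """Reorder every layer's columns to the design's canonical sample order.

    All layers must cover exactly the design's sample set; idempotent.
    """
    order = design.sample_ids
    aligned = []
    for m in layers:
        design.validate_against(m)
        aligned.append(OmicsMatrix(m.layer, m.data.loc[:, order], m.symbols))
    return aligned


def write_manifest(
    run_dir: str | Path,
    config: Mapping,
    seed: int | None = None,
    inputs: Mapping[str, str] | None = None,
) -> Path:
    """Write a reproducibility manifest (inputs, config hash, seed, versions)."""
    import pcafe

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "inputs": dict(inputs or {}),
        "versions": {
            "pcafe": pcafe.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
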