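"""Leave-one-out cross-validated three-class tumor diagnosis.

The four design classes collapse onto three diagnostic labels — the two
surrounding non-tumor groups pool into a single "non-tumor" label — and
each sample is predicted from a classifier trained on the remaining 31,
restricted to a selected feature panel.  Per-feature standardization
(and the optional log transform) uses training-fold statistics only, so
no information about the held-out sample leaks into its prediction.
The confusion matrix is reported with rows = predicted, columns = true.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestCentroid

from .matrices import OmicsMatrix, SampleDesign

__all__ = [
    "DEFAULT_CLASS_MAP",
    "DEFAULT_LABEL_ORDER",
    "DiagnosticTask",
    "ClassificationReport",
    "loocv",
    "accuracy_from_confusion",
    "per_class_metrics",
]

DEFAULT_CLASS_MAP: dict[str, str] = {
    "ICC": "ICC",
    "ICC_NT": "non-tumor",
    "HCC": "HCC",
    "HCC_NT": "non-tumor",
}
DEFAULT_LABEL_ORDER = ("non-tumor", "HCC", "ICC")


@dataclass
class DiagnosticTask:
    """Panel, classifier and class collapse for the diagnosis."""

    panel: list[str]
    class_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )
    labels: tuple[str, ...] = DEFAULT_LABEL_ORDER
    classifier: str = "lda"
    log_transform: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("empty feature panel")
        if self.classifier not in ("lda", "nearest_centroid"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        targets = set(self.class_map.values())
        if not targets <= set(self.labels):
            raise ValueError(
                f"class_map targets {sorted(targets)} not all in labels {self.labels}"
            )


@dataclass
class ClassificationReport:
    """LOOCV predictions, confusion matrix and accuracy."""

    sample_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    labels: tuple[str, ...]
    confusion: np.ndarray  # rows = predicted, columns = true
    accuracy: float  # unrounded fraction in [0, 1]

    @property
    def accuracy_percent(self) -> float:
        """Accuracy as a percentage, rounded half-up to 2 decimals."""
        return _round_percent(self.accuracy * 100.0)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.labels, name="predicted"),
            columns=pd.Index(self.labels, name="true"),
        )


def _round_percent(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _make_classifier(name: str, n_labels: int, regularized: bool = False):
    if name == "nearest_centroid":
        return NearestCentroid()
    if regularized:
        return LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto", priors=np.full(n_labels, 1.0 / n_labels)
        )
    return LinearDiscriminantAnalysis(
        solver="svd", priors=np.full(n_labels, 1.0 / n_labels)
    )


def loocv(
    m: OmicsMatrix, design: SampleDesign, task: DiagnosticTask
) -> ClassificationReport:
    """Leave-one-out cross-validation of the diagnostic task on one layer."""
    missing = [f for f in task.panel if f not in m.data.index]
    if missing:
        raise KeyError(f"panel features missing from layer {m.layer!r}: {missing}")
    design.validate_against(m)

    four_class = design.labels(m.sample_ids)
    unmapped = sorted(set(four_class) - set(task.class_map))
    if unmapped:
        raise ValueError(f"class_map does not cover design classes {unmapped}")
    y = np.asarray([task.class_map[c] for c in four_class], dtype=object)

    present = [lab for lab in task.labels if lab in set(y)]
    counts = {lab: int(np.sum(y == lab)) for lab in present}
    too_small = [lab for lab, c in counts.items() if c < 2]
    if too_small:
        raise ValueError(f"need >= 2 samples per diagnostic label; too few: {too_small}")

    X = m.data.loc[task.panel].to_numpy(dtype=float).T  # samples x panel
    if task.log_transform:
        if (X <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        X = np.log(X)

    n = X.shape[0]
    y_pred = np.empty(n, dtype=object)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        X_tr, y_tr = X[train], y[train]
        if set(y_tr) != set(present):  # pragma: no cover - blocked by the >=2 check
            raise ValueError("training fold lost an entire class")
        if task.standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)  # constant features carry no signal
            X_tr = (X_tr - mu) / sd
            X_te = (X[i] - mu) / sd
        else:
            X_te = X[i]
        clf = _make_classifier(task.classifier, len(present))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X_tr, y_tr)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular within-class covariance; falling back to regularized LDA",
                stacklevel=2,
            )
            clf = _make_classifier(task.classifier, len(present), regularized=True)
            clf.fit(X_tr, y_tr)
        y_pred[i] = clf.predict(X_te.reshape(1, -1))[0]

    confusion = _confusion(y_pred, y, task.labels)
    accuracy = float(np.trace(confusion)) / n
    return ClassificationReport(
        sample_ids=m.sample_ids,
        y_true=list(y),
        y_pred=list(y_pred),
        labels=tuple(task.labels),
        confusion=confusion,
        accuracy=accuracy,
    )


def _confusion(
    y_pred: Sequence[str], y_true: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)), dtype=int)
    for p, t in zip(y_pred, y_true):
        c[index[p], index[t]] += 1
    return c


def accuracy_from_confusion(confusion: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Overall accuracy (percent) of a confusion matrix, 2-decimal half-up.

    Orientation does not matter for the accuracy: it is 100 x trace over
    the grand total.  Entries must be non-negative counts.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {c.shape}")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("confusion entries must be non-negative integers")
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix (total = 0)")
    return _round_percent(100.0 * float(np.trace(c)) / float(total))


def per_class_metrics(
    report: ClassificationReport | np.ndarray,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest sensitivity and specificity per diagnostic label.

    Columns are true labels, rows predicted.  A label with zero true
    (resp. zero negative) instances gets an undefined (NaN) sensitivity
    (resp. specificity) rather than 0.
    """
    if isinstance(report, ClassificationReport):
        c = report.confusion
        labels = report.labels
    else:
        c = np.asarray(report, dtype=float)
        if labels is None:
            labels = [f"class_{i}" for i in range(c.shape[0])]
    total = c.sum()
    rows = []
    for i, lab in enumerate(labels):
        tp = c[i, i]
        true_i = c[:, i].sum()
        pred_i = c[i, :].sum()
        tn = total - true_i - pred_i + tp
        fp = pred_i - tp
        sens = tp / true_i if true_i > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows.append({"label": lab, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows).set_index("label")
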