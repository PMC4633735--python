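"""Reference outputs reported for the GSE57555 liver cohort.

These constants document the published analysis outputs for the cohort
the pipeline was designed around (10 ICC and 6 HCC resections with
matched surrounding non-tumor tissue; mRNA and miRNA arrays deposited as
GEO series GSE57555, metabolites by CE-TOFMS).  Reproducing them end to
end requires the deposited array data, the unreleased metabolome table
and the original supplementary thresholds, so they are reference values
for comparison, not package test expectations — with one exception: the
confusion matrices below are complete published count tables, so the
accuracy arithmetic on them is exact and is verified by the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GSE57555_CLASS_COUNTS",
    "GSE57555_SELECTED_PCS",
    "GSE57555_SELECTED_PC_PVALUES",
    "GSE57555_SELECTED_COUNTS",
    "GSE57555_COMPOUND_PANEL_CONFUSION",
    "GSE57555_MIRNA_PANEL_CONFUSION",
    "DIAGNOSTIC_LABELS",
]

#: Samples per design class in the cohort.
GSE57555_CLASS_COUNTS = {"ICC": 10, "ICC_NT": 10, "HCC": 6, "HCC_NT": 6}

#: The coherent cross-layer PC cluster reported for the cohort.
GSE57555_SELECTED_PCS = (
    ("compound", 3),
    ("mRNA", 1),
    ("mRNA", 2),
    ("miRNA", 1),
    ("miRNA", 2),
)

#: Categorical-regression p-values reported for the five selected PCs,
#: in the order of GSE57555_SELECTED_PCS.
GSE57555_SELECTED_PC_PVALUES = (8.68e-03, 1.69e-02, 3.98e-06, 4.74e-02, 9.42e-03)

#: Outlier features reported per layer (62 mRNAs covered by 67 probes).
GSE57555_SELECTED_COUNTS = {
    "compound": 14,
    "mRNA_symbols": 62,
    "mRNA_probes": 67,
    "miRNA": 17,
}

#: Diagnostic label order used by the published confusion matrices.
DIAGNOSTIC_LABELS = ("non-tumor", "HCC", "ICC")

#: LOOCV confusion matrix for the 14-compound panel
#: (rows = predicted, columns = true, label order DIAGNOSTIC_LABELS).
GSE57555_COMPOUND_PANEL_CONFUSION = np.array(
    [
        [14, 0, 2],
        [0, 5, 0],
        [2, 1, 8],
    ]
)

#: LOOCV confusion matrix for the 17-miRNA panel (same orientation).
GSE57555_MIRNA_PANEL_CONFUSION = np.array(
    [
        [13, 1, 1],
        [2, 4, 1],
        [1, 1, 8],
    ]
)
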