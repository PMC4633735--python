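# Methods

This note records the statistical model behind `pcafe`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Feature-space PCA

Given a layer matrix **X** (*N* features × *M* samples), the default
preprocessing subtracts each feature's mean across samples, so that
principal components describe *between-sample* contrast rather than
overall abundance.  The thin SVD **X**<sub>c</sub> = **U S V**ᵀ supplies

* `contributions` — the rows of **V**ᵀ, i.e. the sample-contribution
  vectors *CX*<sup>k</sup>, orthonormal in sample space;
* `feature_scores` — **U S**, feature *i*'s coordinate
  *PCX*<sub>i</sub><sup>k</sup> along component *k*;
* `variance_fraction` — σ<sub>k</sub>² / Σσ², non-increasing.

Row-centering makes **X**<sub>c</sub>·**1** = 0, so every contribution
vector with non-zero singular value has exactly zero mean; Pearson
correlation between same-layer PCs is therefore exactly zero, which the
integration stage asserts on every run.  Centering `"none"` is supported
because vendor-normalized matrices sometimes arrive pre-centered or on
scales where raw decomposition is wanted; the choice is recorded in the
decomposition and in the run manifest.

Sign convention: the SVD leaves each component's sign arbitrary; each
*CX*<sup>k</sup> is oriented so that its largest-magnitude entry is
positive (first such entry on exact ties).  Exactly tied singular values
keep LAPACK's input-order resolution; both conventions exist purely for
determinism.  Degenerate trailing components (zero singular value, e.g.
the mean direction lost to centering) are kept so that *K* = min(*N*,
*M*), but `effective_rank` flags them and they are given |r| = 0 against
everything in the PC tree.

Whether to log-transform before PCA is a data question, not a fixed
rule: vendor-normalized microarray matrices are often already on a log
scale (flag off), while linear-scale abundances with multiplicative
noise — including the synthetic cohorts — should be transformed
(`log_transform=True` on the model, or `log2=True` at read time).  The
flag's state lands in the manifest.

## PC integration

All PCs of all layers are pooled; the dissimilarity between two PCs is
*d* = 1 − |*r*| with *r* the Pearson correlation of their contribution
vectors over the shared, aligned samples.  The absolute value treats a
PC and its sign-flip as the same contrast; the affine shift to [0, 1]
(rather than using −|*r*| directly) preserves UPGMA topology and merge
order while giving a proper dissimilarity.  Spearman correlation is
available behind a flag for monotone-but-nonlinear agreement.

Average-linkage (UPGMA) clustering is delegated to
`scipy.cluster.hierarchy.linkage`; the test suite holds it to a
brute-force average-linkage oracle on all small instances.  The tree cut
and cluster choice formalize two visual criteria — the tightest cluster,
preferring small component indices:

* among flat clusters at `cut_height` (default 0.4) that contain PCs
  from at least `min_layers` (default 2) distinct layers, select the one
  with the largest mean pairwise |*r*|;
* break exact ties toward the smallest sum of component indices, since
  small *k* carries a larger share of variance;
* `max_k` optionally drops high-order PCs before scoring.

The default `cut_height=0.4` sits well below typical chance |r| levels
(for 32-dimensional random directions E|r| ≈ 0.14, i.e. d ≈ 0.86) while
tolerating real attenuation of cross-layer agreement; no cluster
spanning `min_layers` at the cut is an error that reports the nearest
feasible cut height.

Each selected PC is validated by regressing its contributions on the
four class indicators δ<sub>a,i</sub> without an intercept (cell-means
coding): the least-squares coefficients are the class means, and the F
statistic from the comparison with the grand-mean-only model is
algebraically one-way ANOVA.  Categorical coding is used because no
ordering or spacing among the four tissue groups can be assumed.  Two
degenerate cases are defined explicitly: contributions constant across
all samples give F = 0, p = 1 (no separation *and* no variance), and a
perfect fit (zero residual variance with non-zero between-class
variance) reports the p → 0 limit with a warning.

## Outlier feature extraction

Scores along the criterion axes (one or two PCs) are standardized by the
across-feature standard deviation of each axis; the statistic is the sum
of squared standardized scores, so a two-axis criterion is insensitive
to rotations within its plane.  Under the null of no structure the
statistic is approximately χ² with df = number of axes; upper-tail
p-values are adjusted by Benjamini–Hochberg across the layer's features
and kept at adjusted p < α (default 0.01).  Alternatives: a model-free
quantile threshold on the same statistic (`score_quantile`), and robust
standardization by 1.4826·MAD for heavy-tailed score distributions
(plain SD remains the default because it matches the χ² null).
An empty selection is reported, not fatal.

Pattern calls compare two planned contrasts per selected feature on
standardized effect size — tumor (ICC + HCC) vs non-tumor, and ICC vs
the other three groups — naming the larger; a feature with no effect on
either contrast (e.g. constant) is `mixed`.  Probe-to-symbol collapse
de-duplicates selected probes onto gene symbols, preserving
first-occurrence (strongest-probe) order with per-symbol probe counts.

## LOOCV diagnosis

The four design classes collapse onto three diagnostic labels (both
`_NT` groups → `non-tumor`).  For each held-out sample the classifier is
trained on the remaining samples restricted to the panel; the optional
log transform and the per-feature standardization both use training-fold
statistics only, so nothing about the held-out sample leaks into its
prediction.  The default classifier is linear discriminant analysis with
equal priors — the conventional choice for small-*n* microarray LOOCV,
and equal priors keep the rare HCC class from being swamped; a
nearest-centroid classifier is available as a lighter alternative.  A
singular within-class covariance triggers a logged fallback to the
regularized (lsqr + shrinkage) LDA variant.  Accuracy is reported as
100·trace/total, rounded half-up to two decimals for display
(27/32 → 84.38) with the unrounded value retained; the confusion matrix
is printed with rows = predicted and columns = true, and per-class
one-vs-rest sensitivity/specificity leave undefined entries as NaN
rather than 0.

## Synthetic cohorts

The generator emulates a paired liver cohort: 32 samples (10 ICC, 10
ICC_NT, 6 HCC, 6 HCC_NT) × three layers (150 compounds, 5000 mRNA
probes, 300 miRNA probes).  Values are log-normal: background features
are i.i.d. Normal(μ₀ = 6, σ = `noise_sd`) on the natural-log scale and
exponentiated, giving positive, right-skewed, multiplicative data.  Into
disjoint random feature subsets two patterns are planted as additive
log-scale shifts:

* **tumor features** (7 / 34 / 9 per layer): `effect_size_tumor` = 2.5
  added to all 16 tumor samples;
* **ICC features** (7 / 33 / 8): `effect_size_icc` ×
  `icc_contrast_multiplier` = 2.0 × 1.5 = 3.0 added to the 10 ICC
  samples only, so the ICC/ICC_NT separation exceeds the HCC/HCC_NT one
  and the features separate ICC from all three other groups.

Planted counts mirror the scale of the selected panels in the template
cohort (14 compounds, 67 mRNA probes, 17 miRNAs in total).  The shifts
are large (≈ 6–7.5× the log-scale noise, i.e. ~12–20-fold changes)
because the regime is meant to be clearly detectable: in the
5000-feature layer the planted signal eigenvalue must clear the
Marchenko–Pastur noise edge σ²(√N + √M)² for the leading PCs to carry
the planted contrasts at all, and top liver biomarkers (ALB, APOA1 and
the like) genuinely show order-of-magnitude differences.  `noise_sd` =
0.4 corresponds to a typical ±1.5-fold biological/technical variation.
A single shared `noise_sd` is the default; `variance_inflation_sd` > 0
draws a per-feature log-normal SD multiplier for heterogeneous-variance
experiments.

What the generator does **not** emulate: probe-level array artifacts,
background/saturation effects, missing values, within-class biological
substructure (e.g. fibrosis stage), correlated feature blocks beyond the
planted patterns, or paired tumor/non-tumor dependence within a patient.
Passing tests therefore demonstrate that the pipeline recovers planted
multiplicative class structure of realistic magnitude under i.i.d.
log-normal noise — not that it would reproduce any particular real
cohort's selections.

## Problem sizes and determinism

Repeated-cohort checks use 20 generator seeds for recovery (precision,
recall, PC-set identification) and 5 seeds for the global-null
false-positive control; the permutation band for null LOOCV uses 100
label permutations.  These sizes give stable Monte-Carlo estimates for
the quantities asserted while keeping the full suite fast.  Every
stochastic step flows from a single `numpy` Generator seeded in the
config, and identical config + seed reproduces datasets bit-exactly;
matrix round trips through the text formats are bit-exact as well
(`float_precision="round_trip"` on read).

## Known limitations

* The cluster-selection rule formalizes what was originally a visual
  dendrogram judgment; with `cut_height` far from 0.4 the selected set
  can legitimately differ.
* The χ²/BH thresholding assumes approximately normal scores per axis;
  on raw linear-scale data with heavy tails use the log transform or the
  MAD/quantile options.
* With more features than training samples LDA relies on its SVD
  solver's implicit pseudo-inverse; panels much larger than ~number of
  samples deserve the nearest-centroid alternative.
* Layers are analyzed jointly only through PC correlation; no joint
  factorization (e.g. multi-block PCA) is attempted, and panels are
  evaluated per layer, not combined across layers.
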