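import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, pearsonr

from pcafe import (
    MultiOmicsPCA,
    PCDecomposition,
    PCLabel,
    SampleDesign,
    SelectedPCSet,
    build_tree,
    categorical_regression,
    scatter_report,
    select_pcs,
)
from pcafe import decompose

from _oracles import anova_closed_form, upgma_cophenetic
from conftest import random_matrix


def stub_decomp(layer, contributions, centering="none"):
    """PCDecomposition carrying given contribution rows (tests only)."""
    contributions = np.asarray(contributions, dtype=float)
    K, M = contributions.shape
    vf = np.linspace(0.5, 0.1, K)
    return PCDecomposition(
        layer=layer,
        sample_ids=[f"s{j}" for j in range(M)],
        feature_ids=[f"f{i}" for i in range(K)],
        contributions=contributions,
        feature_scores=np.zeros((max(K, 2), K)),
        variance_fraction=vf / vf.sum(),
        singular_values=np.linspace(2.0, 1.0, K),
        centering=centering,
        effective_rank=K,
    )


def zero_mean_orthonormal_basis(m, k, seed=0):
    rng = np.random.default_rng(seed)
    basis = []
    while len(basis) < k:
        v = rng.normal(size=m)
        v -= v.mean()
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return basis


def test_identical_and_anticorrelated_vectors_have_zero_distance():
    e1, e2 = zero_mean_orthonormal_basis(10, 2)
    tree = build_tree(
        [stub_decomp("a", [e1]), stub_decomp("b", [e1]), stub_decomp("c", [-e1])]
    )
    assert tree.distance[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert tree.distance[0, 2] == pytest.approx(0.0, abs=1e-12)  # |r|=1 on sign flip
    assert np.allclose(tree.distance, tree.distance.T)
    assert np.all(np.diag(tree.distance) == 0.0)


def test_hand_executed_upgma_merge_heights():
    """r = (0.9, 0.1, 0.1): merge at 0.1, then join at 1 - (0.1+0.1)/2 = 0.9."""
    e1, e2, e3 = zero_mean_orthonormal_basis(8, 3)
    v1 = e1
    v2 = 0.9 * e1 + np.sqrt(1 - 0.81) * e2
    c = (0.1 - 0.09) / np.sqrt(0.19)
    v3 = 0.1 * e1 + c * e2 + np.sqrt(1 - 0.01 - c**2) * e3
    tree = build_tree(
        [stub_decomp("a", [v1]), stub_decomp("b", [v2]), stub_decomp("c", [v3])]
    )
    np.testing.assert_allclose(tree.merges[:, 2], [0.1, 0.9], atol=1e-10)


@pytest.mark.parametrize("n_pcs", [3, 5, 10])
def test_upgma_matches_bruteforce_oracle(n_pcs):
    rng = np.random.default_rng(n_pcs)
    decomps = [
        stub_decomp(f"layer{i}", [rng.normal(size=12)]) for i in range(n_pcs)
    ]
    tree = build_tree(decomps)
    oracle_coph, oracle_heights = upgma_cophenetic(tree.distance)
    np.testing.assert_allclose(
        squareform(cophenet(tree.merges)), oracle_coph, atol=1e-10
    )
    np.testing.assert_allclose(np.sort(tree.merges[:, 2]), oracle_heights, atol=1e-10)
    assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)  # monotone heights


def test_distance_invariant_to_sign_flip():
    rng = np.random.default_rng(2)
    v, w = rng.normal(size=10), rng.normal(size=10)
    t1 = build_tree([stub_decomp("a", [v]), stub_decomp("b", [w])])
    t2 = build_tree([stub_decomp("a", [v]), stub_decomp("b", [-w])])
    assert t1.distance[0, 1] == pytest.approx(t2.distance[0, 1], abs=1e-12)


def test_within_layer_pcs_are_uncorrelated(toy_matrix):
    tree = build_tree([decompose(toy_matrix)])  # raises if orthonormality broke
    d = tree.distance
    rank = decompose(toy_matrix).effective_rank
    for i in range(rank):
        for j in range(i + 1, rank):
            assert d[i, j] == pytest.approx(1.0, abs=1e-8)  # r == 0


def test_build_tree_rejects_mismatched_sample_orders():
    rng = np.random.default_rng(0)
    d1 = stub_decomp("a", [rng.normal(size=6)])
    d2 = stub_decomp("b", [rng.normal(size=6)])
    d2.sample_ids = list(reversed(d2.sample_ids))
    with pytest.raises(ValueError, match="sample order"):
        build_tree([d1, d2])


def test_spearman_method_available():
    rng = np.random.default_rng(4)
    decomps = [stub_decomp(f"l{i}", [rng.normal(size=10)]) for i in range(3)]
    tree = build_tree(decomps, method="spearman")
    assert tree.distance.shape == (3, 3)
    with pytest.raises(ValueError, match="method"):
        build_tree(decomps, method="kendall")


def test_select_pcs_recovers_planted_cross_layer_cluster(small_dataset, fitted_results):
    selected = fitted_results.selected
    layers = {lab.layer for lab in selected.members}
    assert layers == set(small_dataset.layers)
    # planted structure lives in the two leading PCs of every layer
    assert all(lab.k <= 2 for lab in selected.members)
    assert selected.cluster_mean_abs_r > 0.5


def test_select_pcs_reports_nearest_feasible_cut():
    e = zero_mean_orthonormal_basis(12, 4)
    decomps = [stub_decomp(f"l{i}", [e[i]]) for i in range(4)]  # all r == 0
    tree = build_tree(decomps)
    with pytest.raises(ValueError, match="cut_height"):
        select_pcs(tree, cut_height=0.05, min_layers=2)


def test_select_pcs_max_k_filters_before_scoring():
    e1, e2 = zero_mean_orthonormal_basis(10, 2)
    decomps = [
        stub_decomp("a", [e1]),  # PC1_a
        stub_decomp("b", [e2, e1]),  # PC2_b correlates with PC1_a
    ]
    tree = build_tree(decomps)
    sel = select_pcs(tree, cut_height=0.5, min_layers=2)
    assert set(sel.members) == {PCLabel("a", 1), PCLabel("b", 2)}
    with pytest.raises(ValueError, match="cut_height"):  # PC2_b filtered out
        select_pcs(tree, cut_height=0.5, min_layers=2, max_k=1)


def test_select_pcs_parameter_validation(fitted_results):
    with pytest.raises(ValueError):
        select_pcs(fitted_results.tree, cut_height=1.5)
    with pytest.raises(ValueError):
        select_pcs(fitted_results.tree, cut_height=0.4, min_layers=0)


def test_categorical_regression_constant_contributions(toy_design):
    d = stub_decomp("a", [np.full(8, 1.0 / np.sqrt(8))])
    fit = categorical_regression(d, 1, toy_design)
    assert fit.F_statistic == 0.0
    assert fit.p_value == 1.0


def test_categorical_regression_equals_anova_on_toy_example(toy_design):
    y = np.array([2.1, 1.9, 0.2, 0.1, 1.0, 1.2, 0.4, 0.5])
    d = stub_decomp("a", [y])
    fit = categorical_regression(d, 1, toy_design)
    labels = toy_design.labels(d.sample_ids)
    F, p = anova_closed_form(y, labels)
    assert fit.F_statistic == pytest.approx(F, abs=1e-10)
    assert fit.p_value == pytest.approx(p, abs=1e-10)
    # cell-means coefficients are the class means of the contributions
    for cls in toy_design.classes:
        assert fit.coefficients[cls] == pytest.approx(
            y[labels == cls].mean(), abs=1e-10
        )


@pytest.mark.parametrize("seed", range(10))
def test_categorical_regression_matches_f_oneway(seed, toy_design):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=8)
    d = stub_decomp("a", [y])
    fit = categorical_regression(d, 1, toy_design)
    labels = toy_design.labels(d.sample_ids)
    res = f_oneway(*[y[labels == c] for c in toy_design.classes])
    assert fit.F_statistic == pytest.approx(res.statistic, abs=1e-10)
    assert fit.p_value == pytest.approx(res.pvalue, abs=1e-10)


def test_categorical_regression_requires_all_classes():
    design = SampleDesign({f"s{j}": "ICC" if j < 4 else "HCC" for j in range(8)})
    d = stub_decomp("a", [np.arange(8.0)])
    with pytest.raises(ValueError, match="absent"):
        categorical_regression(d, 1, design)


def test_scatter_report_matches_pearson(toy_matrix):
    d = decompose(toy_matrix)
    selected = SelectedPCSet(
        members=[PCLabel("compound", 1), PCLabel("compound", 2)],
        cluster_mean_abs_r=0.0,
        cut_height=0.4,
    )
    table = scatter_report(selected, [d])
    table = table.set_index(["pc1", "pc2"])
    self_row = table.loc[("PC1_compound", "PC1_compound")]
    assert self_row["r"] == 1.0 and self_row["p_value"] == 0.0
    cross = table.loc[("PC1_compound", "PC2_compound")]
    r_ref, p_ref = pearsonr(d.contribution(1), d.contribution(2))
    assert cross["r"] == pytest.approx(r_ref, abs=1e-10)
    assert cross["p_value"] == pytest.approx(p_ref, abs=1e-8)
    assert abs(cross["r"]) < 1e-8  # same-layer PCs are orthogonal


def test_newick_export_round_trips_labels(fitted_results):
    from io import StringIO

    from skbio import TreeNode

    newick = fitted_results.to_newick()
    tree = TreeNode.read(StringIO(newick))
    tips = {t.name for t in tree.tips()}
    assert f"PC1_compound" in tips
    assert len(tips) == fitted_results.tree.n


# -- property tests --------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        shape=st.tuples(st.integers(2, 6), st.integers(4, 10)),
        elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
    )
)
def test_pc_distance_is_a_bounded_symmetric_dissimilarity(rows):
    decomps = [stub_decomp(f"l{i}", [row]) for i, row in enumerate(rows)]
    tree = build_tree(decomps)
    d = tree.distance
    assert np.all((d >= 0.0) & (d <= 1.0))
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0.0)
    flipped = build_tree(
        [stub_decomp(f"l{i}", [-row if i == 0 else row]) for i, row in enumerate(rows)]
    )
    np.testing.assert_allclose(flipped.distance, d, atol=1e-12)
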