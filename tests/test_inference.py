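"""The 13 estimators: correlation, partial correlation, mutual information."""

import numpy as np
import pandas as pd
import pytest

from rppanet.inference import (
    METHODS,
    MI_METHODS,
    WeightedNetwork,
    estimate_mi,
    fit_method,
    infer_correlation,
    infer_mi_network,
    infer_parcor_inverse,
    infer_parcor_regression,
    rank_edges,
    symmetrize_coefficients,
)
from rppanet.synth import sample_cohorts


def _df(arr, cols):
    return pd.DataFrame(np.asarray(arr, dtype=float), columns=cols)


class TestCorrelation:
    def test_pearson_perfect_linear(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = _df(np.column_stack([a, 2 * a, rng.normal(size=50)]), ["A", "B", "C"])
        net = infer_correlation(X, "pearson")
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.signed

    def test_spearman_monotone_nonlinear(self):
        a = np.linspace(-2, 2, 40)
        X = _df(np.column_stack([a, a**3]), ["A", "B"])
        sp = infer_correlation(X, "spearman")
        pe = infer_correlation(X, "pearson")
        assert sp.weights[0, 1] == pytest.approx(1.0)
        assert pe.weights[0, 1] < 1.0

    def test_matches_textbook_formula(self):
        # independent oracle: the raw covariance/sd definition, looped
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        net = infer_correlation(_df(X, list("ABC")), "pearson")
        for i in range(3):
            for j in range(i + 1, 3):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert net.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected_by_name(self):
        X = _df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], ["Akt", "Src"])
        with pytest.raises(ValueError, match="Src"):
            infer_correlation(X, "pearson")


class TestParcorInverse:
    def test_chain_partial_correlation_vanishes(self, chain_truth):
        study = sample_cohorts(chain_truth, {"X": 4000}, noise_sd=0.0, seed=3)
        X = study.cohorts["X"]
        net = infer_parcor_inverse(X, "simple")
        cor = infer_correlation(X, "pearson")
        assert abs(cor.weights[0, 2]) > 0.1
        assert abs(net.weights[0, 2]) < 0.05

    def test_shrinkage_approaches_simple_for_large_n(self):
        from rppanet.synth import generate_ground_truth

        gt = generate_ground_truth(5, density=0.3, seed=21)
        big = sample_cohorts(gt, {"X": 30000}, noise_sd=0.0, seed=8).cohorts["X"]
        simple = infer_parcor_inverse(big, "simple")
        shrunk = infer_parcor_inverse(big, "shrinkage")
        assert shrunk.params["shrinkage_intensity"] < 0.02
        assert np.max(np.abs(simple.weights - shrunk.weights)) < 1e-3

    def test_glasso_full_penalization_empties_network(self, small_study):
        X = small_study.cohorts["C1"]
        net = infer_parcor_inverse(X, "glasso", rho=10.0)
        assert np.all(net.weights == 0)


class TestParcorRegression:
    def test_ridge_small_penalty_matches_inverse(self, small_study):
        gt = small_study.ground_truth
        X = sample_cohorts(gt, {"X": 3000}, noise_sd=0.0, seed=13).cohorts["X"]
        ridge = infer_parcor_regression(X, "ridge", penalties=(1e-6,), seed=0)
        simple = infer_parcor_inverse(X, "simple")
        assert np.max(np.abs(ridge.weights - simple.weights)) < 1e-2

    def test_lasso_full_penalization_empties_network(self, small_study):
        X = small_study.cohorts["C1"]
        net = infer_parcor_regression(X, "lasso", penalties=(1e4,), seed=0)
        assert np.all(net.weights == 0)

    def test_sign_conflict_rule(self):
        # symmetrization by hand: agreeing signs -> geometric mean, conflict -> 0
        B = np.array([[0.0, 0.4, -0.5], [0.9, 0.0, 0.2], [0.5, 0.3, 0.0]])
        W = symmetrize_coefficients(B)
        assert W[0, 1] == pytest.approx(np.sqrt(0.4 * 0.9))
        assert W[0, 2] == 0.0  # B_13 < 0 but B_31 > 0
        assert W[1, 2] == pytest.approx(np.sqrt(0.2 * 0.3))
        assert np.allclose(W, W.T)

    def test_empty_penalty_grid_rejected(self, small_study):
        with pytest.raises(ValueError):
            infer_parcor_regression(small_study.cohorts["C1"], "ridge", penalties=())


class TestMutualInformation:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        X = _df(rng.normal(size=(2000, 4)), list("ABCD"))
        mi = estimate_mi(X, k_neighbors=3, seed=0)
        off = mi[np.triu_indices(4, k=1)]
        assert off.mean() < 0.05

    def test_functional_dependence_is_maximal(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=300)
        X = _df(np.column_stack([a, a, rng.normal(size=300)]), list("ABC"))
        mi = estimate_mi(X, k_neighbors=3, seed=0)
        assert mi[0, 1] == np.max(mi)

    def test_gaussian_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        mi = estimate_mi(_df(z, ["A", "B"]), k_neighbors=3, seed=0)
        truth = -0.5 * np.log(1 - rho**2)
        assert abs(mi[0, 1] - truth) / truth < 0.25

    def test_constant_column_rejected(self):
        X = _df([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]], ["A", "B"])
        with pytest.raises(ValueError, match="A"):
            estimate_mi(X, k_neighbors=2, seed=0)


class TestMINetworks:
    def test_aracne_prunes_weakest_triangle_edge(self):
        mi = np.array([[0.0, 0.9, 0.3], [0.9, 0.0, 0.8], [0.3, 0.8, 0.0]])
        net = infer_mi_network(mi, "aracne_a", eps=0.0, antibody_ids=list("ABC"))
        assert net.weights[0, 2] == 0.0
        assert net.weights[0, 1] == pytest.approx(0.9)
        assert net.weights[1, 2] == pytest.approx(0.8)

    def test_aracne_tolerance_monotone(self):
        rng = np.random.default_rng(8)
        raw = rng.uniform(0.1, 1.0, size=(8, 8))
        mi = (raw + raw.T) / 2
        np.fill_diagonal(mi, 0.0)
        prev = -1
        for eps in (0.0, 0.05, 0.1, 0.2, 0.5):
            n_edges = np.count_nonzero(
                infer_mi_network(mi, "aracne_a", eps=eps).weights
            )
            assert n_edges >= prev  # larger tolerance prunes less
            prev = n_edges
        # every ARACNE output is a subset of the raw MI support
        net = infer_mi_network(mi, "aracne_m", tau=0.1)
        assert np.all((net.weights > 0) <= (mi > 0))

    def test_clr_flat_matrix_gives_zero(self):
        mi = np.full((4, 4), 0.5)
        np.fill_diagonal(mi, 0.0)
        net = infer_mi_network(mi, "clr")
        # all rows share mean/sd, so no z-score can be positive
        assert np.all(net.weights == 0)

    def test_mrnet_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(0.05, 1.0, size=(4, 4))
        mi = (raw + raw.T) / 2
        np.fill_diagonal(mi, 0.0)

        def oracle_scores(target):
            # explicit forward MRMR selection, written independently
            scores = np.zeros(4)
            remaining = [j for j in range(4) if j != target]
            chosen = []
            while remaining:
                objs = []
                for j in remaining:
                    red = np.mean([mi[j, s] for s in chosen]) if chosen else 0.0
                    objs.append(mi[j, target] - red)
                best = int(np.argmax(objs))
                if chosen and objs[best] <= 0:
                    break
                scores[remaining[best]] = max(0.0, objs[best])
                chosen.append(remaining.pop(best))
            return scores

        expected = np.zeros((4, 4))
        for t in range(4):
            s = oracle_scores(t)
            for j in range(4):
                expected[t, j] = s[j]
        expected = np.maximum(expected, expected.T)
        np.fill_diagonal(expected, 0.0)
        net = infer_mi_network(mi, "mrnet")
        np.testing.assert_allclose(net.weights, expected, atol=1e-12)

    def test_negative_tolerance_rejected(self):
        mi = np.zeros((3, 3))
        with pytest.raises(ValueError):
            infer_mi_network(mi, "aracne_a", eps=-0.1)


class TestRankEdges:
    def test_tie_averaging(self):
        W = np.array([[0.0, 0.9, -0.9], [0.9, 0.0, 0.1], [-0.9, 0.1, 0.0]])
        net = WeightedNetwork(list("ABC"), W, signed=True)
        ranking = rank_edges(net)
        ranks = dict(zip(ranking.pairs, ranking.avg_rank))
        assert ranks[("A", "B")] == ranks[("A", "C")] == 1.5
        assert ranks[("B", "C")] == 3.0

    def test_all_zero_network(self):
        net = WeightedNetwork(list("ABCD"), np.zeros((4, 4)), signed=True)
        ranking = rank_edges(net)
        m = 6
        assert np.all(ranking.avg_rank == (m + 1) / 2)
        # traversal falls back to lexicographic pair order
        assert ranking.ordered_pairs() == sorted(ranking.pairs)

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(10)
        raw = rng.normal(size=(6, 6))
        W = (raw + raw.T) / 2
        np.fill_diagonal(W, 0.0)
        ranking = rank_edges(WeightedNetwork([f"V{i}" for i in range(6)], W, signed=True))
        m = len(ranking.pairs)
        assert ranking.avg_rank.sum() == pytest.approx(m * (m + 1) / 2)


@pytest.mark.parametrize("method", METHODS)
def test_every_method_satisfies_network_invariants(method, small_study):
    """Symmetry, zero diagonal, sign contract — for all 13 estimators."""
    X = small_study.cohorts["C2"].iloc[:120]
    mi = estimate_mi(X, seed=0) if method in MI_METHODS else None
    net = fit_method(method, X, seed=0, mi_matrix=mi)
    assert net.antibody_ids == list(X.columns)
    np.testing.assert_allclose(net.weights, net.weights.T)
    assert np.all(np.diag(net.weights) == 0)
    if not net.signed:
        assert np.all(net.weights >= 0)
    assert net.signed == (method not in MI_METHODS)


def test_correlation_invariant_to_column_transforms(small_study):
    X = small_study.cohorts["C1"]
    affine = X * np.array([2.0] * X.shape[1]) + 5.0
    pe1 = infer_correlation(X, "pearson").weights
    pe2 = infer_correlation(affine, "pearson").weights
    np.testing.assert_allclose(pe1, pe2, atol=1e-12)
    monotone = X.apply(lambda c: np.exp(c))
    sp1 = infer_correlation(X, "spearman").weights
    sp2 = infer_correlation(monotone, "spearman").weights
    np.testing.assert_allclose(sp1, sp2, atol=1e-12)
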