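"""PR curves, limited-recall AUPR, grid optimization, method ranking."""

import numpy as np
import pandas as pd
import pytest

from rppanet.data import GoldStandardNetwork
from rppanet.evaluation import (
    aupr,
    method_similarity,
    optimize_params,
    pr_curve,
    rank_methods,
    top_k_methods,
)
from rppanet.inference import EdgeRanking, WeightedNetwork, rank_edges


def ranking_from_order(pairs_in_order):
    """An EdgeRanking that traverses pairs in exactly the given order."""
    m = len(pairs_in_order)
    canon = sorted(pairs_in_order)
    pos = {p: k for k, p in enumerate(pairs_in_order)}
    avg_rank = np.array([pos[p] + 1 for p in canon], dtype=float)
    order = np.argsort([pos[p] for p in canon])
    return EdgeRanking(pairs=canon, avg_rank=avg_rank, order=np.asarray(order))


class TestPRCurve:
    def test_hand_enumerated_four_pair_toy(self):
        gold = GoldStandardNetwork.from_edges([("A", "B"), ("C", "D")], universe="ABCD")
        ranking = ranking_from_order([("A", "B"), ("A", "C"), ("C", "D"), ("B", "D")])
        curve = pr_curve(ranking, gold)
        np.testing.assert_allclose(curve.precision, [1.0, 0.5, 2 / 3, 0.5])
        np.testing.assert_allclose(curve.recall, [0.5, 0.5, 1.0, 1.0])

    def test_perfect_ranking_holds_precision_one(self):
        gold = GoldStandardNetwork.from_edges([("A", "B"), ("A", "C")], universe="ABC")
        ranking = ranking_from_order([("A", "B"), ("A", "C"), ("B", "C")])
        curve = pr_curve(ranking, gold)
        assert np.all(curve.precision[curve.recall < 1.0] == 1.0)
        assert curve.recall[-1] == 1.0

    def test_final_precision_equals_density(self):
        rng = np.random.default_rng(2)
        ids = [f"V{i}" for i in range(10)]
        raw = rng.normal(size=(10, 10))
        net = WeightedNetwork(ids, (raw + raw.T) / 2 - np.diag(np.diag(raw + raw.T)) / 1, signed=True)
        all_pairs = net.pairs()
        gold_pairs = [all_pairs[k] for k in rng.choice(len(all_pairs), size=9, replace=False)]
        gold = GoldStandardNetwork.from_edges(gold_pairs, universe=ids)
        curve = pr_curve(rank_edges(net), gold)
        assert curve.precision[-1] == pytest.approx(gold.density)

    def test_universe_restriction_ignores_unbenchmarked_antibodies(self):
        gold = GoldStandardNetwork.from_edges([("A", "B")], universe="ABC")
        base = ranking_from_order([("A", "B"), ("A", "C"), ("B", "C")])
        padded = ranking_from_order(
            [("A", "Z"), ("A", "B"), ("A", "C"), ("B", "Z"), ("B", "C"), ("C", "Z")]
        )
        c1, c2 = pr_curve(base, gold), pr_curve(padded, gold)
        np.testing.assert_allclose(c1.precision, c2.precision)
        np.testing.assert_allclose(c1.recall, c2.recall)

    def test_empty_gold_rejected(self):
        ranking = ranking_from_order([("A", "B")])
        with pytest.raises((ValueError, TypeError)):
            pr_curve(ranking, GoldStandardNetwork(pairs=frozenset(), universe=frozenset("AB")))


class TestAUPR:
    def test_perfect_curve_attains_window_bound(self):
        gold = GoldStandardNetwork.from_edges([("A", "B"), ("A", "C")], universe="ABC")
        ranking = ranking_from_order([("A", "B"), ("A", "C"), ("B", "C")])
        curve = pr_curve(ranking, gold)
        assert aupr(curve, 0.1) == pytest.approx(0.1)

    def test_toy_trapezoid_matches_hand_computation(self):
        gold = GoldStandardNetwork.from_edges([("A", "B"), ("C", "D")], universe="ABCD")
        ranking = ranking_from_order([("A", "B"), ("A", "C"), ("C", "D"), ("B", "D")])
        curve = pr_curve(ranking, gold)
        # hand trapezoid over r=(0,.5,.5,1,1), p=(1,1,.5,2/3,.5)
        expected = 0.5 * (1 + 1) / 2 + 0.0 + 0.5 * (0.5 + 2 / 3) / 2 + 0.0
        assert aupr(curve, 1.0) == pytest.approx(expected)

    def test_random_ranking_tracks_gold_density(self):
        rng = np.random.default_rng(3)
        ids = [f"V{i}" for i in range(40)]
        raw = rng.normal(size=(40, 40))
        W = (raw + raw.T) / 2
        np.fill_diagonal(W, 0.0)
        net = WeightedNetwork(ids, W, signed=True)
        pairs = net.pairs()
        density = 0.2
        m_gold = int(density * len(pairs))
        gold_pairs = [pairs[k] for k in rng.choice(len(pairs), size=m_gold, replace=False)]
        gold = GoldStandardNetwork.from_edges(gold_pairs, universe=ids)
        a = aupr(pr_curve(rank_edges(net), gold), 1.0)
        assert abs(a - gold.density) / gold.density < 0.25

    def test_monotone_and_bounded_in_recall_max(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            hits = rng.uniform(size=30) < 0.3
            if hits.sum() == 0:
                hits[0] = True
            tp = np.cumsum(hits)
            curve_r, curve_p = tp / tp[-1], tp / np.arange(1, 31)
            from rppanet.evaluation import PRCurve

            curve = PRCurve(recall=curve_r, precision=curve_p)
            prev = 0.0
            for rmax in (0.05, 0.1, 0.3, 0.6, 1.0):
                a = aupr(curve, rmax)
                assert a <= rmax + 1e-12
                assert a >= prev - 1e-12
                prev = a


class TestOptimizeParams:
    def test_single_point_grid(self, small_study):
        gold = small_study.ground_truth.to_gold_standard()
        X = small_study.cohorts["C1"]
        best, score, (net, _), table = optimize_params("glasso", [{"rho": 0.05}], X, gold)
        assert best == {"rho": 0.05}
        assert len(table) == 1

    def test_grid_prefers_informative_penalty(self, small_study):
        gold = small_study.ground_truth.to_gold_standard()
        X = small_study.cohorts["C1"]
        # rho=10 empties the network entirely; a mild penalty must win
        best, score, _, table = optimize_params(
            "glasso", [{"rho": 10.0}, {"rho": 0.05}], X, gold
        )
        assert best == {"rho": 0.05}
        assert score == table["aupr"].max()

    def test_parameterless_method_evaluated_once(self, small_study):
        gold = small_study.ground_truth.to_gold_standard()
        X = small_study.cohorts["C1"]
        best, score, _, table = optimize_params("pearsoncor", None, X, gold)
        assert best == {}
        assert len(table) == 1
        assert score > 0

    def test_empty_grid_rejected(self, small_study):
        gold = small_study.ground_truth.to_gold_standard()
        with pytest.raises(ValueError):
            optimize_params("glasso", [], small_study.cohorts["C1"], gold)


class TestRankMethods:
    def test_hand_arithmetic_two_by_two(self):
        table = pd.DataFrame([[0.2, 0.3], [0.1, 0.4]], index=["m1", "m2"], columns=["c1", "c2"])
        scores = rank_methods(table)
        assert scores.loc["m1", "overall_aupr"] == pytest.approx(0.5)
        assert scores.loc["m2", "overall_aupr"] == pytest.approx(0.5)
        assert scores.loc["m1", "overall_aupr_rank"] == pytest.approx(3.0)
        assert scores.loc["m2", "overall_aupr_rank"] == pytest.approx(3.0)

    def test_dominant_method_has_minimal_rank_sum(self):
        table = pd.DataFrame(
            [[0.5, 0.6, 0.7], [0.1, 0.2, 0.3], [0.2, 0.1, 0.2]],
            index=["good", "meh", "bad"],
            columns=["c1", "c2", "c3"],
        )
        scores = rank_methods(table)
        assert scores.loc["good", "overall_aupr_rank"] == 3.0

    def test_cohort_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.uniform(size=(4, 5)), index=list("wxyz"))
        s1 = rank_methods(table)
        s2 = rank_methods(table[table.columns[::-1]])
        pd.testing.assert_series_equal(s1["overall_aupr"], s2["overall_aupr"])
        pd.testing.assert_series_equal(s1["overall_aupr_rank"], s2["overall_aupr_rank"])

    def test_top_k_by_both_criteria(self):
        table = pd.DataFrame(
            [[0.5, 0.5], [0.4, 0.4], [0.3, 0.3], [0.1, 0.1]],
            index=["a", "b", "c", "d"],
        )
        assert set(top_k_methods(rank_methods(table), k=2)) == {"a", "b"}


class TestMethodSimilarity:
    def test_duplicate_vectors_correlate_perfectly(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=20)
        stacked = pd.DataFrame([v, v, rng.normal(size=20)], index=["m1", "m2", "m3"])
        spearman, _, explained, _ = method_similarity(stacked)
        assert spearman.loc["m1", "m2"] == pytest.approx(1.0)
        assert explained.sum() == pytest.approx(1.0)

    def test_matches_rank_correlation_oracle(self):
        stacked = pd.DataFrame(
            [[0.9, 0.1, 0.5, 0.3], [0.8, 0.2, 0.6, 0.1], [0.1, 0.9, 0.2, 0.7]],
            index=["m1", "m2", "m3"],
        )
        spearman, _, _, _ = method_similarity(stacked)
        from scipy.stats import rankdata

        for a in range(3):
            for b in range(3):
                ra = rankdata(stacked.iloc[a])
                rb = rankdata(stacked.iloc[b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert spearman.iloc[a, b] == pytest.approx(expected)

    def test_constant_vector_warns_and_zeroes(self):
        stacked = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.2, 0.5, 0.1], [0.3, 0.1, 0.9]],
            index=["flat", "m2", "m3"],
        )
        with pytest.warns(UserWarning):
            spearman, _, _, _ = method_similarity(stacked)
        assert spearman.loc["flat", "m2"] == 0.0
        assert spearman.loc["flat", "flat"] == 1.0
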