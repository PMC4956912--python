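"""Rank aggregation: ranking, consistency, weight solving, consensus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kolrank.aggregate import (
    RankedList,
    aggregate_rankings,
    borda_baseline,
    consistency,
    mean_ranking,
    rank_by_feature,
    solve_weights,
    top_k,
)
from kolrank.features import FeatureMatrix


def matrix_from(values, category="c"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FeatureMatrix(
        category_id=category,
        doctor_ids=[f"d{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(m)],
        values=values,
    )


def grid_search_weights(sigmas, step=0.001):
    """Exhaustive minimization of J(w) = sum w_i^2 sigma_i on the simplex."""
    sigmas = np.asarray(sigmas, dtype=float)
    m = len(sigmas)
    ticks = np.arange(0, 1 + step / 2, step)
    best, best_j = None, np.inf
    if m == 1:
        return np.array([1.0])
    if m == 2:
        grid = np.stack([ticks, 1 - ticks], axis=1)
    else:
        w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
        keep = w1 + w2 <= 1 + 1e-12
        grid = np.stack([w1[keep], w2[keep], 1 - w1[keep] - w2[keep]], axis=1)
    j = (grid**2 * sigmas).sum(axis=1)
    return grid[np.argmin(j)]


class TestRankByFeature:
    def test_descending_order(self):
        rl = rank_by_feature(matrix_from([[3.2], [1.1], [2.0]]), 0)
        assert [rl.ranks[d] for d in ["d0", "d1", "d2"]] == [1, 3, 2]

    def test_average_rank_ties(self):
        rl = rank_by_feature(matrix_from([[5.0], [5.0], [1.0]]), 0)
        assert [rl.ranks[d] for d in ["d0", "d1", "d2"]] == [1.5, 1.5, 3]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=12))
    def test_rank_sum_invariant(self, scores):
        rl = rank_by_feature(matrix_from([[s] for s in scores]), 0)
        n = len(scores)
        assert sum(rl.ranks.values()) == pytest.approx(n * (n + 1) / 2)

    def test_invalid_rank_assignment_rejected(self):
        with pytest.raises(ValueError):
            RankedList(doctor_ids=["a", "b"], ranks={"a": 1.0, "b": 1.0})


class TestMeanRanking:
    def test_identical_lists(self):
        rl = rank_by_feature(matrix_from([[3.0], [2.0], [1.0]]), 0)
        mean = mean_ranking([rl, rl], [0.3, 0.7])
        assert mean == pytest.approx(rl.ranks)

    def test_two_opposite_lists_uniform(self):
        m = matrix_from([[1.0, 2.0], [2.0, 1.0]])
        lists = [rank_by_feature(m, 0), rank_by_feature(m, 1)]
        mean = mean_ranking(lists, [0.5, 0.5])
        assert mean == {"d0": 1.5, "d1": 1.5}

    def test_degenerate_weight_selects_single_list(self):
        m = matrix_from([[1.0, 2.0], [2.0, 1.0]])
        lists = [rank_by_feature(m, 0), rank_by_feature(m, 1)]
        assert mean_ranking(lists, [1.0, 0.0]) == lists[0].ranks

    def test_doctor_set_mismatch_rejected(self):
        a = rank_by_feature(matrix_from([[1.0], [2.0]]), 0)
        b = RankedList(doctor_ids=["x"], ranks={"x": 1.0})
        with pytest.raises(ValueError):
            mean_ranking([a, b], [0.5, 0.5])


class TestConsistency:
    def test_identical_to_mean_is_zero(self):
        rl = rank_by_feature(matrix_from([[3.0], [2.0], [1.0]]), 0)
        assert consistency(rl, rl.ranks) == 0.0

    def test_hand_computed_reversal(self):
        rl = RankedList(doctor_ids=["a", "b", "c"], ranks={"a": 1, "b": 2, "c": 3})
        mean = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert consistency(rl, mean) == pytest.approx(8 / 3)

    def test_relabel_invariance(self):
        rl1 = RankedList(doctor_ids=["a", "b"], ranks={"a": 1, "b": 2})
        rl2 = RankedList(doctor_ids=["x", "y"], ranks={"x": 1, "y": 2})
        assert consistency(rl1, {"a": 2.0, "b": 1.0}) == consistency(
            rl2, {"x": 2.0, "y": 1.0}
        )


class TestSolveWeights:
    def test_symmetric_sigmas(self):
        assert np.allclose(solve_weights([1, 1, 1]), [1 / 3] * 3)

    def test_inverse_sigma_rule(self):
        assert np.allclose(solve_weights([1, 2]), [2 / 3, 1 / 3])

    def test_single_feature(self):
        assert np.allclose(solve_weights([7.0]), [1.0])

    def test_zero_sigma_takes_all_mass(self):
        assert np.allclose(solve_weights([0.0, 5.0]), [1.0, 0.0])
        assert np.allclose(solve_weights([0.0, 0.0, 5.0]), [0.5, 0.5, 0.0])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            solve_weights([-1.0, 2.0])

    @pytest.mark.parametrize(
        "sigmas", [[1.0, 2.0], [0.5, 0.5, 2.0], [3.0, 1.0, 0.2], [1.0]]
    )
    def test_matches_grid_search(self, sigmas):
        closed = solve_weights(sigmas)
        grid = grid_search_weights(sigmas)
        assert np.max(np.abs(closed - grid)) < 2e-3

    def test_projected_gradient_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(2, 9))
            sig = rng.uniform(0.05, 5.0, m)
            cf = solve_weights(sig, "closed_form")
            pg = solve_weights(sig, "projected_gradient")
            assert np.max(np.abs(cf - pg)) < 1e-6


class TestAggregateRankings:
    def test_unanimous_features_give_uniform_weights(self):
        col = np.array([[3.0], [2.0], [1.0]])
        res = aggregate_rankings(matrix_from(np.hstack([col, 2 * col, col + 1])))
        assert np.allclose(res.weights, 1 / 3)
        assert res.final_ranking.doctor_ids == ["d0", "d1", "d2"]
        assert res.converged and res.iterations == 1

    def test_single_doctor(self):
        res = aggregate_rankings(matrix_from([[0.0, 0.0]]))
        assert res.final_ranking.ranks == {"d0": 1.0}
        assert np.allclose(res.weights, 0.5)

    def test_outvoted_reversal_gets_smallest_weight(self):
        """Two features agree with a planted order, the third reverses it:
        the reversal earns the strictly smallest weight and the planted
        order wins."""
        planted = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        m = matrix_from(np.stack([planted, planted * 2, -planted], axis=1))
        res = aggregate_rankings(m)
        assert res.weights[2] < res.weights[0]
        assert res.weights[2] < res.weights[1]
        assert res.final_ranking.doctor_ids == [f"d{i}" for i in range(5)]

    def test_weight_sigma_monotonicity(self, default_corpus):
        from kolrank.pipeline import rank_category

        corpus, _ = default_corpus
        res = rank_category(corpus, corpus.category_ids[0])
        order = np.argsort(res.sigmas)
        sorted_weights = res.weights[order]
        assert all(np.diff(sorted_weights) <= 1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 3))
        m = matrix_from(values)
        perm = rng.permutation(6)
        m2 = FeatureMatrix(
            category_id="c",
            doctor_ids=[m.doctor_ids[i] for i in perm],
            feature_names=m.feature_names,
            values=values[perm],
        )
        r1, r2 = aggregate_rankings(m), aggregate_rankings(m2)
        assert np.allclose(r1.weights, r2.weights)
        assert r1.final_ranking.ranks == r2.final_ranking.ranks
        assert r1.final_ranking.doctor_ids == r2.final_ranking.doctor_ids

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rankings(matrix_from(np.empty((0, 2))))


class TestTopK:
    def test_full_list_and_argmax(self):
        m = matrix_from([[1.0], [3.0], [2.0]])
        res = aggregate_rankings(m)
        assert top_k(res, 3) == ["d1", "d2", "d0"]
        assert top_k(res, 1) == ["d1"]
        assert top_k(res, 10) == ["d1", "d2", "d0"]

    def test_k_must_be_positive(self):
        res = aggregate_rankings(matrix_from([[1.0]]))
        with pytest.raises(ValueError):
            top_k(res, 0)


class TestBordaBaseline:
    def test_matches_aggregate_when_sigmas_equal(self):
        col = np.array([[3.0], [2.0], [1.0]])
        m = matrix_from(np.hstack([col, col]))
        assert borda_baseline(m).ranks == aggregate_rankings(m).final_ranking.ranks

    def test_opposite_lists_tie(self):
        m = matrix_from(np.stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], axis=1))
        rl = borda_baseline(m)
        assert set(rl.ranks.values()) == {2.0}

    def test_matches_mean_rank_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(7, 4))
        m = matrix_from(values)
        rl = borda_baseline(m)
        from scipy.stats import rankdata

        mean_ranks = np.mean(
            [rankdata(-values[:, j]) for j in range(4)], axis=0
        )
        expected = rankdata(mean_ranks)
        assert np.allclose([rl.ranks[f"d{i}"] for i in range(7)], expected)


class TestNoiseRejection:
    def test_aggregate_beats_median_feature(self):
        """Noisy quality copies plus pure-noise columns: the weighted
        consensus tracks the planted order better than the median single
        feature in nearly all replicates."""
        from scipy.stats import kendalltau

        rng = np.random.default_rng(0)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            q = rng.beta(2, 2, size=80)
            cols = [q + 0.2 * rng.standard_normal(80) for _ in range(3)]
            cols += [rng.standard_normal(80) for _ in range(2)]
            from kolrank.features import znormalize

            m = znormalize(matrix_from(np.stack(cols, axis=1)))
            res = aggregate_rankings(m)
            taus = []
            for j in range(5):
                taus.append(kendalltau(m.values[:, j], q).statistic)
            agg_tau = kendalltau(
                [-res.final_ranking.ranks[d] for d in m.doctor_ids], q
            ).statistic
            wins += agg_tau > np.median(taus)
        assert wins >= int(0.9 * n_rep)
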