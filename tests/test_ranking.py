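import numpy as np
import pytest

from serorank import FeatureTable, LabelAssignment, build_affinity, normalize
from serorank.graph import NormalizedGraph, estimate_sigma, pairwise_distances
from serorank.ranking import (
    RankingParams,
    rank_closed_form,
    rank_iterative,
    rank_universal,
    tune_alpha,
)
from .conftest import labels_for, random_affinity


def norm_graph(seed=0, n=10):
    return normalize(random_affinity(n, seed))


def empty_graph(n=5):
    return NormalizedGraph(np.zeros((n, n)), None)


class TestParams:
    @pytest.mark.parametrize("alpha", [-0.1, 1.0, 1.5])
    def test_alpha_range_enforced(self, alpha):
        with pytest.raises(ValueError):
            RankingParams(alpha=alpha)

    def test_closed_form_result_flags(self):
        g = norm_graph()
        y = np.zeros(10)
        y[0] = 1.0
        res = rank_closed_form(g, y)
        assert res.converged and res.iterations == 0


class TestIterative:
    def test_alpha_zero_returns_y(self):
        g = norm_graph()
        y = np.zeros(10)
        y[3] = 1.0
        res = rank_iterative(g, y, RankingParams(alpha=0.0))
        np.testing.assert_allclose(res.scores, y)
        assert res.order[0] == 3

    def test_zero_evidence_stays_zero(self):
        g = norm_graph()
        res = rank_iterative(g, np.zeros(10))
        assert not res.scores.any()

    def test_path_graph_scores_decay_with_distance(self):
        # 1-D points 0,1,2: evidence at node 0 decays along the path
        t = FeatureTable(("a", "b", "c"), np.array([[0.0], [1.0], [2.0]]))
        D = pairwise_distances(t)
        g = normalize(build_affinity(D, estimate_sigma(D)))
        y = np.array([1.0, 0.0, 0.0])
        res = rank_iterative(g, y, RankingParams(alpha=0.5))
        assert res.scores[0] > res.scores[1] > res.scores[2]
        closed = rank_closed_form(g, y, RankingParams(alpha=0.5))
        np.testing.assert_allclose(res.scores, closed.scores, atol=1e-8)

    def test_nonconvergence_is_flagged(self):
        g = norm_graph()
        y = np.ones(10)
        res = rank_iterative(g, y, RankingParams(alpha=0.9, max_iter=2, tol=1e-15))
        assert not res.converged and res.iterations == 2

    def test_geometric_residual_decay(self):
        """The update is a contraction with ratio at most alpha."""
        g = norm_graph(seed=4, n=15)
        y = np.zeros(15)
        y[0] = 1.0
        a = 0.7
        f = y.copy()
        prev_delta = None
        for _ in range(30):
            f_next = a * (g.L @ f) + (1 - a) * y
            # 2-norm: the spectral bound ||L||_2 <= 1 gives the contraction
            delta = np.linalg.norm(f_next - f)
            if prev_delta is not None and prev_delta > 1e-14:
                assert delta <= a * prev_delta + 1e-12
            prev_delta = delta
            f = f_next


class TestClosedForm:
    def test_alpha_zero_identity(self):
        g = norm_graph()
        y = np.arange(10.0)
        np.testing.assert_allclose(
            rank_closed_form(g, y, RankingParams(alpha=0.0)).scores, y
        )

    def test_empty_graph_scales_y(self):
        y = np.array([3.0, 1.0, 2.0, 0.0, 5.0])
        res = rank_closed_form(empty_graph(), y, RankingParams(alpha=0.4))
        np.testing.assert_allclose(res.scores, 0.6 * y)
        assert res.order.tolist() == np.argsort(-y, kind="stable").tolist()

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_agrees_with_long_iteration(self, alpha):
        g = norm_graph(seed=30, n=30)
        y = np.zeros(30)
        y[[2, 17]] = 1.0
        params = RankingParams(alpha=alpha, tol=1e-13, max_iter=5000)
        np.testing.assert_allclose(
            rank_closed_form(g, y, params).scores,
            rank_iterative(g, y, params).scores,
            atol=1e-8,
        )

    def test_order_invariant_to_positive_scaling(self):
        g = norm_graph(seed=7)
        y = np.zeros(10)
        y[5] = 1.0
        res = rank_closed_form(g, y, RankingParams(alpha=0.5))
        # dropping the (1 - alpha) factor rescales scores but not the order
        rescaled = res.scores / 0.5
        assert np.argsort(-rescaled, kind="stable").tolist() == res.order.tolist()

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_evidence(self, seed):
        """Adding a positive never lowers any score: (I - aL)^-1 >= 0."""
        g = norm_graph(seed=seed, n=12)
        y1 = np.zeros(12)
        y1[0] = 1.0
        y2 = y1.copy()
        y2[6] = 1.0
        f1 = rank_closed_form(g, y1).scores
        f2 = rank_closed_form(g, y2).scores
        assert (f2 - f1 >= -1e-12).all()


class TestUniversal:
    def setup_method(self):
        self.g = norm_graph(seed=3, n=8)
        self.y_plus = np.zeros(8)
        self.y_plus[0] = 1.0
        self.y_minus = np.zeros(8)
        self.y_minus[5] = -1.0

    def test_gamma_zero_reproduces_positive_only_bitwise(self):
        uni = rank_universal(self.g, self.y_plus, self.y_minus, RankingParams(gamma=0.0))
        pos = rank_closed_form(self.g, self.y_plus)
        assert (uni.scores == pos.scores).all()

    def test_empty_negatives_reproduce_positive_only_bitwise(self):
        uni = rank_universal(self.g, self.y_plus, np.zeros(8), RankingParams(gamma=0.7))
        pos = rank_closed_form(self.g, self.y_plus)
        assert (uni.scores == pos.scores).all()

    def test_matches_combined_linear_solve(self):
        params = RankingParams(gamma=1.0, alpha=0.5)
        uni = rank_universal(self.g, self.y_plus, self.y_minus, params)
        A = np.eye(8) - 0.5 * self.g.L
        expect = 0.5 * np.linalg.solve(A, self.y_plus + self.y_minus)
        np.testing.assert_allclose(uni.scores, expect, atol=1e-12)

    def test_known_negative_scores_lowest_contribution(self):
        params = RankingParams(gamma=1.0)
        uni = rank_universal(self.g, self.y_plus, self.y_minus, params)
        pos = rank_closed_form(self.g, self.y_plus)
        diff = uni.scores - pos.scores
        assert diff.argmin() == 5

    def test_overlapping_supports_rejected(self):
        y_minus = np.zeros(8)
        y_minus[0] = -1.0
        with pytest.raises(ValueError, match="disjoint"):
            rank_universal(self.g, self.y_plus, y_minus)


class TestTuneAlpha:
    def make_data(self, seed=0):
        from serorank.synthetic import SyntheticSpec, generate

        t, lab, truth = generate(
            SyntheticSpec(m=5, n_query=12, n_hidden_pos=0, n_neg=40, seed=seed)
        )
        return t, lab

    def test_single_grid_value(self):
        t, lab = self.make_data()
        best, table = tune_alpha(t, lab, grid=[0.5], folds=4)
        assert best == 0.5 and set(table) == {0.5}

    def test_returns_argmax_of_recorded_table(self):
        t, lab = self.make_data(seed=2)
        best, table = tune_alpha(t, lab, grid=[0.2, 0.5, 0.8], folds=4, seed=1)
        assert table[best] == max(table.values())

    def test_too_few_positives_for_folds(self):
        t, lab = self.make_data()
        with pytest.raises(ValueError, match="folds"):
            tune_alpha(t, lab, folds=50)
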