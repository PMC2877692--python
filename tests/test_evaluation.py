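import numpy as np
import pytest

from serorank import FeatureTable
from serorank.evaluation import (
    METHODS,
    nearest_distance_ranker,
    pr_curve,
    run_benchmark,
    svm_ranker,
)
from serorank.prefilter import nearest_positive_distance
from .conftest import labels_for, random_table


class TestPRCurve:
    def test_perfect_ranking(self):
        auc = pr_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])).auc
        assert auc == 1.0

    def test_single_positive_ranked_last(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        truth = np.array([0, 0, 0, 0, 1])
        assert pr_curve(scores, truth).auc == pytest.approx(1 / 5)

    def test_hand_worked_four_samples(self):
        curve = pr_curve(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0]))
        assert curve.auc == pytest.approx((1 / 1 + 2 / 3) / 2)  # = 5/6
        np.testing.assert_allclose(curve.recall, [0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(curve.precision, [1.0, 0.5, 2 / 3, 0.5])

    def test_recall_non_decreasing_and_bounds(self):
        rng = np.random.default_rng(0)
        curve = pr_curve(rng.standard_normal(50), rng.integers(0, 2, 50))
        assert (np.diff(curve.recall) >= 0).all()
        assert (curve.precision >= 0).all() and (curve.precision <= 1).all()
        assert 0 < curve.auc <= 1

    def test_exclusion_removes_queries(self):
        scores = np.array([10.0, 0.5, 0.4])
        truth = np.array([1, 1, 0])
        # excluding the top-scoring query leaves one positive at rank 1
        assert pr_curve(scores, truth, exclude=[0]).auc == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(40)
        truth = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        a1 = pr_curve(scores, truth).auc
        a2 = pr_curve(scores[perm], truth[perm]).auc
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(11)
        scores = rng.standard_normal(100)  # continuous, no ties
        truth = rng.integers(0, 2, 100)
        assert pr_curve(scores, truth).auc == pytest.approx(
            average_precision_score(truth, scores)
        )

    def test_random_scores_auc_matches_exact_expectation(self):
        """Random rankings average the closed-form expected AP, which sits
        slightly above the prevalence at finite n."""
        N, P = 100, 20
        rng = np.random.default_rng(17)
        truth = np.zeros(N, dtype=int)
        truth[:P] = 1
        aucs = [pr_curve(rng.standard_normal(N), truth).auc for _ in range(60)]
        H = np.sum(1.0 / np.arange(1, N + 1))
        expected = H / N * (1 - (P - 1) / (N - 1)) + (P - 1) / (N - 1)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert expected > P / N  # the finite-sample excess is positive
        assert abs(np.mean(aucs) - expected) < 3 * se


class TestRankers:
    def separable(self, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 0.3, (15, 3))
        neg = rng.normal(4, 0.3, (60, 3))
        X = np.vstack([pos, neg])
        t = FeatureTable(tuple(f"s{i}" for i in range(75)), X)
        labels = labels_for(t, range(5))  # 5 queries among the positives
        truth = np.zeros(75, dtype=int)
        truth[:15] = 1
        return t, labels, truth

    def test_nearest_matches_prefilter_distances(self):
        t, labels, _ = self.separable()
        np.testing.assert_array_equal(
            nearest_distance_ranker(t, labels),
            -nearest_positive_distance(t, labels),
        )

    def test_binary_svm_separates_toy(self):
        from serorank import LabelAssignment

        t, _, truth = self.separable()
        pos = np.zeros(t.n, dtype=bool)
        pos[:5] = True
        neg = ~truth.astype(bool)  # known negatives available for training
        labels = LabelAssignment(t.n, pos, neg)
        scores = svm_ranker(t, labels, strategy="binary", seed=0)
        auc = pr_curve(scores, truth, exclude=np.flatnonzero(pos)).auc
        assert auc == 1.0

    def test_one_class_svm_prefers_cluster_members(self):
        t, labels, truth = self.separable()
        scores = svm_ranker(t, labels, strategy="one_class")
        hidden = truth.astype(bool) & ~labels.positive
        assert scores[hidden].min() > scores[~truth.astype(bool)].max()

    def test_svm_deterministic_given_seed(self):
        t, labels, _ = self.separable()
        s1 = svm_ranker(t, labels, strategy="binary", seed=5)
        s2 = svm_ranker(t, labels, strategy="binary", seed=5)
        np.testing.assert_array_equal(s1, s2)

    def test_one_class_needs_two_queries(self):
        t, labels, _ = self.separable()
        solo = labels_for(t, [0])
        with pytest.raises(ValueError, match="2"):
            svm_ranker(t, solo, strategy="one_class")


class TestBenchmark:
    def data(self):
        t = random_table(60, 4, seed=21)
        labels = labels_for(t, range(12))
        return t, labels

    def test_report_shape_and_means(self):
        t, labels = self.data()
        rep = run_benchmark(t, labels, [3, 5], repeats=2, methods=["nearest"], seed=4)
        assert len(rep.results) == 4  # 2 sizes x 2 repeats x 1 method
        summary = rep.summary
        for _, row in summary.iterrows():
            cells = rep.results[
                (rep.results.query_size == row.query_size)
                & (rep.results.method == row.method)
            ].auc
            assert row.mean_auc == pytest.approx(cells.mean())

    def test_single_repeat_mean_is_value(self):
        t, labels = self.data()
        rep = run_benchmark(t, labels, [4], repeats=1, methods=["nearest"], seed=0)
        assert rep.summary.mean_auc.iloc[0] == rep.results.auc.iloc[0]

    def test_deterministic_given_seed(self):
        t, labels = self.data()
        r1 = run_benchmark(t, labels, [3], 2, ["manifold", "nearest"], seed=9)
        r2 = run_benchmark(t, labels, [3], 2, ["manifold", "nearest"], seed=9)
        assert r1.results.equals(r2.results)

    def test_unknown_method_lists_registry(self):
        t, labels = self.data()
        with pytest.raises(ValueError, match="registered"):
            run_benchmark(t, labels, [3], 1, ["nope"], seed=0)

    def test_query_size_exceeding_positives_rejected(self):
        t, labels = self.data()
        with pytest.raises(ValueError, match="exceeds"):
            run_benchmark(t, labels, [200], 1, ["nearest"], seed=0)

    def test_all_registered_methods_run(self):
        t, labels = self.data()
        rep = run_benchmark(t, labels, [5], 1, list(METHODS), seed=2)
        assert set(rep.results.method) == set(METHODS)
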