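"""Max-min seeding, Lloyd's k-means, severity ordering, summaries."""

import itertools

import numpy as np
import pytest

from depclust import (
    adjusted_rand,
    kmeans_fit,
    maxmin_init,
    severity_labels,
    severity_map,
    summarize_clusters,
    total_scores,
)
from depclust.cluster import ClusterModel
from tests.conftest import make_matrix


def _col(values):
    """1-D data as an (n, 1) float array."""
    return np.asarray(values, dtype=float).reshape(-1, 1)


class TestMaxMinInit:
    def test_hand_enumerated_1d_example(self):
        # anchor (0); farthest is 10; then min-distances are 5 for point 5
        # and 2 for point 2, so 5 is the third center
        centers = maxmin_init(_col([0, 10, 5, 2]), k=3)
        np.testing.assert_array_equal(centers.ravel(), [0, 10, 5])

    def test_k2_is_anchor_plus_farthest_point(self):
        X = _col([0, 3, 9, 4])
        centers = maxmin_init(X, k=2)
        np.testing.assert_array_equal(centers.ravel(), [0, 9])

    def test_anchor_used_even_when_absent_from_data(self):
        centers = maxmin_init(_col([5, 9, 7]), k=2)
        assert centers[0, 0] == 0.0

    def test_ties_break_to_lowest_row_index(self):
        X = np.array([[0.0, 5.0], [5.0, 0.0], [0.0, 0.0]])
        centers = maxmin_init(X, k=2)
        np.testing.assert_array_equal(centers[1], [0.0, 5.0])

    def test_too_few_points_or_duplicates_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            maxmin_init(_col([0, 1]), k=3)
        with pytest.raises(ValueError, match="distinct"):
            maxmin_init(_col([0, 7, 7]), k=3)


class TestKMeansFit:
    def test_mass_points_converge_immediately_with_zero_sse(self):
        X = _col([1, 1, 8, 8, 8])
        model = kmeans_fit(X, init=np.array([[1.0], [8.0]]))
        assert model.converged
        assert model.n_iterations == 1
        assert model.sse == 0.0

    def test_hand_iterated_1d_example(self):
        model = kmeans_fit(_col([0, 1, 9, 10]), init=np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(np.sort(model.centers.ravel()), [0.5, 9.5])
        assert model.sse == pytest.approx(1.0)
        assert model.converged

    def test_sse_history_is_non_increasing(self, paper_like_dataset):
        X = paper_like_dataset.responses.values[:1500]
        model = kmeans_fit(X, maxmin_init(X, 4))
        hist = model.sse_history
        assert all(b <= a + 1e-8 for a, b in zip(hist, hist[1:]))

    def test_fit_is_deterministic(self, well_sep_dataset):
        X = well_sep_dataset.responses
        m1 = kmeans_fit(X, maxmin_init(X, 4))
        m2 = kmeans_fit(X, maxmin_init(X, 4))
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_array_equal(m1.centers, m2.centers)

    def test_empty_cluster_keeps_previous_center(self):
        # center at 10 captures nothing; it must survive unchanged
        model = kmeans_fit(_col([0, 1]), init=np.array([[10.0], [0.0]]))
        assert 10.0 in model.centers.ravel()
        assert np.all(model.labels == 1)

    def test_duplicate_init_centers_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_fit(_col([0, 1, 2]), init=np.array([[1.0], [1.0]]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exhaustive_two_partition_oracle(self, seed):
        """No 2-partition of a tiny point set beats the fitted SSE by
        more than numerical noise, and on a separated toy they agree."""
        rng = np.random.default_rng(seed)
        n = 8
        X = rng.integers(0, 4, size=(n, 2)).astype(float)
        if len(np.unique(X, axis=0)) < 2:
            pytest.skip("degenerate draw")
        model = kmeans_fit(X, maxmin_init(X, 2))

        best = np.inf
        for assignment in itertools.product([0, 1], repeat=n):
            a = np.asarray(assignment)
            if a.min() == a.max():
                continue
            sse = sum(
                ((X[a == c] - X[a == c].mean(axis=0)) ** 2).sum()
                for c in (0, 1)
            )
            best = min(best, sse)
        assert best <= model.sse + 1e-9

    def test_oracle_agreement_on_separated_toy(self):
        X = np.array([[0, 0], [0, 1], [9, 9], [9, 8]], dtype=float)
        model = kmeans_fit(X, maxmin_init(X, 2))
        assert model.sse == pytest.approx(1.0)  # 0.5 within each pair


class TestSeverityOrdering:
    def _model(self, center_totals):
        centers = np.asarray(center_totals, dtype=float).reshape(-1, 1)
        return ClusterModel(
            centers=centers, labels=np.zeros(1, dtype=int),
            severity_order=np.arange(len(center_totals)),
            n_iterations=1, converged=True, sse=0.0,
        )

    def test_printed_center_totals_map_to_ordered_levels(self):
        order = severity_map(self._model([7.84, 1.47, 18.7, 11.27]))
        np.testing.assert_array_equal(order, [1, 0, 3, 2])

    def test_sorted_centers_give_identity(self):
        order = severity_map(self._model([1.0, 5.0, 9.0]))
        np.testing.assert_array_equal(order, [0, 1, 2])

    def test_equal_totals_tie_to_lower_index(self):
        order = severity_map(self._model([5.0, 5.0]))
        np.testing.assert_array_equal(order, [0, 1])


class TestSummaryAndRecovery:
    def test_counts_partition_the_sample(self, paper_like_dataset):
        X = paper_like_dataset.responses
        model = kmeans_fit(X, maxmin_init(X, 4))
        summary = summarize_clusters(model, X)
        assert summary.counts.sum() == X.n_respondents
        for rec in summary.to_records():
            assert rec["score_min"] <= rec["score_max"]

    def test_well_separated_ranges_do_not_overlap(self, well_sep_dataset):
        X = well_sep_dataset.responses
        model = kmeans_fit(X, maxmin_init(X, 4))
        summary = summarize_clusters(model, X)
        for (_, hi), (lo, _) in zip(summary.score_ranges, summary.score_ranges[1:]):
            assert hi < lo

    def test_recovery_of_well_separated_classes(self, well_sep_dataset):
        X = well_sep_dataset.responses
        model = kmeans_fit(X, maxmin_init(X, 4))
        ari = adjusted_rand(severity_labels(model), well_sep_dataset.true_class)
        assert ari >= 0.95

    def test_severity_levels_increase_with_total_score(self, well_sep_dataset):
        X = well_sep_dataset.responses
        model = kmeans_fit(X, maxmin_init(X, 4))
        sev = severity_labels(model)
        means = [total_scores(X)[sev == s].mean() for s in range(4)]
        assert means == sorted(means)
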