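"""Linear discriminant, cross-validation, balancing, robustness, curves."""

import numpy as np
import pytest

from depclust import (
    crossval,
    kmeans_fit,
    lda_fit,
    lda_predict,
    learning_curve,
    maxmin_init,
    robustness,
    severity_labels,
    undersample,
)


def _blobs(seed=0, n=60, gap=8.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 0.5, size=(n, 2)),
        rng.normal(gap, 0.5, size=(n, 2)),
    ])
    y = np.repeat([0, 1], n)
    return X, y


def _four_class_grid(seed=0, n_per=80):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    X = np.vstack([rng.normal(c, 0.4, size=(n_per, 2)) for c in centers])
    return X, np.repeat(np.arange(4), n_per)


class TestLDA:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = _blobs()
        clf = lda_fit(X, y)
        pred, _ = lda_predict(clf, X)
        assert np.mean(pred == y) == 1.0

    def test_class_swapped_duplicates_score_chance(self):
        X, y = _blobs(n=30)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, 1 - y])
        clf = lda_fit(X2, y2)
        pred, _ = lda_predict(clf, X2)
        assert np.mean(pred == y2) == pytest.approx(0.5)

    def test_refitting_gives_identical_predictions(self):
        X, y = _four_class_grid()
        p1 = lda_predict(lda_fit(X, y), X)
        p2 = lda_predict(lda_fit(X, y), X)
        np.testing.assert_array_equal(p1[0], p2[0])
        np.testing.assert_array_equal(p1[1], p2[1])

    def test_probabilities_sum_to_one(self):
        X, y = _four_class_grid()
        _, proba = lda_predict(lda_fit(X, y), X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_midpoint_between_symmetric_classes_splits_evenly(self):
        X = np.array([[-1, 0], [-1, 1], [-1, -1], [1, 0], [1, 1], [1, -1]],
                     dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        _, proba = lda_predict(lda_fit(X, y), np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(proba[0], [0.5, 0.5], atol=1e-9)

    def test_single_class_and_dimension_mismatch_rejected(self):
        X, y = _blobs()
        with pytest.raises(ValueError, match="2 classes"):
            lda_fit(X, np.zeros_like(y))
        clf = lda_fit(X, y)
        with pytest.raises(ValueError, match="item count mismatch"):
            lda_predict(clf, np.zeros((3, 5)))


class TestCrossval:
    def test_separable_four_class_metrics_near_one(self):
        X, y = _four_class_grid(n_per=60)
        report = crossval(X, y, folds=5, seed=0)
        assert report.accuracy >= 0.99
        assert report.auc_macro >= 0.99
        assert all(v >= 0.99 for v in report.sensitivity.values())

    def test_seeded_determinism(self, well_sep_dataset):
        X = well_sep_dataset.responses
        y = well_sep_dataset.true_class
        r1 = crossval(X, y, folds=5, seed=3)
        r2 = crossval(X, y, folds=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_class_smaller_than_folds_rejected(self):
        X, y = _four_class_grid(n_per=4)
        with pytest.raises(ValueError, match="folds"):
            crossval(X, y, folds=10)

    def test_accuracy_matches_per_fold_confusion_diagonal(self):
        X, y = _four_class_grid(n_per=40)
        report = crossval(X, y, folds=4, seed=1)
        assert report.accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in report.per_fold])
        )


class TestUndersample:
    def test_all_classes_shrink_to_smallest(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2, 3], [400, 250, 70, 50])
        X = rng.normal(size=(len(y), 3))
        _, yb, idx = undersample(X, y, seed=5)
        assert np.all(np.bincount(yb) == 50)
        assert np.all(np.diff(idx) > 0)  # original order preserved

    def test_balanced_input_is_a_permutation_equivalent(self):
        y = np.repeat([0, 1], 20)
        X = np.arange(40, dtype=float).reshape(-1, 1)
        Xb, yb, _ = undersample(X, y, seed=0)
        np.testing.assert_array_equal(np.sort(Xb.ravel()), X.ravel())
        np.testing.assert_array_equal(np.bincount(yb), [20, 20])

    def test_seeded_determinism(self):
        y = np.repeat([0, 1, 2], [30, 20, 10])
        X = np.random.default_rng(1).normal(size=(60, 2))
        idx1 = undersample(X, y, seed=9)[2]
        idx2 = undersample(X, y, seed=9)[2]
        np.testing.assert_array_equal(idx1, idx2)


class TestRobustness:
    def test_degenerate_full_sample_replicate_scores_one(self, well_sep_dataset):
        X = well_sep_dataset.responses
        report = robustness(X, reps=1, train_fraction=1.0, seed=0)
        assert report.ari_values[0] == pytest.approx(1.0)

    def test_well_separated_fixture_is_stable(self, well_sep_dataset):
        X = well_sep_dataset.responses
        report = robustness(X, reps=30, seed=2)
        assert report.ari_mean >= 0.95
        assert report.n_failed == 0
        assert report.ari_mean == pytest.approx(report.ari_values.mean())

    def test_seeded_determinism(self, well_sep_dataset):
        X = well_sep_dataset.responses.values[:500]
        r1 = robustness(X, reps=5, seed=4)
        r2 = robustness(X, reps=5, seed=4)
        np.testing.assert_array_equal(r1.ari_values, r2.ari_values)

    def test_zero_reps_rejected(self, well_sep_dataset):
        with pytest.raises(ValueError):
            robustness(well_sep_dataset.responses, reps=0)


class TestLearningCurve:
    def test_one_record_per_feasible_size(self):
        X, y = _four_class_grid(n_per=60)
        curve = learning_curve(X, y, train_sizes=(0.2, 0.5, 1.0),
                               folds=3, seed=0)
        assert list(curve["train_size"]) == [0.2, 0.5, 1.0]

    def test_separable_data_learns_with_small_generalization_gap(self):
        X, y = _four_class_grid(n_per=80)
        curve = learning_curve(X, y, train_sizes=(0.5, 1.0), folds=3, seed=1)
        last = curve.iloc[-1]
        assert last["train_accuracy"] >= 0.95
        assert last["test_accuracy"] >= 0.95
        assert abs(last["train_accuracy"] - last["test_accuracy"]) <= 0.05

    def test_infeasible_sizes_warn_and_are_skipped(self):
        X, y = _four_class_grid(n_per=6)
        with pytest.warns(UserWarning):
            curve = learning_curve(X, y, train_sizes=(0.01, 1.0),
                                   folds=2, seed=0)
        assert 0.01 not in set(curve.get("train_size", []))
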