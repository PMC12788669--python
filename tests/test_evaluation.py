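"""Fold construction, multiclass metrics, and the CV harness."""

import numpy as np
import pytest

from dbmca.evaluation import compute_metrics, make_folds, run_cv


class TestFolds:
    def test_partition_ten_into_five(self):
        labels = [0, 1] * 5
        fa = make_folds(labels, k=5, seed=0)
        sizes = [len(fa.test_indices(f)) for f in range(5)]
        assert sizes == [2] * 5
        all_idx = np.sort(np.concatenate([fa.test_indices(f) for f in range(5)]))
        assert np.array_equal(all_idx, np.arange(10))

    def test_stratification_exact_on_balanced_labels(self):
        # 3 balanced classes, n=30, k=5 -> every fold holds 2 of each class
        labels = np.repeat([0, 1, 2], 10)
        fa = make_folds(labels, k=5, seed=3)
        for f in range(5):
            te = fa.test_indices(f)
            counts = np.bincount(np.asarray(labels)[te], minlength=3)
            assert list(counts) == [2, 2, 2]

    def test_same_seed_same_assignment(self):
        labels = np.arange(40) % 4
        a = make_folds(labels, k=5, seed=9)
        b = make_folds(labels, k=5, seed=9)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds([0, 1, 0], k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 2, 3, 4, 5]
        rep = compute_metrics(y, y)
        assert rep.accuracy == rep.f1 == rep.recall == rep.precision == 1.0

    def test_hand_enumerated_three_class_example(self):
        # confusion matrix worked by hand:
        # class0: P=1/2 R=1/2; class1: P=2/3 R=1; class2: P=1 R=1/2
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 2, 0]
        rep = compute_metrics(y_true, y_pred, n_classes=3)
        assert rep.accuracy == pytest.approx(2 / 3, abs=1e-12)
        assert rep.precision == pytest.approx(0.7222, abs=1e-4)
        assert rep.recall == pytest.approx(0.6667, abs=1e-4)
        assert rep.f1 == pytest.approx(0.6556, abs=1e-4)

    def test_constant_prediction_on_balanced_binary(self):
        # all-one-class prediction: acc 0.5; macro F1 = (2/3 + 0)/2
        y_true = [0, 0, 1, 1]
        y_pred = [0, 0, 0, 0]
        rep = compute_metrics(y_true, y_pred, n_classes=2)
        assert rep.accuracy == 0.5
        assert rep.f1 == pytest.approx(1 / 3, abs=1e-12)

    def test_confusion_matrix_row_sums_are_support(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 6, 120)
        y_pred = rng.integers(0, 6, 120)
        rep = compute_metrics(y_true, y_pred)
        assert np.array_equal(rep.confusion.sum(axis=1),
                              np.bincount(y_true, minlength=6))
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 120)

    def test_macro_recall_equals_accuracy_on_balanced_symmetric_errors(self):
        # balanced truth, one symmetric error per class
        y_true = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        y_pred = [0, 0, 1, 1, 1, 2, 2, 2, 0]
        rep = compute_metrics(y_true, y_pred, n_classes=3)
        assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


class TestRunCv:
    def _constant_fit_predict(self, value=0):
        def _run(_model, tr, te, labels):
            return np.full(len(te), value, dtype=np.int64)

        return _run

    def test_constant_model_scores_one_sixth_on_balanced_labels(self):
        rng = np.random.default_rng(1)
        labels = rng.permutation(np.repeat(np.arange(6), 60))
        res = run_cv(np.zeros((360, 2)), labels,
                     fit_predict=self._constant_fit_predict(0), k=5, seed=0)
        # binomial error band around 1/6 with n=72 per fold
        for acc in res.fold_accuracies:
            assert abs(acc - 1 / 6) < 3 * np.sqrt((1 / 6) * (5 / 6) / 72)

    def test_exactly_k_reports_and_summary_is_arithmetic_mean(self):
        labels = np.arange(50) % 5
        res = run_cv(np.zeros((50, 1)), labels,
                     fit_predict=self._constant_fit_predict(1), k=5, seed=2)
        assert len(res.fold_reports) == 5
        assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))
        assert res.min_accuracy <= res.mean_accuracy <= res.max_accuracy

    def test_determinism_end_to_end(self):
        labels = np.arange(60) % 6

        def noisy_fit_predict(_model, tr, te, labels_):
            rng = np.random.default_rng(len(tr))  # depends only on fold shape
            return rng.integers(0, 6, len(te))

        a = run_cv(np.zeros((60, 1)), labels, fit_predict=noisy_fit_predict, k=5, seed=4)
        b = run_cv(np.zeros((60, 1)), labels, fit_predict=noisy_fit_predict, k=5, seed=4)
        assert a.fold_accuracies == b.fold_accuracies

    def test_leakage_is_asserted(self):
        labels = np.arange(20) % 2
        seen = {}

        def spy(_model, tr, te, labels_):
            assert len(np.intersect1d(tr, te)) == 0
            seen.setdefault("folds", []).append(te)
            return labels_[te]  # perfect predictions

        res = run_cv(np.zeros((20, 1)), labels, fit_predict=spy, k=5, seed=0)
        assert res.mean_accuracy == 1.0
        assert len(seen["folds"]) == 5
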