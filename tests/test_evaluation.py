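"""Classifier presets, confusion matrices, per-class metrics, CV protocols."""

import numpy as np
import pytest

from fundusfuse import confusion_matrix, evaluate_protocol, make_classifier, per_class_metrics
from fundusfuse.evaluation import ALL_PRESETS


def brute_force_metrics(y_true, y_pred, c):
    """Independent per-pair counting of TP/FN/FP/TN for class c."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
    sen = 100 * tp / (tp + fn) if tp + fn else 0.0
    spe = 100 * tn / (fp + tn) if fp + tn else 0.0
    pre = 100 * tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return sen, spe, pre, f1


def separable_features(n_per_class=10, t=5, seed=0):
    """Every column carries the class signal, so per-column standardization
    (applied inside every preset) preserves separability."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(t), n_per_class)
    x = y[:, None] + rng.normal(0, 0.05, (y.size, 4))
    return x, y


class TestPresets:
    def test_fine_knn_is_one_nearest_neighbor(self):
        assert make_classifier("fine-knn").params["n_neighbors"] == 1

    def test_quadratic_svm_is_degree_two_polynomial(self):
        spec = make_classifier("quadratic-svm")
        assert spec.params["kernel"] == "poly" and spec.params["degree"] == 2

    def test_preset_set_is_closed(self):
        with pytest.raises(ValueError, match="linear-svm"):
            make_classifier("linear-qda")

    @pytest.mark.parametrize("preset", ALL_PRESETS)
    def test_every_preset_builds_and_fits(self, preset):
        x, y = separable_features(n_per_class=8)
        spec = make_classifier(preset)
        rep = evaluate_protocol(x, y, spec, "holdout:0.3", seed=0)
        assert 0 <= rep.overall_acc <= 100


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        cm = confusion_matrix(y, y, 3)
        assert np.array_equal(np.diag(cm.counts), [2, 1, 3]) and cm.counts.sum() == 6

    def test_single_off_diagonal_entry(self):
        cm = confusion_matrix([2], [4], 5)
        assert cm.counts[2, 4] == 1 and cm.total == 1

    def test_total_conserved_on_random_vectors(self, rng):
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        cm = confusion_matrix(y_true, y_pred, 5)
        assert cm.total == 200
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(y_true, minlength=5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)


class TestPerClassMetrics:
    def test_perfect_diagonal_gives_all_hundreds(self):
        cm = confusion_matrix([0, 1, 2, 3, 4] * 3, [0, 1, 2, 3, 4] * 3, 5)
        for c in range(5):
            assert per_class_metrics(cm, c) == (100.0, 100.0, 100.0, 100.0)

    def test_binary_handworked_example(self):
        # TP=3, FN=1, FP=2, TN=4 for class 1
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        cm = confusion_matrix(y_true, y_pred, 2)
        sen, spe, pre, f1 = per_class_metrics(cm, 1)
        assert sen == pytest.approx(75.0)
        assert spe == pytest.approx(66.6667, abs=1e-3)
        assert pre == pytest.approx(60.0)
        assert f1 == pytest.approx(66.6667, abs=1e-3)

    def test_no_predicted_positives_warns_and_zeroes_precision(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 0, 0, 0], 2)
        with pytest.warns(UserWarning, match="predicted"):
            _, _, pre, _ = per_class_metrics(cm, 1)
        assert pre == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 4, 80)
        y_pred = rng.integers(0, 4, 80)
        cm = confusion_matrix(y_true, y_pred, 4)
        for c in range(4):
            if (y_pred == c).sum() == 0:
                continue
            assert per_class_metrics(cm, c) == pytest.approx(brute_force_metrics(y_true, y_pred, c))


class TestProtocols:
    def test_separable_data_reaches_perfect_accuracy(self):
        x, y = separable_features()
        for preset in ("linear-svm", "fine-knn", "medium-knn"):
            rep = evaluate_protocol(x, y, make_classifier(preset), "kfold:5", seed=0)
            assert rep.overall_acc == 100.0

    def test_fold_assignment_is_seeded_and_partitions_data(self):
        x, y = separable_features()
        a = evaluate_protocol(x, y, make_classifier("fine-knn"), "kfold:5", seed=7)
        b = evaluate_protocol(x, y, make_classifier("fine-knn"), "kfold:5", seed=7)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert sorted(np.unique(a.fold_assignment)) == [0, 1, 2, 3, 4]
        # stratification: every fold holds the same number per class
        for fold in range(5):
            assert np.bincount(y[a.fold_assignment == fold], minlength=5).tolist() == [2] * 5

    def test_macro_sensitivity_equals_accuracy_on_balanced_data(self):
        """With equal class supports, mean per-class recall equals overall
        accuracy: ACC = sum TP_c / (t*n) = mean(TP_c / n) = macro SEN."""
        rng = np.random.default_rng(3)
        y = np.repeat(np.arange(5), 20)
        y_pred = rng.integers(0, 5, y.size)
        cm = confusion_matrix(y, y_pred, 5)
        sens = [per_class_metrics(cm, c)[0] for c in range(5)]
        acc = 100 * np.trace(cm.counts) / cm.total
        assert np.mean(sens) == pytest.approx(acc)

    def test_holdout_report_includes_wall_time(self):
        x, y = separable_features()
        rep = evaluate_protocol(x, y, make_classifier("linear-svm"), "holdout:0.30", seed=0)
        assert rep.protocol == "holdout:0.3" and rep.wall_time > 0
        assert rep.cm.total == 15  # 30% of 50, stratified

    def test_too_many_folds_rejected(self):
        x, y = separable_features(n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            evaluate_protocol(x, y, make_classifier("fine-knn"), "kfold:5", seed=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_protocol(np.zeros((6, 2)), np.zeros(6, dtype=int), make_classifier("fine-knn"))
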