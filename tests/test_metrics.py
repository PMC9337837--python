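"""ACC, per-class recall, covariance-form multiclass MCC, and CV machinery.

The central equivalence: the covariance-form MCC over one-hot indicator
matrices equals the confusion-matrix R_K closed form — asserted numerically
over random confusion tables against an independently coded formula, and
against the classical binary MCC on 2x2 tables.
"""

import itertools
import math

import numpy as np
import pytest

from cinorigin.io_formats import ExpressionMatrix, LabelVector
from cinorigin.learners import MajorityLearner
from cinorigin.metrics import (
    ConfusionMatrix,
    accuracy,
    confusion_matrix,
    cross_validate,
    evaluate_predictions,
    individual_accuracy,
    mcc_multiclass,
    repeated_cv,
)


def rk_from_confusion(C: np.ndarray) -> float:
    """Independently coded closed-form multiclass R_K from confusion counts."""
    C = np.asarray(C, dtype=float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # true-class counts
    p = C.sum(axis=0)  # predicted-class counts
    num = c * s - float(t @ p)
    den = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    return num / den if den > 0 else 0.0


def labels_from_confusion(C: np.ndarray) -> tuple[list, list]:
    y_true, y_pred = [], []
    for i, j in itertools.product(range(C.shape[0]), range(C.shape[1])):
        y_true += [f"k{i}"] * int(C[i, j])
        y_pred += [f"k{j}"] * int(C[i, j])
    return y_true, y_pred


class TestAccuracies:
    def test_diagonal_only_is_one(self):
        cm = ConfusionMatrix(["a", "b"], [[5, 0], [0, 7]])
        assert accuracy(cm) == 1.0

    def test_zero_diagonal_is_zero(self):
        cm = ConfusionMatrix(["a", "b"], [[0, 5], [7, 0]])
        assert accuracy(cm) == 0.0

    def test_seventy_of_hundred(self):
        cm = ConfusionMatrix(["a", "b"], [[50, 10], [20, 20]])
        assert accuracy(cm) == pytest.approx(0.7)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(["a"], [[0]]))

    @pytest.mark.parametrize(
        "row,expected", [((20, 0), 1.0), ((0, 7), 0.0), ((19, 1), 0.95)]
    )
    def test_individual_accuracy_is_per_class_recall(self, row, expected):
        cm = ConfusionMatrix(["a", "b"], [list(row), [0, 1]])
        assert individual_accuracy(cm, "a") == pytest.approx(expected)

    def test_empty_class_reported_missing_not_zero(self):
        cm = ConfusionMatrix(["a", "b"], [[0, 0], [1, 1]])
        assert individual_accuracy(cm, "a") is None

    def test_report_fields_consistent_with_confusion(self):
        rng = np.random.default_rng(11)
        y_true = [f"k{v}" for v in rng.integers(0, 3, 200)]
        y_pred = [f"k{v}" for v in rng.integers(0, 3, 200)]
        rep = evaluate_predictions(y_true, y_pred)
        assert rep.acc == pytest.approx(accuracy(rep.confusion))
        for c in rep.confusion.classes:
            assert rep.individual_accuracy[c] == pytest.approx(
                individual_accuracy(rep.confusion, c)
            )


class TestMccMulticlass:
    def test_perfect_prediction_is_one(self):
        y = ["a", "b", "c", "a", "b", "c"]
        assert mcc_multiclass(y, y) == pytest.approx(1.0)

    def test_constant_predictor_zero_by_fallback(self):
        assert mcc_multiclass(["a", "b", "a"], ["a", "a", "a"]) == 0.0

    def test_matches_rk_closed_form_on_random_3class_tables(self):
        """1,000 random 3x3 confusion matrices: |covariance form - R_K| < 1e-12."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            C = rng.integers(0, 20, size=(3, 3))
            if C.sum() < 2 or C.sum(axis=0).max() == C.sum() or C.sum(axis=1).max() == C.sum():
                continue  # degenerate: constant truth or predictions
            y_true, y_pred = labels_from_confusion(C)
            assert abs(mcc_multiclass(y_true, y_pred) - rk_from_confusion(C)) < 1e-12
            checked += 1

    def test_matches_classical_binary_mcc_on_random_2x2_tables(self):
        """1,000 random 2x2 tables: equals (TP*TN - FP*FN)/sqrt(...)."""
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 1000:
            tp, fn, fp, tn = (int(v) for v in rng.integers(0, 30, size=4))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom == 0 or tp + fn + fp + tn < 2:
                continue
            binary = (tp * tn - fp * fn) / math.sqrt(denom)
            y_true, y_pred = labels_from_confusion(np.array([[tp, fn], [fp, tn]]))
            assert mcc_multiclass(y_true, y_pred) == pytest.approx(binary, abs=1e-12)
            checked += 1

    def test_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(3)
        y_true = [f"k{v}" for v in rng.integers(0, 3, 100)]
        y_pred = [f"k{v}" for v in rng.integers(0, 3, 100)]
        rename = {"k0": "zz", "k1": "aa", "k2": "mm"}
        assert mcc_multiclass(y_true, y_pred) == pytest.approx(
            mcc_multiclass([rename[v] for v in y_true], [rename[v] for v in y_pred]),
            abs=1e-12,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcc_multiclass(["a"], ["a", "b"])


class _SingleFeatureOracle:
    """Memorises the deterministic label function of the first feature."""

    def fit(self, matrix, labels):
        self.lut = {v: c for v, c in zip(matrix.values[:, 0], labels.classes)}
        return self

    def predict(self, matrix):
        return [self.lut[v] for v in matrix.values[:, 0]]


def _feature_coded_dataset(n_per_class=20):
    """One feature whose value encodes the class exactly."""
    classes = ["A", "B", "C"]
    y = [c for c in classes for _ in range(n_per_class)]
    x = np.array([[float(classes.index(c))] for c in y])
    cells = [f"c{i}" for i in range(len(y))]
    return ExpressionMatrix(cells, ["g"], x), LabelVector(cells, y)


class TestCrossValidation:
    def test_majority_stub_recalls(self):
        matrix, labels = _feature_coded_dataset(n_per_class=10)
        # make A the majority class
        matrix = ExpressionMatrix(
            matrix.cell_ids + ["extra1", "extra2"],
            matrix.gene_ids,
            np.vstack([matrix.values, [[0.0]], [[0.0]]]),
        )
        labels = LabelVector(matrix.cell_ids, labels.classes + ["A", "A"])
        rep = cross_validate(matrix, labels, MajorityLearner(), folds=5, seed=0)
        assert rep.individual_accuracy["A"] == 1.0
        assert rep.individual_accuracy["B"] == 0.0
        assert rep.individual_accuracy["C"] == 0.0

    def test_feature_oracle_reaches_perfect_accuracy(self):
        matrix, labels = _feature_coded_dataset()
        rep = cross_validate(matrix, labels, _SingleFeatureOracle(), folds=10, seed=1)
        assert rep.acc == 1.0 and rep.mcc == pytest.approx(1.0)

    def test_leave_one_out_equals_per_sample_loop(self):
        """folds=n (unstratified) reproduces a brute-force per-sample loop."""
        rng = np.random.default_rng(7)
        n = 20
        cells = [f"c{i}" for i in range(n)]
        X = rng.random((n, 3))
        y = ["A" if v < 0.5 else "B" for v in rng.random(n)]
        matrix, labels = ExpressionMatrix(cells, ["g1", "g2", "g3"], X), LabelVector(cells, y)

        from sklearn.neighbors import KNeighborsClassifier

        class OneNN:
            def fit(self, m, l):
                self.m = KNeighborsClassifier(1).fit(m.values, l.classes)
                return self

            def predict(self, m):
                return [str(p) for p in self.m.predict(m.values)]

        rep = cross_validate(matrix, labels, OneNN(), folds=n, stratified=False, seed=0)
        # oracle: explicit per-sample loop
        preds = []
        for i in range(n):
            rest = [j for j in range(n) if j != i]
            model = KNeighborsClassifier(1).fit(X[rest], [y[j] for j in rest])
            preds.append(str(model.predict(X[i : i + 1])[0]))
        expect = evaluate_predictions(y, preds, classes=labels.class_order())
        assert np.array_equal(rep.confusion.counts, expect.confusion.counts)
        assert rep.acc == expect.acc and rep.mcc == pytest.approx(expect.mcc)

    def test_small_class_error_names_class(self):
        matrix, labels = _feature_coded_dataset(n_per_class=5)
        with pytest.raises(ValueError, match="'A'"):
            cross_validate(matrix, labels, MajorityLearner(), folds=6)

    def test_deterministic_given_seed(self):
        matrix, labels = _feature_coded_dataset()
        a = cross_validate(matrix, labels, _SingleFeatureOracle(), folds=5, seed=3)
        b = cross_validate(matrix, labels, _SingleFeatureOracle(), folds=5, seed=3)
        assert np.array_equal(a.confusion.counts, b.confusion.counts)


class TestRepeatedCV:
    def test_times_one_equals_cross_validate(self):
        matrix, labels = _feature_coded_dataset()
        rep = repeated_cv(matrix, labels, _SingleFeatureOracle(), folds=5, times=1, base_seed=4)
        single = cross_validate(matrix, labels, _SingleFeatureOracle(), folds=5, seed=4)
        assert rep.accs == [single.acc] and rep.mccs == [single.mcc]

    def test_identical_seeds_identical_repeats(self):
        matrix, labels = _feature_coded_dataset()
        a = repeated_cv(matrix, labels, _SingleFeatureOracle(), folds=5, times=3, base_seed=0)
        b = repeated_cv(matrix, labels, _SingleFeatureOracle(), folds=5, times=3, base_seed=0)
        assert a.accs == b.accs and a.mccs == b.mccs

    def test_summary_min_median_max(self):
        matrix, labels = _feature_coded_dataset()
        rep = repeated_cv(matrix, labels, _SingleFeatureOracle(), folds=5, times=3, base_seed=0)
        s = rep.summary()
        assert s["mcc"]["min"] <= s["mcc"]["median"] <= s["mcc"]["max"]
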