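"""Evaluation metrics and cross-validation.

The headline statistic is the multiclass Matthews correlation coefficient in
its covariance form: encode true and predicted labels as n x K one-hot
indicator matrices X and Y, define cov(A, B) as the sum over the K columns of
the per-column sample covariances, and report

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)).

This equals the Gorodkin R_K statistic computed from the confusion matrix;
the equivalence is asserted numerically in the test suite rather than
assumed. When either variance term vanishes (e.g. a constant predictor) the
statistic is defined as 0 so that feature-selection curves stay well-defined.

Cross-validation is stratified: within each class, cells are shuffled by a
seeded RNG and dealt round-robin to folds, which keeps per-fold class balance
for compositions like 856/957/856 and makes fold assignment reproducible.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import SCHEMA_VERSION, ExpressionMatrix, LabelVector

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "RepeatedCVResult",
    "confusion_matrix",
    "accuracy",
    "individual_accuracy",
    "indicator_matrices",
    "mcc_multiclass",
    "evaluate_predictions",
    "cross_validate",
    "repeated_cv",
]


@dataclass
class ConfusionMatrix:
    """True-class rows x predicted-class columns over an ordered label set."""

    classes: list[str]
    counts: np.ndarray  # int, shape (K, K)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, classes: list[str] | None = None) -> ConfusionMatrix:
    """Build a confusion matrix; class order = first appearance in y_true then y_pred."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    if classes is None:
        seen: dict[str, None] = {}
        for v in list(y_true) + list(y_pred):
            seen.setdefault(v, None)
        classes = list(seen)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(classes), counts)


def accuracy(confusion: ConfusionMatrix) -> float:
    """Fraction of correctly predicted samples (trace over total)."""
    if confusion.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion.counts)) / confusion.total


def individual_accuracy(confusion: ConfusionMatrix, klass: str) -> float | None:
    """Per-class recall: correct members of a class over all its members.

    Returns None (missing) for a class with no true members rather than 0.
    """
    i = confusion.classes.index(klass)
    row = confusion.counts[i].sum()
    if row == 0:
        return None
    return float(confusion.counts[i, i]) / float(row)


def indicator_matrices(y_true, y_pred, classes: list[str] | None = None):
    """One-hot n x K matrices (X for truth, Y for predictions)."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if classes is None:
        seen: dict[str, None] = {}
        for v in list(y_true) + list(y_pred):
            seen.setdefault(v, None)
        classes = list(seen)
    index = {c: i for i, c in enumerate(classes)}
    n, k = len(y_true), len(classes)
    X = np.zeros((n, k))
    Y = np.zeros((n, k))
    X[np.arange(n), [index[v] for v in y_true]] = 1.0
    Y[np.arange(n), [index[v] for v in y_pred]] = 1.0
    return X, Y, classes


def _matrix_cov(A: np.ndarray, B: np.ndarray) -> float:
    # sum over columns of per-column sample covariances (1/(n-1); cancels in the ratio)
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    return float((Ac * Bc).sum() / (n - 1))


def mcc_multiclass(y_true, y_pred) -> float:
    """Covariance-form multiclass MCC over one-hot indicator matrices.

    Returns 0.0 when either variance term is zero (constant truth or
    predictions), keeping the statistic defined for degenerate predictors.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    if len(y_true) < 2:
        raise ValueError("need at least two samples")
    X, Y, _ = indicator_matrices(y_true, y_pred)
    cxy = _matrix_cov(X, Y)
    cxx = _matrix_cov(X, X)
    cyy = _matrix_cov(Y, Y)
    if cxx <= 0 or cyy <= 0:
        return 0.0
    return cxy / np.sqrt(cxx * cyy)


@dataclass
class EvalReport:
    """Confusion matrix plus ACC, multiclass MCC and per-class recalls."""

    confusion: ConfusionMatrix
    acc: float
    mcc: float
    individual_accuracy: dict[str, float | None]
    folds: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "classes": self.confusion.classes,
            "confusion": self.confusion.counts.tolist(),
            "acc": self.acc,
            "mcc": self.mcc,
            "individual_accuracy": self.individual_accuracy,
            "folds": self.folds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        cm = ConfusionMatrix(list(d["classes"]), np.asarray(d["confusion"]))
        return cls(
            cm, d["acc"], d["mcc"], dict(d["individual_accuracy"]),
            d.get("folds"), d.get("seed"),
        )

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def evaluate_predictions(
    y_true, y_pred, classes: list[str] | None = None,
    folds: int | None = None, seed: int | None = None,
) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred, classes)
    return EvalReport(
        confusion=cm,
        acc=accuracy(cm),
        mcc=mcc_multiclass(list(y_true), list(y_pred)),
        individual_accuracy={c: individual_accuracy(cm, c) for c in cm.classes},
        folds=folds,
        seed=seed,
    )


def stratified_folds(
    labels: LabelVector, folds: int, seed: int, stratified: bool = True
) -> list[list[int]]:
    """Deterministic fold assignment: shuffle within class, deal round-robin.

    Unstratified assignment (``stratified=False``) shuffles all cells as one
    group; with ``folds = n`` it degenerates to leave-one-out.
    """
    rng = np.random.default_rng(seed)
    assignment: list[list[int]] = [[] for _ in range(folds)]
    if stratified:
        groups = [
            [i for i, c in enumerate(labels.classes) if c == klass]
            for klass in labels.class_order()
        ]
        for klass, idx in zip(labels.class_order(), groups):
            if len(idx) < folds:
                raise ValueError(
                    f"class {klass!r} has {len(idx)} members, fewer than {folds} folds"
                )
    else:
        if len(labels) < folds:
            raise ValueError(f"{len(labels)} cells, fewer than {folds} folds")
        groups = [list(range(len(labels)))]
    for idx in groups:
        idx = [idx[j] for j in rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            assignment[pos % folds].append(i)
    return [sorted(f) for f in assignment]


def cross_validate(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    learner,
    folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; aggregates all held-out predictions into one report.

    The learner must expose ``fit(matrix, labels)`` and ``predict(matrix)``;
    a fresh copy is fitted per fold so state never leaks across folds.
    """
    if len(labels) != matrix.n_cells:
        raise ValueError("labels and matrix differ in cell count")
    fold_sets = stratified_folds(labels, folds, seed, stratified=stratified)
    y_true: list[str] = [""] * matrix.n_cells
    y_pred: list[str] = [""] * matrix.n_cells
    for test_idx in fold_sets:
        test_set = set(test_idx)
        train_idx = [i for i in range(matrix.n_cells) if i not in test_set]
        model = copy.deepcopy(learner)
        model.fit(
            matrix.take_cells(train_idx),
            LabelVector(
                [labels.cell_ids[i] for i in train_idx],
                [labels.classes[i] for i in train_idx],
            ),
        )
        preds = model.predict(matrix.take_cells(test_idx))
        for i, p in zip(test_idx, preds):
            y_true[i] = labels.classes[i]
            y_pred[i] = str(p)
    return evaluate_predictions(
        y_true, y_pred, classes=labels.class_order(), folds=folds, seed=seed
    )


@dataclass
class RepeatedCVResult:
    """ACC/MCC distributions over repeated independent fold partitions."""

    accs: list[float]
    mccs: list[float]
    reports: list[EvalReport] = field(default_factory=list)

    def summary(self) -> dict:
        def stats(xs):
            return {
                "min": float(np.min(xs)),
                "median": float(np.median(xs)),
                "max": float(np.max(xs)),
            }

        return {"acc": stats(self.accs), "mcc": stats(self.mccs)}

    @property
    def mcc_spread(self) -> float:
        return float(np.max(self.mccs) - np.min(self.mccs))


def repeated_cv(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    learner,
    folds: int = 10,
    times: int = 10,
    base_seed: int = 0,
) -> RepeatedCVResult:
    """Repeat stratified CV with seeds base_seed .. base_seed+times-1."""
    reports = [
        cross_validate(matrix, labels, learner, folds=folds, seed=base_seed + t)
        for t in range(times)
    ]
    return RepeatedCVResult(
        accs=[r.acc for r in reports], mccs=[r.mcc for r in reports], reports=reports
    )
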