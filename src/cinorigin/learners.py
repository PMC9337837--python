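"""Learner adapters satisfying the fit/predict contract used by CV and IFS.

A learner exposes ``fit(matrix, labels)`` and ``predict(matrix) -> labels``
on :class:`~cinorigin.io_formats.ExpressionMatrix` /
:class:`~cinorigin.io_formats.LabelVector`. Three kinds are provided:

* ``tree_ensemble`` — a 100-tree random forest (scikit-learn), the strong
  black-box baseline;
* ``ripper`` — the interpretable decision-list learner from
  :mod:`cinorigin.ripper`;
* ``stub`` — predicts the modal training label; useful as a null baseline
  and in tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from sklearn.ensemble import RandomForestClassifier

from .io_formats import ExpressionMatrix, LabelVector
from .ripper import RipperConfig, RuleSet, fit_ripper, predict_ruleset

__all__ = [
    "LearnerSpec",
    "make_learner",
    "TreeEnsembleLearner",
    "RipperLearner",
    "MajorityLearner",
]


@dataclass
class LearnerSpec:
    """Declarative learner choice: kind plus kind-specific parameters."""

    kind: str  # "tree_ensemble" | "ripper" | "stub"
    params: dict = field(default_factory=dict)


class TreeEnsembleLearner:
    """Random forest with a fixed seed; deterministic predictions."""

    def __init__(self, n_trees: int = 100, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed
        self._model: RandomForestClassifier | None = None

    def fit(self, matrix: ExpressionMatrix, labels: LabelVector) -> "TreeEnsembleLearner":
        self._model = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        self._model.fit(matrix.values, labels.classes)
        return self

    def predict(self, matrix: ExpressionMatrix) -> list[str]:
        if self._model is None:
            raise RuntimeError("predict before fit")
        return [str(p) for p in self._model.predict(matrix.values)]


class RipperLearner:
    """Decision-list learner; the fitted model is an explicit RuleSet."""

    def __init__(self, config: RipperConfig | None = None):
        self.config = config or RipperConfig()
        self.ruleset: RuleSet | None = None

    def fit(self, matrix: ExpressionMatrix, labels: LabelVector) -> "RipperLearner":
        self.ruleset = fit_ripper(matrix, labels, self.config)
        return self

    def predict(self, matrix: ExpressionMatrix) -> list[str]:
        if self.ruleset is None:
            raise RuntimeError("predict before fit")
        return predict_ruleset(self.ruleset, matrix, strict=False)


class MajorityLearner:
    """Constant predictor of the modal training class (ties: first seen)."""

    def __init__(self):
        self.majority: str | None = None

    def fit(self, matrix: ExpressionMatrix, labels: LabelVector) -> "MajorityLearner":
        counts = Counter(labels.classes)
        top = max(counts.values())
        for c in labels.classes:  # first appearance wins ties
            if counts[c] == top:
                self.majority = c
                break
        return self

    def predict(self, matrix: ExpressionMatrix) -> list[str]:
        if self.majority is None:
            raise RuntimeError("predict before fit")
        return [self.majority] * matrix.n_cells


def make_learner(spec: LearnerSpec):
    """Instantiate a learner from its spec; unknown kinds are a config error."""
    if spec.kind == "tree_ensemble":
        return TreeEnsembleLearner(
            n_trees=int(spec.params.get("n_trees", 100)),
            seed=int(spec.params.get("seed", 0)),
        )
    if spec.kind == "ripper":
        cfg = RipperConfig(
            grow_fraction=float(spec.params.get("grow_fraction", 2.0 / 3.0)),
            seed=int(spec.params.get("seed", 0)),
            max_conditions=spec.params.get("max_conditions"),
        )
        return RipperLearner(cfg)
    if spec.kind == "stub":
        return MajorityLearner()
    raise ValueError(f"unknown learner kind {spec.kind!r}")
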