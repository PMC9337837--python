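"""Threshold-rule decision lists and the engine that applies them.

A ruleset is an ordered list of conjunctive threshold rules over gene
expression values, plus a default class. Application uses first-match
semantics: the first rule whose conditions all hold assigns its class;
a sample matching no rule receives the default class. Gene-name lookup
is case-insensitive because public expression tables mix capitalisation
conventions (``Lhx8`` vs ``LHX8``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RuleLookupError",
    "apply_ruleset",
    "predict_ruleset",
    "ruleset_stats",
]

_OPS = ("<=", ">=")


class RuleLookupError(KeyError):
    """A strict-mode rule application referenced a gene absent from the sample."""


@dataclass(frozen=True)
class Condition:
    """One threshold test ``gene <op> threshold`` with op in {<=, >=}."""

    gene: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {_OPS}")
        t = float(self.threshold)
        if t != t or t in (float("inf"), float("-inf")):
            raise ValueError(f"threshold must be finite, got {self.threshold!r}")

    def holds(self, value: float) -> bool:
        if self.op == "<=":
            return value <= self.threshold
        return value >= self.threshold


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions implying a class; empty conjunction matches all."""

    conditions: tuple[Condition, ...]
    klass: str

    def genes(self) -> tuple[str, ...]:
        return tuple(c.gene for c in self.conditions)


@dataclass(frozen=True)
class RuleSet:
    """Ordered decision list with first-match semantics and a fallback class."""

    rules: tuple[Rule, ...] = field(default_factory=tuple)
    default_class: str = ""

    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.klass, None)
        seen.setdefault(self.default_class, None)
        return tuple(seen)


def _lookup(sample: Mapping[str, float]) -> dict[str, float]:
    # Case-insensitive view; last occurrence wins on a (degenerate) case clash.
    return {str(k).upper(): float(v) for k, v in sample.items()}


def apply_ruleset(
    ruleset: RuleSet, sample: Mapping[str, float], strict: bool = False
) -> str:
    """Classify one sample (gene -> expression mapping).

    In strict mode a condition on a gene missing from the sample raises
    :class:`RuleLookupError`; in lenient mode (default) the condition simply
    fails, which lets the published ruleset score partial expression vectors.
    """
    values = _lookup(sample)
    for i, rule in enumerate(ruleset.rules):
        matched = True
        for cond in rule.conditions:
            key = cond.gene.upper()
            if key not in values:
                if strict:
                    raise RuleLookupError(
                        f"gene {cond.gene!r} (rule {i + 1}) absent from sample"
                    )
                matched = False
                break
            if not cond.holds(values[key]):
                matched = False
                break
        if matched:
            return rule.klass
    return ruleset.default_class


def predict_ruleset(ruleset: RuleSet, matrix, strict: bool = False) -> list[str]:
    """Apply a ruleset to every cell of an expression matrix (cells x genes)."""
    out = []
    for i in range(len(matrix.cell_ids)):
        sample = dict(zip(matrix.gene_ids, matrix.values[i]))
        out.append(apply_ruleset(ruleset, sample, strict=strict))
    return out


def ruleset_stats(ruleset: RuleSet) -> dict:
    """Structural summary: rule counts, per-class counts, condition lengths, genes."""
    per_class = Counter(r.klass for r in ruleset.rules)
    genes: dict[str, None] = {}
    for r in ruleset.rules:
        for g in r.genes():
            genes.setdefault(g, None)
    return {
        "n_rules": len(ruleset.rules),
        "rules_per_class": dict(per_class),
        "conditions_per_rule": [len(r.conditions) for r in ruleset.rules],
        "genes_used": list(genes),
        "default_class": ruleset.default_class,
    }
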