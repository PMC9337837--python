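"""Stable text formats for expression matrices, labels, rulesets and reports.

On-disk orientation of expression tables is genes x cells (the convention of
public expression repositories); in memory the orientation is cells x features
(the learning convention). :func:`read_expression_matrix` performs the
transposition, :func:`write_expression_matrix` undoes it, and both are stated
explicitly here to prevent silent transposition bugs.

Floats are written with Python's shortest round-trip representation, so
write -> read -> write is byte-stable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rules import Condition, Rule, RuleSet

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "FormatError",
    "AlignmentError",
    "RulesetParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "align_labels",
    "parse_ruleset",
    "format_ruleset",
    "read_ruleset",
    "write_ruleset",
]

SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """A file violated the expression/label format contract."""


class AlignmentError(ValueError):
    """Labels and matrix do not describe the same cells in the same order."""


class RulesetParseError(ValueError):
    """A ruleset text could not be parsed; carries the offending line number."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes matrix of nonnegative RPKM-like expression values."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # float64, shape (n_cells, n_genes)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.cell_ids),
            len(self.gene_ids),
        ):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for kind, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dup = _first_duplicate(ids)
                raise FormatError(f"duplicate {kind} identifier {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression value")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.gene_ids[j]!r}, cell {self.cell_ids[i]!r}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_pos[gene_id]
        except AttributeError:
            self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_pos[gene_id]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            list(self.cell_ids), [self.gene_ids[i] for i in idx], self.values[:, idx]
        )

    def take_cells(self, indices: Sequence[int]) -> "ExpressionMatrix":
        indices = list(indices)
        return ExpressionMatrix(
            [self.cell_ids[i] for i in indices],
            list(self.gene_ids),
            self.values[indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class LabelVector:
    """Per-cell class labels, aligned (same order) with an expression matrix."""

    cell_ids: list[str]
    classes: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.classes = [str(c) for c in self.classes]
        if len(self.cell_ids) != len(self.classes):
            raise FormatError("cell_ids and classes differ in length")

    def class_order(self) -> list[str]:
        """Distinct classes in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.classes:
            seen.setdefault(c, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.cell_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVector):
            return NotImplemented
        return self.cell_ids == other.cell_ids and self.classes == other.classes


def _first_duplicate(ids: Iterable[str]) -> str:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x cells TSV (first row cell ids, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"non-numeric entry in {path}: {e}") from None
    try:
        return ExpressionMatrix(cell_ids, gene_ids, body.T)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def _fmt(x: float) -> str:
    # shortest round-trip decimal; integers still carry ".0" for stability
    return repr(float(x))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the genes x cells TSV; inverse of :func:`read_expression_matrix`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.cell_ids) + "\n")
        vt = matrix.values.T
        for g, row in zip(matrix.gene_ids, vt):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_labels(path) -> LabelVector:
    """Read a two-column (cell_id, class) CSV with header, order preserved."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, class)")
    return LabelVector(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: LabelVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id,class\n")
        for c, k in zip(labels.cell_ids, labels.classes):
            fh.write(f"{c},{k}\n")


def align_labels(labels: LabelVector, matrix: ExpressionMatrix) -> None:
    """Raise :class:`AlignmentError` unless labels match the matrix cells in order."""
    if labels.cell_ids != matrix.cell_ids:
        missing = set(matrix.cell_ids) - set(labels.cell_ids)
        if missing:
            raise AlignmentError(f"cells without labels: {sorted(missing)[:5]}")
        raise AlignmentError("label order differs from matrix cell order")


# --- ruleset text format -----------------------------------------------------
#
#   (GENE <= 3.6524) and (GENE >= 1.4699) => CGE
#   others => dMGE
#
# Unicode <=/>= variants are accepted on input and normalised on output.

_COND_RE = re.compile(
    r"^\(\s*(?P<gene>[^\s()]+)\s*(?P<op><=|>=|≰?|≥|≦|≧)\s*"
    r"(?P<num>[-+0-9.eE]+)\s*\)$"
)
_OP_NORM = {"<=": "<=", ">=": ">=", "≤": "<=", "≥": ">=", "≦": "<=", "≧": ">="}


def _parse_condition(tok: str, lineno: int) -> Condition:
    m = _COND_RE.match(tok.strip())
    if not m:
        raise RulesetParseError(f"line {lineno}: cannot parse condition {tok!r}")
    op = _OP_NORM.get(m.group("op"))
    if op is None:
        raise RulesetParseError(f"line {lineno}: unknown operator in {tok!r}")
    try:
        num = float(m.group("num"))
    except ValueError:
        raise RulesetParseError(
            f"line {lineno}: unparseable number {m.group('num')!r}"
        ) from None
    return Condition(m.group("gene"), op, num)


def parse_ruleset(text: str) -> RuleSet:
    """Parse the decision-list text format (one rule per line, default last)."""
    rules: list[Rule] = []
    default: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if default is not None:
            raise RulesetParseError(f"line {lineno}: rule after the default line")
        if "=>" not in line:
            raise RulesetParseError(f"line {lineno}: missing '=>'")
        lhs, _, klass = line.rpartition("=>")
        lhs, klass = lhs.strip(), klass.strip()
        if not klass:
            raise RulesetParseError(f"line {lineno}: empty class label")
        if lhs.lower() == "others":
            default = klass
            continue
        conds = tuple(
            _parse_condition(tok, lineno) for tok in re.split(r"\s+and\s+", lhs)
        )
        rules.append(Rule(conds, klass))
    if default is None:
        raise RulesetParseError("missing default line ('others => CLASS')")
    return RuleSet(tuple(rules), default)


def format_ruleset(ruleset: RuleSet) -> str:
    lines = []
    for rule in ruleset.rules:
        if not rule.conditions:
            raise ValueError(
                "the text format cannot express an empty-antecedent rule "
                f"(class {rule.klass!r}); only the default line matches everything"
            )
        lhs = " and ".join(
            f"({c.gene} {c.op} {_fmt(c.threshold)})" for c in rule.conditions
        )
        lines.append(f"{lhs} => {rule.klass}")
    lines.append(f"others => {ruleset.default_class}")
    return "\n".join(lines) + "\n"


def read_ruleset(path) -> RuleSet:
    return parse_ruleset(Path(path).read_text())


def write_ruleset(ruleset: RuleSet, path) -> None:
    Path(path).write_text(format_ruleset(ruleset))
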