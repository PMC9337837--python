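"""Incremental feature selection over an mRMR-ranked gene list.

Nested prefixes of the ranked list are evaluated by stratified k-fold
cross-validation with a pluggable learner; the resulting size-vs-MCC curve
supports two selections: the *optimal* classifier (maximal MCC, smallest size
on ties) and the *compact* classifier (smallest size whose MCC is within
``delta`` of the maximum — a formalisation of picking the knee of the curve
by eye). Per-size CV seeds are derived from the base seed and the subset
size, never from execution order, so evaluations could run in any order and
still reproduce bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .io_formats import SCHEMA_VERSION, ExpressionMatrix, LabelVector
from .metrics import EvalReport, cross_validate
from .mrmr import RankedFeatureList

__all__ = [
    "IFSResult",
    "Selection",
    "build_subset_grid",
    "run_ifs",
    "select_optimal",
    "select_compact",
    "plot_ifs_curve",
]

#: Default MCC tolerance for the compact selection.
DEFAULT_COMPACT_DELTA = 0.015


def build_subset_grid(
    n_features: int, step: int = 10, max_size: int | None = None
) -> list[int]:
    """Subset sizes (step, 2*step, ...) up to max_size, appending max_size itself.

    The i-th grid point is ``10 * i`` under the default step, so index 24
    corresponds to a 240-feature subset.
    """
    if max_size is None:
        max_size = n_features
    if not 1 <= max_size <= n_features:
        raise ValueError(f"max_size={max_size} out of range 1..{n_features}")
    if step < 1 or step > max_size:
        raise ValueError(f"step={step} out of range 1..{max_size}")
    sizes = list(range(step, max_size + 1, step))
    if sizes[-1] != max_size:
        sizes.append(max_size)
    return sizes


def _size_seed(base_seed: int, size: int) -> int:
    # independent of execution order; stays below 2**31
    return (base_seed * 100003 + size * 7919) % (2**31 - 1)


@dataclass
class IFSResult:
    """One EvalReport per subset size, plus provenance of the run."""

    grid: list[int]
    reports: list[EvalReport]
    learner: str
    ranking_scheme: str

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.reports):
            raise ValueError("one report required per grid point")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid sizes must be strictly increasing")

    @property
    def mccs(self) -> list[float]:
        return [r.mcc for r in self.reports]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "grid": self.grid,
            "learner": self.learner,
            "ranking_scheme": self.ranking_scheme,
            "reports": [r.to_dict() for r in self.reports],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IFSResult":
        return cls(
            grid=list(d["grid"]),
            reports=[EvalReport.from_dict(r) for r in d["reports"]],
            learner=d["learner"],
            ranking_scheme=d["ranking_scheme"],
        )

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def read_json(cls, path) -> "IFSResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Selection:
    """A chosen grid point: the optimal or the compact classifier."""

    size: int
    report: EvalReport
    mode: str  # "optimal" | "compact"
    delta: float | None = None

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "mode": self.mode,
            "delta": self.delta,
            "acc": self.report.acc,
            "mcc": self.report.mcc,
        }


def run_ifs(
    ranked: RankedFeatureList,
    matrix: ExpressionMatrix,
    labels: LabelVector,
    learner,
    grid: list[int],
    folds: int = 10,
    seed: int = 0,
    learner_name: str | None = None,
    progress=None,
) -> IFSResult:
    """Cross-validate the learner on each ranked-prefix feature subset.

    ``progress``, if given, is called with (size, report) after each grid
    point — the pipeline uses it for structured logging.
    """
    if max(grid) > len(ranked):
        raise ValueError(f"grid point {max(grid)} exceeds ranked list ({len(ranked)})")
    missing = [g for g in ranked.top(max(grid)) if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"ranked gene {missing[0]!r} absent from matrix")
    reports = []
    for size in grid:
        sub = matrix.subset_genes(ranked.top(size))
        report = cross_validate(
            sub, labels, learner, folds=folds, seed=_size_seed(seed, size)
        )
        reports.append(report)
        if progress is not None:
            progress(size, report)
    return IFSResult(
        grid=list(grid),
        reports=reports,
        learner=learner_name or type(learner).__name__,
        ranking_scheme=ranked.scheme,
    )


def select_optimal(result: IFSResult) -> Selection:
    """Grid point with maximal MCC; ties go to the smallest subset."""
    if not result.grid:
        raise ValueError("empty IFS result")
    best = max(range(len(result.grid)), key=lambda i: (result.mccs[i], -result.grid[i]))
    return Selection(result.grid[best], result.reports[best], mode="optimal")


def select_compact(result: IFSResult, delta: float = DEFAULT_COMPACT_DELTA) -> Selection:
    """Smallest grid size whose MCC is within delta of the curve maximum."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    best_mcc = max(result.mccs)
    for i, size in enumerate(result.grid):
        if result.mccs[i] >= best_mcc - delta:
            return Selection(size, result.reports[i], mode="compact", delta=delta)
    raise AssertionError("unreachable: the maximum always satisfies the bound")


def plot_ifs_curve(
    result: IFSResult,
    selections: list[Selection] | None = None,
    path=None,
    x_range: tuple[int, int] | None = None,
):
    """Size-vs-MCC line plot with markers at the selected sizes.

    ``x_range`` windows the plot (e.g. (10, 500)) without re-running anything.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes, mccs = result.grid, result.mccs
    if x_range is not None:
        lo, hi = x_range
        pairs = [(s, m) for s, m in zip(sizes, mccs) if lo <= s <= hi]
        sizes, mccs = [p[0] for p in pairs], [p[1] for p in pairs]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(sizes, mccs, marker="o", markersize=3, lw=1, label=result.learner)
    for sel in selections or []:
        if x_range is None or x_range[0] <= sel.size <= x_range[1]:
            ax.axvline(sel.size, color="grey", lw=0.8, ls="--")
            ax.annotate(
                f"{sel.mode}: {sel.size}\nMCC={sel.report.mcc:.3f}",
                xy=(sel.size, sel.report.mcc),
                fontsize=8,
            )
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("CV multiclass MCC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
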