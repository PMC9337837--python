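"""End-to-end orchestration: filter -> discretize -> rank -> IFS -> rules.

:func:`run_pipeline` executes the whole analysis on an expression TSV and a
labels CSV and writes every derived artifact into a run directory:

* ``ranked.tsv`` — the mRMR feature list;
* ``ifs_<learner>.json`` + ``ifs_<learner>.png`` — IFS results and curves;
* ``selection_<learner>.json`` — optimal and compact selections;
* ``repeated_cv.json`` — repeated-CV stability of the compact tree ensemble;
* ``ruleset.txt`` + ``ruleset_report.json`` — decision list fitted on the
  rule learner's optimal subset, with its training-set evaluation;
* ``manifest.json`` — config echo, seeds and package versions.

Re-running with the same config byte-reproduces every JSON output (manifests
carry no timestamps; all seeds are explicit).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ifs import (
    IFSResult,
    Selection,
    build_subset_grid,
    plot_ifs_curve,
    run_ifs,
    select_compact,
    select_optimal,
)
from .io_formats import (
    align_labels,
    read_expression_matrix,
    read_labels,
    write_ruleset,
)
from .learners import LearnerSpec, make_learner
from .metrics import repeated_cv
from .mrmr import mrmr_rank, write_ranked_list
from .preprocessing import discretize_three_state, remove_all_zero_features
from .ripper import RipperConfig, fit_ripper, training_report

log = logging.getLogger("cinorigin.pipeline")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """All inputs, knobs and seeds of one pipeline run."""

    expression_path: str
    labels_path: str
    out_dir: str
    alpha: float = 1.0
    log1p: bool = False
    mrmr_scheme: str = "MID"
    mrmr_k: int | None = None
    ifs_step: int = 10
    ifs_max: int | None = None
    ifs_max_ripper: int | None = None  # rule induction is the slow stage
    compact_delta: float = 0.015
    folds: int = 10
    repeats: int = 10
    n_trees: int = 100
    seed: int = 0
    learners: tuple[str, ...] = ("tree_ensemble", "ripper")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["learners"] = list(self.learners)
        return d


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _stage("read")(read_expression_matrix)(config.expression_path)
    labels = _stage("read_labels")(read_labels)(config.labels_path)
    align_labels(labels, matrix)

    filtered, removed = _stage("filter_zeros")(remove_all_zero_features)(matrix)
    log.info("removed %d all-zero transcripts, %d retained", len(removed), filtered.n_genes)

    disc = _stage("discretize")(discretize_three_state)(
        filtered, alpha=config.alpha, log1p=config.log1p
    )
    k = config.mrmr_k or filtered.n_genes
    ranked = _stage("mrmr_rank")(mrmr_rank)(disc, labels, k=k, scheme=config.mrmr_scheme)
    write_ranked_list(ranked, out / "ranked.tsv")

    selections: dict[str, dict[str, Selection]] = {}
    results: dict[str, IFSResult] = {}
    for kind in config.learners:
        cap = config.ifs_max_ripper if kind == "ripper" else config.ifs_max
        max_size = min(cap or len(ranked), len(ranked))
        try:
            grid = build_subset_grid(len(ranked), step=config.ifs_step, max_size=max_size)
        except ValueError as e:
            raise PipelineError(f"stage 'ifs_{kind}' failed: {e}") from e
        learner = make_learner(
            LearnerSpec(kind, {"seed": config.seed, "n_trees": config.n_trees})
        )

        def progress(size, report, kind=kind):
            log.info("ifs[%s] size=%d acc=%.4f mcc=%.4f", kind, size, report.acc, report.mcc)

        result = _stage(f"ifs_{kind}")(run_ifs)(
            ranked, filtered, labels, learner, grid,
            folds=config.folds, seed=config.seed, learner_name=kind, progress=progress,
        )
        result.write_json(out / f"ifs_{kind}.json")
        opt = select_optimal(result)
        comp = select_compact(result, delta=config.compact_delta)
        selections[kind] = {"optimal": opt, "compact": comp}
        results[kind] = result
        (out / f"selection_{kind}.json").write_text(
            json.dumps(
                {m: s.to_dict() for m, s in selections[kind].items()},
                indent=2, sort_keys=True,
            )
        )
        plot_ifs_curve(result, [opt, comp], out / f"ifs_{kind}.png")

    if "tree_ensemble" in selections:
        comp = selections["tree_ensemble"]["compact"]
        sub = filtered.subset_genes(ranked.top(comp.size))
        learner = make_learner(
            LearnerSpec("tree_ensemble", {"seed": config.seed, "n_trees": config.n_trees})
        )
        rep = _stage("repeated_cv")(repeated_cv)(
            sub, labels, learner,
            folds=config.folds, times=config.repeats, base_seed=config.seed,
        )
        (out / "repeated_cv.json").write_text(
            json.dumps(
                {"accs": rep.accs, "mccs": rep.mccs, "summary": rep.summary()},
                indent=2, sort_keys=True,
            )
        )

    if "ripper" in selections:
        opt = selections["ripper"]["optimal"]
        sub = filtered.subset_genes(ranked.top(opt.size))
        ruleset = _stage("fit_rules")(fit_ripper)(
            sub, labels, RipperConfig(seed=config.seed)
        )
        write_ruleset(ruleset, out / "ruleset.txt")
        training_report(ruleset, sub, labels).write_json(out / "ruleset_report.json")

    manifest = {
        "schema_version": "1",
        "config": config.to_dict(),
        "versions": {"cinorigin": __version__},
        "n_cells": matrix.n_cells,
        "n_genes_input": matrix.n_genes,
        "n_genes_retained": filtered.n_genes,
        "n_all_zero_removed": len(removed),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
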