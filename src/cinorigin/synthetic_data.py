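"""Synthetic three-class expression matrices and published reference fixtures.

The generator emulates the structure of the GSE109796 subpallium single-cell
dataset: three classes of cells (CGE, dMGE, vMGE), tens of thousands of
nonnegative RPKM-like gene features, heavy zero-inflation, and a small set of
class-specific marker genes whose expression is threshold-separable. Each
entry is log-normal — exp of a Gaussian with per-gene log-mean — with a
planted log-scale mean shift (``effect_size``) for each marker gene in its
own class, followed by an independent Bernoulli dropout mask that zeroes
entries with probability ``dropout_prob``. Log-normality gives nonnegative
heavy-tailed values with closed-form moments; dropout reproduces the sparsity
of single-cell measurements. UMI counting noise, library-size differences and
batch effects are deliberately not modelled.

Markers occupy the first ``3 * markers_per_class`` gene indices in
class-sized blocks, so ground truth is positionally deterministic.

The module also ships two in-package fixtures: the published 23-rule decision
list for CGE/dMGE/vMGE classification (22 explicit rules plus a default), and
the dataset manifest (class sizes 856/957/856; 37,310 transcripts of which
6,037 are zero in every cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io_formats import ExpressionMatrix, LabelVector, parse_ruleset
from .rules import RuleSet

__all__ = [
    "GeneratorConfig",
    "DatasetManifest",
    "CLASS_NAMES",
    "generate_dataset",
    "published_ruleset",
    "gse109796_manifest",
]

#: Region-of-origin class labels, in the order used throughout the package.
CLASS_NAMES = ("CGE", "dMGE", "vMGE")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-marker log-normal generator.

    n_per_class: cells per class (CGE, dMGE, vMGE).
    n_genes: total gene features.
    markers_per_class: planted marker genes per class.
    effect_size: log-scale mean shift of a marker within its class.
    baseline_log_mean: log-scale mean of background expression.
    noise_sd: log-scale SD of every entry.
    dropout_prob: probability an entry is zeroed after sampling.
    """

    n_per_class: tuple[int, int, int] = (100, 100, 100)
    n_genes: int = 2000
    markers_per_class: int = 20
    effect_size: float = 2.0
    baseline_log_mean: float = 1.0
    noise_sd: float = 0.5
    dropout_prob: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be 3 nonnegative integers")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.markers_per_class < 0:
            raise ValueError("markers_per_class must be nonnegative")
        if 3 * self.markers_per_class > self.n_genes:
            raise ValueError("3 * markers_per_class exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass(frozen=True)
class DatasetManifest:
    """Shape summary of a three-class expression dataset."""

    class_names: tuple[str, str, str]
    class_counts: tuple[int, int, int]
    total_transcripts: int
    all_zero_transcripts: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts):
            raise ValueError("negative class count")
        if self.all_zero_transcripts > self.total_transcripts:
            raise ValueError("all_zero_transcripts exceeds total_transcripts")

    @property
    def n_cells(self) -> int:
        return sum(self.class_counts)

    @property
    def retained_transcripts(self) -> int:
        return self.total_transcripts - self.all_zero_transcripts


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, LabelVector, dict[str, list[str]]]:
    """Draw one dataset; bit-identical for identical configs (incl. seed).

    Returns the cells x genes matrix, per-cell labels, and the planted truth:
    a mapping from class name to its marker gene identifiers.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = sum(config.n_per_class)
    p = config.n_genes
    m = config.markers_per_class

    log_means = np.full((n_cells, p), float(config.baseline_log_mean))
    class_of_cell = np.repeat(np.arange(3), config.n_per_class)
    truth: dict[str, list[str]] = {}
    gene_ids = [f"G{j:05d}" for j in range(p)]
    for k, name in enumerate(CLASS_NAMES):
        marker_cols = np.arange(k * m, (k + 1) * m)
        truth[name] = [gene_ids[j] for j in marker_cols]
        rows = class_of_cell == k
        log_means[np.ix_(rows, marker_cols)] += config.effect_size

    values = np.exp(rng.normal(loc=log_means, scale=config.noise_sd))
    keep = rng.random((n_cells, p)) >= config.dropout_prob
    values = values * keep

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(cell_ids, gene_ids, values)
    labels = LabelVector(cell_ids, [CLASS_NAMES[c] for c in class_of_cell])
    return matrix, labels, truth


def write_truth(truth: dict[str, list[str]], path) -> None:
    """Two-column TSV (gene_id, class) recording the planted markers."""
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for klass, genes in truth.items():
            for g in genes:
                fh.write(f"{g}\t{klass}\n")


def published_ruleset() -> RuleSet:
    """The published 23-rule decision list for GSE109796 region-of-origin calls.

    22 explicit rules (12 CGE, 10 vMGE) with thresholds reproduced to all
    printed decimals, plus dMGE as the default class. Two typographical
    glitches in the printed table (an unbalanced parenthesis in rule 1 and a
    '> =' with a spurious space in rule 4) are normalised to well-formed
    conditions without altering any number.
    """
    text = resources.files("cinorigin.data").joinpath("published_rules.txt").read_text()
    return parse_ruleset(text)


def gse109796_manifest() -> DatasetManifest:
    """Shape manifest of the GSE109796 dataset the published rules describe."""
    raw = resources.files("cinorigin.data").joinpath("gse109796_manifest.json").read_text()
    d = json.loads(raw)
    return DatasetManifest(
        class_names=tuple(d["class_names"]),
        class_counts=tuple(d["class_counts"]),
        total_transcripts=d["total_transcripts"],
        all_zero_transcripts=d["all_zero_transcripts"],
    )
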