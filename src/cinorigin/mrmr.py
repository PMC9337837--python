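"""Minimum-redundancy maximum-relevance (mRMR) greedy feature ranking.

Ranks discretized genes by repeatedly appending the gene maximising

    MID:  I(g; label) - mean_{s in selected} I(g; s)
    MIQ:  I(g; label) / max(mean_{s in selected} I(g; s), MIQ_FLOOR)

where I is the plug-in (maximum-likelihood) mutual information in bits over
the empirical joint distribution. The first gene is the one with maximal
relevance I(g; label). Ties at every argmax are broken towards the lowest
original gene index, so the ranking is deterministic and order-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LabelVector
from .preprocessing import DiscretizedMatrix

__all__ = ["RankedFeature", "RankedFeatureList", "mutual_information", "mrmr_rank"]

#: MIQ mean-redundancy denominator floor, in bits, to avoid division blow-up.
MIQ_FLOOR = 0.001

_SCHEMES = ("MID", "MIQ")


@dataclass(frozen=True)
class RankedFeature:
    gene_id: str
    relevance: float  # I(gene; label), bits
    score: float  # mRMR objective value at the moment of selection


@dataclass
class RankedFeatureList:
    """Genes in mRMR selection order with relevance and score-at-selection."""

    entries: list[RankedFeature]
    scheme: str

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def __len__(self) -> int:
        return len(self.entries)


def _encode(values) -> np.ndarray:
    """Map arbitrary discrete values to consecutive integer codes."""
    _, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes.astype(np.intp)


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty input")
    xi = _encode(x)
    yi = _encode(y)
    a, b = xi.max() + 1, yi.max() + 1
    counts = np.bincount(xi * b + yi, minlength=a * b).reshape(a, b)
    return float(_mi_from_counts(counts[None, :, :])[0])


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI in bits for a stack of contingency tables, shape (p, A, B)."""
    n = counts.sum(axis=(1, 2), keepdims=True).astype(float)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    terms[~np.isfinite(terms)] = 0.0
    mi = terms.sum(axis=(1, 2))
    return np.maximum(mi, 0.0)


def _mi_all_genes_vs(states: np.ndarray, other: np.ndarray, n_other: int) -> np.ndarray:
    """MI in bits between every column of ``states`` (codes 0..2) and ``other``."""
    n, p = states.shape
    flat = (states * n_other + other[:, None]).astype(np.intp)
    flat += np.arange(p, dtype=np.intp) * (3 * n_other)
    counts = np.bincount(flat.ravel(), minlength=p * 3 * n_other)
    return _mi_from_counts(counts.reshape(p, 3, n_other))


def mrmr_rank(
    disc: DiscretizedMatrix,
    labels: LabelVector,
    k: int | None = None,
    scheme: str = "MID",
) -> RankedFeatureList:
    """Greedy mRMR ranking of all genes in ``disc`` against the class labels.

    Returns the first ``k`` entries of the ranking (all genes by default).
    Redundancy against the selected set is the mean pairwise MI, updated
    incrementally, so mrmr_rank(..., k) is a prefix of mrmr_rank(..., k').
    """
    scheme = scheme.upper()
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}, got {scheme!r}")
    p = len(disc.gene_ids)
    if k is None:
        k = p
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range 1..{p}")
    if len(labels) != len(disc.cell_ids):
        raise ValueError("labels and matrix differ in cell count")

    states = (disc.states.astype(np.intp) + 1)  # codes 0..2
    y = _encode(labels.classes)
    n_classes = int(y.max()) + 1

    relevance = _mi_all_genes_vs(states, y, n_classes)

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)

    first = int(np.argmax(relevance))  # argmax takes the lowest index on ties
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining[first] = False

    while len(selected) < k:
        last = selected[-1]
        redundancy_sum += _mi_all_genes_vs(states, states[:, last], 3)
        mean_red = redundancy_sum / len(selected)
        if scheme == "MID":
            objective = relevance - mean_red
        else:
            objective = relevance / np.maximum(mean_red, MIQ_FLOOR)
        objective = np.where(remaining, objective, -np.inf)
        nxt = int(np.argmax(objective))
        selected.append(nxt)
        scores.append(float(objective[nxt]))
        remaining[nxt] = False

    entries = [
        RankedFeature(disc.gene_ids[g], float(relevance[g]), s)
        for g, s in zip(selected, scores)
    ]
    return RankedFeatureList(entries, scheme)


def write_ranked_list(ranked: RankedFeatureList, path) -> None:
    """Ranked-list TSV: rank, gene_id, relevance (bits), score at selection."""
    with open(path, "w") as fh:
        fh.write(f"# scheme={ranked.scheme}\n")
        fh.write("rank\tgene_id\trelevance_bits\tscore\n")
        for i, e in enumerate(ranked.entries, start=1):
            fh.write(f"{i}\t{e.gene_id}\t{e.relevance!r}\t{e.score!r}\n")


def read_ranked_list(path) -> RankedFeatureList:
    entries = []
    scheme = "MID"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scheme="):
            scheme = first.strip().split("=", 1)[1]
            first = fh.readline()
        if not first.startswith("rank\t"):
            raise ValueError(f"{path}: not a ranked-list TSV")
        for line in fh:
            _, gene, rel, score = line.rstrip("\n").split("\t")
            entries.append(RankedFeature(gene, float(rel), float(score)))
    return RankedFeatureList(entries, scheme=scheme)
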