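"""Feature representation: all-zero transcript removal and 3-state discretization.

Transcripts that are zero in every cell carry no information and are dropped
before ranking. For the mutual-information computations each retained gene is
discretized per gene into three states around its own mean: below
``mean - alpha*sd`` -> -1, above ``mean + alpha*sd`` -> +1, else 0. The SD is
the population SD (divide by n), and the default ``alpha = 1.0`` follows the
classical mRMR discretization convention. A constant gene (sd = 0) maps
entirely to state 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix

__all__ = ["DiscretizedMatrix", "remove_all_zero_features", "discretize_three_state"]


@dataclass
class DiscretizedMatrix:
    """Cells x genes matrix of states in {-1, 0, +1} plus the alpha used."""

    cell_ids: list[str]
    gene_ids: list[str]
    states: np.ndarray  # int8, shape (n_cells, n_genes)
    alpha: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("states outside the {-1, 0, +1} alphabet")
        if self.states.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("states shape does not match identifiers")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


def remove_all_zero_features(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes that are zero in every cell; gene order otherwise preserved.

    Returns the filtered matrix and the list of removed gene identifiers.
    """
    nonzero = (matrix.values != 0).any(axis=0)
    kept = [g for g, keep in zip(matrix.gene_ids, nonzero) if keep]
    removed = [g for g, keep in zip(matrix.gene_ids, nonzero) if not keep]
    filtered = ExpressionMatrix(
        list(matrix.cell_ids), kept, matrix.values[:, nonzero]
    )
    return filtered, removed


def discretize_three_state(
    matrix: ExpressionMatrix, alpha: float = 1.0, log1p: bool = False
) -> DiscretizedMatrix:
    """Per-gene mean +/- alpha*sd three-state coding of an expression matrix.

    ``log1p=True`` applies log(1+x) before computing the per-gene mean and SD,
    as a sensitivity option; the default operates on the raw values.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    vals = np.log1p(matrix.values) if log1p else matrix.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)  # population SD
    lo = mu - alpha * sd
    hi = mu + alpha * sd
    states = np.zeros(vals.shape, dtype=np.int8)
    states[vals < lo] = -1
    states[vals > hi] = 1
    states[:, sd == 0] = 0
    return DiscretizedMatrix(
        list(matrix.cell_ids), list(matrix.gene_ids), states, float(alpha)
    )
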