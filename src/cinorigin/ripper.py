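"""RIPPER-style decision-list induction for continuous-feature multiclass data.

Sequential covering: classes are handled in ascending frequency order, and for
each class (except the most frequent, which becomes the default) rules are
grown and pruned until no positive samples remain. One rule is grown on a
growing set by greedily adding the single threshold condition with maximal
FOIL information gain until the rule covers no negatives (or a condition cap
is hit), then pruned on a held-out pruning set by deleting trailing conditions
to maximise (p - n) / (p + n). A pruned rule whose pruning-set error exceeds
50% is discarded and its class is closed.

This is the classic grow/prune core of RIPPER. The MDL-based stopping
criterion and the k=2 post-optimisation passes of the full algorithm are
deliberately not implemented: the simplified stop rule (positives exhausted,
or pruned-rule error > 50%) is the default behaviour, which keeps the learner
small, deterministic and easy to reason about. Rule counts can therefore
differ from implementations that run the full optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix, LabelVector
from .rules import Condition, Rule, RuleSet, apply_ruleset, predict_ruleset, ruleset_stats

__all__ = [
    "RipperConfig",
    "fit_ripper",
    "foil_gain",
    "Condition",
    "Rule",
    "RuleSet",
    "apply_ruleset",
    "predict_ruleset",
    "ruleset_stats",
]

NEG_INF = float("-inf")


@dataclass
class RipperConfig:
    """Knobs of the grow/prune loop.

    grow_fraction: share of the remaining pool used for growing (rest prunes).
    max_conditions: cap on conditions per rule (None = until pure).
    seed: RNG seed for the stratified grow/prune splits.
    """

    grow_fraction: float = 2.0 / 3.0
    seed: int = 0
    max_conditions: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.grow_fraction < 1:
            raise ValueError("grow_fraction must be in (0, 1)")


def foil_gain(p0: int, n0: int, p1: int, n1: int) -> float:
    """FOIL information gain of refining a rule from (p0, n0) to (p1, n1) coverage.

    gain = p1 * (log2(p1/(p1+n1)) - log2(p0/(p0+n0))). Zero positive coverage
    after the refinement yields -inf, so such a condition is never selected.
    """
    if p1 == 0:
        return NEG_INF
    return p1 * (math.log2(p1 / (p1 + n1)) - math.log2(p0 / (p0 + n0)))


def _grow_rule(
    X: np.ndarray, pos: np.ndarray, gene_ids: list[str], max_conditions: int | None
) -> list[Condition]:
    """Greedily add the best FOIL-gain threshold condition until no negatives."""
    covered = np.ones(len(pos), dtype=bool)
    conds: list[Condition] = []
    while True:
        p0 = int((pos & covered).sum())
        n0 = int((~pos & covered).sum())
        if p0 == 0 or n0 == 0:
            break
        if max_conditions is not None and len(conds) >= max_conditions:
            break
        best = (NEG_INF, -1, "", 0.0)  # gain, feature idx, op, threshold
        base = math.log2(p0 / (p0 + n0))
        for f in range(X.shape[1]):
            v = X[covered, f]
            y = pos[covered]
            order = np.argsort(v, kind="stable")
            vs, ys = v[order], y[order]
            # candidate thresholds: midpoints between consecutive distinct values
            distinct_end = np.nonzero(np.diff(vs))[0]  # last index of each run
            if distinct_end.size == 0:
                continue
            mids = (vs[distinct_end] + vs[distinct_end + 1]) / 2.0
            cum_pos = np.cumsum(ys)
            total_pos = int(cum_pos[-1])
            total = len(vs)
            # '<= t' keeps the sorted prefix through each run end
            p_le = cum_pos[distinct_end].astype(int)
            n_le = (distinct_end + 1) - p_le
            p_ge = total_pos - p_le
            n_ge = (total - (distinct_end + 1)) - n_le
            for op, parr, narr in (("<=", p_le, n_le), (">=", p_ge, n_ge)):
                with np.errstate(divide="ignore", invalid="ignore"):
                    gains = np.where(
                        parr > 0,
                        parr * (np.log2(parr / np.maximum(parr + narr, 1)) - base),
                        NEG_INF,
                    )
                j = int(np.argmax(gains))
                if gains[j] > best[0]:
                    best = (float(gains[j]), f, op, float(mids[j]))
        gain, f, op, thr = best
        if gain <= 0:
            break
        cond = Condition(gene_ids[f], op, thr)
        conds.append(cond)
        if op == "<=":
            covered &= X[:, f] <= thr
        else:
            covered &= X[:, f] >= thr
    return conds


def _rule_mask(conds: list[Condition], X: np.ndarray, gene_pos: dict[str, int]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in conds:
        col = X[:, gene_pos[c.gene]]
        mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
    return mask


def _prune_rule(
    conds: list[Condition], X: np.ndarray, pos: np.ndarray, gene_pos: dict[str, int]
) -> list[Condition]:
    """Keep the prefix maximising (p - n)/(p + n) on the pruning set.

    Empty coverage scores -1 (worst). Ties prefer the shortest prefix (the
    more general rule). The antecedent is never pruned to empty.
    """
    best_val, best_len = -math.inf, len(conds)
    mask = np.ones(X.shape[0], dtype=bool)
    vals = []
    for c in conds:
        col = X[:, gene_pos[c.gene]]
        mask = mask & ((col <= c.threshold) if c.op == "<=" else (col >= c.threshold))
        p = int((pos & mask).sum())
        n = int((~pos & mask).sum())
        vals.append((p - n) / (p + n) if p + n > 0 else -1.0)
    for i, v in enumerate(vals, start=1):
        if v > best_val:
            best_val, best_len = v, i
    return conds[:best_len]


def fit_ripper(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    config: RipperConfig | None = None,
) -> RuleSet:
    """Induce an ordered decision list from an expression matrix and labels.

    Deterministic given ``config.seed``. Classes are processed from rarest to
    most frequent (frequency ties broken by first appearance in the labels);
    the most frequent class never receives explicit rules and becomes the
    default class of the returned :class:`RuleSet`.
    """
    if config is None:
        config = RipperConfig()
    order = labels.class_order()
    if len(order) < 2:
        raise ValueError("need at least two classes")
    counts = {c: labels.classes.count(c) for c in order}
    # ascending frequency; stable sort keeps first-appearance order on ties
    by_freq = sorted(order, key=lambda c: counts[c])
    default_class = by_freq[-1]

    X = matrix.values
    y = np.asarray(labels.classes)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rng = np.random.default_rng(config.seed)

    pool = np.ones(matrix.n_cells, dtype=bool)
    rules: list[Rule] = []
    for klass in by_freq[:-1]:
        while True:
            pool_idx = np.nonzero(pool)[0]
            pos_mask = y[pool_idx] == klass
            if not pos_mask.any() or pos_mask.all():
                break
            grow_idx, prune_idx = _split_grow_prune(
                pool_idx, pos_mask, config.grow_fraction, rng
            )
            conds = _grow_rule(
                X[grow_idx],
                y[grow_idx] == klass,
                matrix.gene_ids,
                config.max_conditions,
            )
            if not conds:
                break
            if len(prune_idx):
                conds = _prune_rule(
                    conds, X[prune_idx], y[prune_idx] == klass, gene_pos
                )
                mask_p = _rule_mask(conds, X[prune_idx], gene_pos)
                p = int((y[prune_idx][mask_p] == klass).sum())
                n = int(mask_p.sum()) - p
                if p + n > 0 and n / (p + n) > 0.5:
                    break  # pruned rule worse than chance on held-out data
            mask_pool = _rule_mask(conds, X[pool_idx], gene_pos)
            if not (y[pool_idx][mask_pool] == klass).any():
                break
            rules.append(Rule(tuple(conds), klass))
            pool[pool_idx[mask_pool]] = False
    return RuleSet(tuple(rules), default_class)


def _split_grow_prune(
    pool_idx: np.ndarray, pos_mask: np.ndarray, grow_fraction: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (by positive/negative) split of the pool into grow and prune."""
    grow_parts, prune_parts = [], []
    for group in (pool_idx[pos_mask], pool_idx[~pos_mask]):
        perm = group[rng.permutation(len(group))]
        cut = max(1, int(math.ceil(grow_fraction * len(group)))) if len(group) else 0
        grow_parts.append(perm[:cut])
        prune_parts.append(perm[cut:])
    grow = np.sort(np.concatenate(grow_parts))
    prune = np.sort(np.concatenate(prune_parts))
    return grow, prune


def training_report(ruleset: RuleSet, matrix: ExpressionMatrix, labels: LabelVector):
    """Training-set evaluation of a ruleset via the shared rule engine."""
    from .metrics import evaluate_predictions

    preds = predict_ruleset(ruleset, matrix)
    return evaluate_predictions(labels.classes, preds, classes=labels.class_order())
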