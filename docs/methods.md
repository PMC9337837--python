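# Methods

## Problem and pipeline

Single cells from the embryonic mouse subpallium carry a label for their
region of origin — CGE, dMGE or vMGE — and an RPKM expression vector over
tens of thousands of transcripts. The pipeline treats region prediction as a
three-class supervised problem and extracts both a strong black-box
classifier and an interpretable rule list:

filter all-zero transcripts → three-state discretization → mRMR ranking →
incremental feature selection (IFS) with cross-validated learners →
optimal/compact subset selection → rule induction on the selected subset.

## Feature representation

Transcripts with zero expression in every cell are removed (they carry no
information and only dilute the ranking). For mutual-information estimation
each gene is discretized per gene into three states around its own
statistics: −1 below μ − ασ, +1 above μ + ασ, 0 otherwise. Conventions,
fixed and documented rather than inferred:

* σ is the **population** SD (divide by n), matching the classical mRMR
  program's discretization;
* default **α = 1.0**, the mean ± 1 SD convention of that program;
* no transformation of the raw RPKM values by default; a `log1p` flag exists
  purely as a sensitivity option, since whether any transformation preceded
  ranking in prior analyses of such data is typically unstated.

A constant gene (σ = 0) maps entirely to state 0 and therefore has zero
relevance.

## mRMR ranking

Relevance and redundancy are plug-in (maximum-likelihood) mutual
informations in bits over empirical joint frequencies — no bias correction,
again matching the classical program. The greedy recurrence seeds the list
with the most relevant gene, then repeatedly appends the gene maximising

* MID (default): I(g; y) − mean over selected s of I(g; s)
* MIQ: I(g; y) / max(mean redundancy, 0.001)

The 0.001-bit floor prevents division blow-up for genes nearly independent
of the selected set. Ties at every argmax go to the lowest original gene
index, making the ranking deterministic; because redundancy is accumulated
incrementally, `mrmr_rank(..., k)` is always a prefix of
`mrmr_rank(..., k')` for k < k'. Relevance and redundancy are computed on
the discretized matrix only.

## Multiclass MCC and cross-validation

True and predicted labels are encoded as n × K one-hot indicator matrices X
and Y. With cov(A, B) defined as the sum over columns of per-column sample
covariances (1/(n−1); the constant cancels),

    MCC = cov(X, Y) / sqrt(cov(X, X) · cov(Y, Y)).

This equals the Gorodkin R_K statistic computed from confusion-matrix
entries; the test suite asserts the equivalence numerically on random tables
rather than assuming it (the correlation-coefficient wording and the
covariance ratio coincide because the normalisations cancel). When either
variance term vanishes — e.g. a constant predictor on a weak subset — the
statistic is defined as 0, not NaN, so IFS curves stay well-defined.
Accuracy is trace/total of the confusion matrix; individual accuracy is
per-class recall, reported as missing (not 0) for an empty class.

Cross-validation is stratified and deterministic: within each class, cells
are shuffled by a seeded RNG and dealt round-robin to folds, preserving
class balance for compositions like 856/957/856. A `stratified=False` mode
(global dealing) exists for leave-one-out, where per-class stratification is
impossible. A fresh copy of the learner is fitted per fold. Repeated CV uses
seeds base, base+1, …, giving independent partitions.

## Incremental feature selection

The subset grid is (step, 2·step, …) up to the cap, with the cap itself
appended when not a multiple; the default step of 10 makes grid index 24 the
240-feature subset. Each grid point evaluates the ranked prefix by CV; the
per-size CV seed is derived from the base seed and the size (not execution
order), so evaluations are order-independent and reproducible.

Two selections are reported: **optimal** (maximal MCC, smallest size on
ties) and **compact** (smallest size within δ of the maximum). The compact
rule formalises the usual practice of picking the knee of the IFS curve by
eye; the default δ = 0.015 is chosen so that a curve passing through MCC
0.711 at 120 features and 0.725 at 240 features compacts 240 → 120
(gap 0.014 ≤ 0.015).

## Rule induction

The rule learner is a RIPPER-style sequential-covering inducer for
continuous features. Classes are processed from rarest to most frequent
(frequency ties broken by first appearance); the most frequent class becomes
the default and receives no explicit rules. Per class, while positives
remain in the pool:

1. split the pool, stratified by positive/negative, into a growing set
   (2/3 by default) and a pruning set;
2. grow one rule by greedily adding the threshold condition (gene, ≤/≥,
   threshold) with maximal FOIL gain
   p₁·(log₂ p₁/(p₁+n₁) − log₂ p₀/(p₀+n₀)); candidate thresholds are
   midpoints between consecutive distinct observed values; growth stops when
   the rule covers no negatives on the growing set (or a configurable
   condition cap);
3. prune by keeping the condition prefix maximising (p−n)/(p+n) on the
   pruning set (empty coverage scores −1; ties prefer the shorter, more
   general prefix; the antecedent is never emptied);
4. accept the rule and remove covered cells — unless its pruning-set error
   exceeds 50%, which discards the rule and closes the class.

The MDL stopping criterion and the k=2 post-optimisation passes of the full
original algorithm are deliberately omitted: the simplified stop rule keeps
the learner compact and deterministic, at the cost that rule counts can
differ from implementations running the full optimisation. Grow fraction,
condition cap and seed are explicit config knobs.

Rule application is first-match-wins with a fallback class. Gene lookup is
case-insensitive (public tables mix `Lhx8`/`LHX8`). Missing genes fail the
condition in the default lenient mode — so the published ruleset can score
partial vectors — and raise in strict mode, which the pipeline uses.

Note one consequence of first-match semantics worth knowing when using the
shipped published ruleset: its rule 20 contains only upper-bound (≤)
conditions, so an all-zero expression vector matches it and is classified
vMGE, not the default dMGE.

## Synthetic data: what it emulates and what it does not

Each entry is exp(N(μ, noise_sd²)) with μ = baseline_log_mean, plus
effect_size for a marker gene in its own class, then multiplied by an
independent Bernoulli(1 − dropout_prob) mask. Defaults: 100 cells per class,
2,000 genes, 20 markers per class, effect_size 2.0 (log scale),
baseline_log_mean 1.0, noise_sd 0.5, dropout 0.3, seed 7. These defaults
define the standard test conditions used throughout the suite; they mimic
the three-class structure, nonnegativity, heavy right tail and sparsity of
RPKM single-cell data at a size where the full pipeline runs in seconds.
Markers occupy the first 3 × markers_per_class gene indices in class blocks,
so ground truth is positional and deterministic; generation is bit-identical
given the config.

Not modelled, hence not demonstrated by passing tests: UMI counting noise,
library-size variation, batch effects, correlated gene modules,
developmental time points, and genes that are zero in *every* cell (dropout
is per-entry, so all-zero transcripts essentially never arise at these
sizes — the all-zero filter is exercised by constructed fixtures instead).
Planted markers are far cleaner than real marker genes; perfect recovery on
synthetic defaults shows the machinery is correct, not that real data would
yield such scores.

A caution established while validating the pipeline: because the ranking is
computed once on the full dataset before cross-validation (as is common in
this analysis style), CV scores of selected subsets are optimistically
biased. With no signal at all (effect_size 0) the best IFS CV MCC on the
default generator sizes is around 0.3–0.4, not ≈ 0 — pure selection bias at
p ≫ n. Conclusions about absolute performance should rest on external
validation; the package reports this null measurement in its acceptance
script rather than hiding it.

## Numerical and design choices

* Plug-in MI, base-2 logs; zero-probability terms contribute 0.
* MIQ denominator floor 0.001 bits.
* Covariance normalisation 1/(n−1) (cancels; fixed for definiteness).
* MCC zero-variance fallback 0.
* Float round-trips: all text formats write shortest round-trip decimals, so
  write→read→write is byte-stable; Unicode ≤/≥ are accepted on input and
  normalised to ASCII on output.
* On-disk expression orientation is genes × cells (repository convention);
  in memory cells × genes (learning convention). Stated explicitly to
  prevent silent transposition bugs.
* The published fixture normalises two typographical glitches of the printed
  table (an unbalanced parenthesis; a "> =" with a stray space) without
  altering any threshold digit.
* The tree-ensemble learner wraps scikit-learn's RandomForestClassifier
  (100 trees, fixed seed) behind the learner contract; the bespoke science —
  mRMR, covariance MCC, IFS, rule induction — is implemented here.
* Pipeline IFS caps the rule learner's grid lower than the forest's by
  default (`ifs_max_ripper`), as rule induction is the slowest stage; both
  caps are configurable.

## Limitations

* The rule learner's simplified stopping means its rule lists are not
  expected to match tools that implement full MDL-based RIPPER rule for
  rule; structural properties (decision-list semantics, default class,
  threshold conditions) do match.
* No GEO download or series-matrix parsing; real-data runs start from a TSV.
* Dense matrices only; at 31,273 genes × 2,669 cells this is ~0.7 GB of
  float64, acceptable for the intended scale but not for atlas-size data.
* The discretization α and the absence of a pre-ranking transform are
  conventions, not fitted choices; the sensitivity flag exists to probe
  them.
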