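# Methods

## Problem

Genome-wide CRISPRi enhancer-perturbation screens assign each candidate
enhancer-promoter (EP) pair a binary outcome: *functional* if blocking
the enhancer significantly down-regulated the gene (adjusted p < 0.1,
down direction only; up-regulation is never positive; pairs with a
missing adjusted p-value are excluded).  The resulting data are
extremely imbalanced (~2% positives) and spatially autocorrelated along
the genome.  `epspec` implements a supervised analysis of such data:
engineered genomic features per candidate pair, leakage-free blocked
splitting, gradient-boosted classification, Shapley interpretation, and
imbalance-aware evaluation — exercised end to end on a synthetic genome
generator so every stage is testable without external data.

## Candidate pairs and features

Candidates are all same-chromosome (enhancer, TSS) pairs whose
center-to-center distance is at most half the candidate window
(`window_bp` = 5 Mb total span, i.e. ±2.5 Mb, closed boundary).  The
window wording is ambiguous between a total span and a radius; the
default here is total span, configurable.  One neighborhood notion is
used everywhere ("near" = the same half-window).

Per pair the families are:

* **distance** — |enhancer midpoint − TSS position| in bp.
* **contact** — KR-normalized Hi-C value of the pair's bin pair
  (`bin_size` = 5 kb default; the source resolution is not fixed by the
  data formats, so both bin size and midpoint lookup are config knobs).
* **abc** — activity-by-contact score
  `A_e·C_ep / Σ_{e'} A_{e'}·C_{e'p}`, with activity the geometric mean
  of H3K27ac and DHS (H3K27ac alone when DHS is absent).  Scores of one
  promoter sum to 1 whenever the denominator is positive; a zero
  denominator yields all-zero scores.
* **relative contact** — max contact in the neighborhood, difference
  from that max, and dense rank (1 = strongest, ties share the better
  rank), computed TSS-centric (contacts reaching the focal TSS) and
  enhancer-centric (contacts originating from the focal enhancer), plus
  the *remaining* (non-focal) contact sums on both sides.
* **density** — `Enhancer.count.near.TSS` and `TSS.count.near.enhancer`,
  region totals including the focal element (so the focal-side minimum
  on a candidate row is 1).
* **signals** — H3K27ac/H3K4me3/H3K27me3 and DHS per side, and target
  gene expression.
* **TF presence** — one binary column per TF and side: half-open
  interval overlap with the enhancer, and with the TSS ± 500 bp (flank
  chosen here; promoter-side overlap needs some slack around a 1-bp
  TSS).
* **NMF co-binding clusters** — see below.

All ops are vectorized; a brute-force all-pairs loop oracle checks them
exactly on small instances.

## ChIN distance classes

Per promoter, a Chromatin Interaction Network restricts the loop graph
to the promoter and the enhancers tested in the screen.  An edge is a
*significant* loop between the two elements' contact bins; significance
normally comes from an external caller's q-values (q < 0.05), with a
built-in distance-stratified top-quantile rule (log-spaced distance
strata, top fraction by contact within each) as a self-contained
stand-in, flagged as such in output manifests.

Classes: `e0` when enhancer and promoter share a bin (the bin test
precedes the graph test), otherwise the shortest path length from the
promoter where only enhancer nodes may serve as intermediates — 1, 2, 3
map to `e1`, `e2`, `e3`; longer or disconnected is `einf`.  Shortest-
path semantics make node revisits irrelevant.  `e1minus` = {e0, e1}
(direct contact) and `e2plus` = {e2, e3, einf} partition every table.
The labeling is checked against exhaustive path enumeration on random
graphs and is monotone: adding an edge never worsens a class.

## Blocked splitting

Whole chromosomes are first set aside as an untouched test set (the
TSS chromosome decides; pairs are intra-chromosomal).  Remaining
elements are clustered single-linkage along each chromosome with a new
group whenever the gap reaches `gap_bp` (5 Mb); each pair inherits the
merged (union-find) group of its endpoints, which preserves the
separation guarantee because merged groups are bridged by a real pair.
Nested folds assign groups whole, by greedy bin-packing balancing
positive counts then totals with seeded tie-breaking — a deterministic,
dependency-free stand-in for a stratified group splitter with the same
guarantees.  An instrumented checker asserts the invariant directly: no
genomic window narrower than the gap contains elements used by EPs of
two different outer folds.

## Learning

XGBoost binary classifier per outer fold; scaling, selection, and
tuning see only the outer training split, and per-fold models are never
merged or refit on combined folds.

* **Scaling** — per-feature min/max to [0, 1] from training rows;
  constant columns map to 0; unseen rows may fall outside [0, 1] (no
  clipping).
* **Selection (Boruta)** — each round appends a permuted shadow copy of
  every feature, trains a preliminary ensemble, and scores a hit for
  features whose mean |Shapley attribution| beats the best shadow;
  after n rounds, hit counts above/below the binomial(0.5) bounds at
  α = 0.05 are confirmed/rejected, the remainder tentative and kept by
  default (conservative under extreme imbalance).
* **Tuning** — seeded random search (depth 2–10, learning rate
  0.005–0.3 log-uniform, ≤ 2000 rounds, child weight 1–16, subsamples
  0.5–1, L1/L2 1e-3–10, positive-class weight 1–(neg/pos)), each
  candidate scored by mean average precision over the inner validation
  folds with early stopping; the across-fold argmax wins.
* **Early stopping** — on validation average precision, the same metric
  as the tuning objective.
* **Attribution** — exact tree-path Shapley values from XGBoost's
  built-in tree SHAP (`pred_contribs`); local accuracy (attributions +
  base = margin) is asserted to 1e-4.  Per-fold test attributions are
  combined by concatenation; features are ranked by mean |attribution|
  with name tie-breaks.

A poisoning test (sentinel values injected into test rows) verifies
that no test-row statistic enters any fit.

Two profiles exist: the full protocol above, and a *fast* profile
(fixed mid-range hyper-parameters — depth 6, learning rate 0.08,
subsample 0.9/0.8, positive-class weight √(neg/pos), ≤ 400 rounds with
early stopping on a group-aware validation split; no selection or
tuning) used wherever many seeded repetitions are needed.

## TF co-binding clusters (NMF)

The binary element × TF presence matrices (TSS side and enhancer side
separately) are factored at rank k = 12 by multiplicative-update NMF
minimizing squared Frobenius error, 5 seeded restarts keeping the best.
The solver is written in-package because the per-iteration error
trajectory is part of the tested contract (monotone descent within
1e-10); an external NMF implementation serves as an independent quality
cross-check in the tests.  Scale indeterminacy is resolved by
normalizing H rows to unit max (W rescaled inversely).  Fitting uses
unique elements, not EP rows, so dense regions do not weight elements
by pair multiplicity; W scores are then broadcast to pairs as
`TF_NMF<i>_e` / `TF_NMF<i>_TSS` columns.  Whether to factor the raw
binary matrix or a normalized variant was open; the raw binary matrix
is used.

## Evaluation

Average precision is computed by definition — the mean over positives
of the precision at each positive's rank, ties in stable input order —
and is the single scalar (AUC-PR and mean average precision are treated
as the same quantity).  Models are compared at matched recall: the
threshold is the largest score value whose recall is ≥ 0.70, chosen on
the evaluation set itself, which maximizes precision subject to the
recall floor.  Degenerate rates (0/0) are reported as undefined, never
as zero.  Supporting views: ABC and inverse-distance baselines (zero
distance maps to the top finite score), filtering to genes with at
least one positive pair, confusion proportions stratified by
regulatory-element density bins, and weak/strong contact partitions
(≥ threshold is strong; presets 0.002 and 0.005).

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment:

| parameter | default | rationale |
| --- | --- | --- |
| genome | 5 chromosomes × 40 Mb | ~20,000 candidate pairs, desk scale |
| elements | 2,200 enhancers, 380 TSSs | ~11 enhancers/Mb, screen-like candidate density |
| placement | blockwise log-normal intensity, heterogeneity 1.0 | high/low-density neighborhoods |
| contact | 0.2·(d/5 kb)^(−1), log-normal noise σ = 0.5 | power-law decay; values span the 0.002/0.005 cut-offs |
| TFs | 40 in 4 planted clusters, p_in 0.7 / p_out 0.05 | block co-binding structure (a 250-TF panel scaled down) |
| prevalence | 0.02 | genome-wide screen imbalance |
| outcome model | logistic over standardized log-contact (β 1.0), log enhancer H3K27ac (0.7), −log distance (0.8), latent promoter insensitivity (−1.5), causal TF-cluster count (0.6) | effect directions of the known biology: stronger contact, shorter distance, higher enhancer activity predict positive; insensitive promoters suppress |

The intercept is calibrated by bisection on the mean sigmoid so the
realized prevalence equals the target exactly in expectation (no
rejection sampling).  15% of promoters are latently *insensitive* with
3× boosted active promoter marks — the learner can see only the marks,
not the flag, so the achievable ceiling is below 1, as in real screens.
Outcomes are materialized as adjusted p-values (small and ``down`` for
positives, uniform otherwise, 2% masked to ``NA``) so the labeling op
reconstructs the planted labels from the same interface real data use.

What the generator does **not** emulate: read-level noise, guide
efficiency variation, multi-TSS genes, trans effects, cell-type-
specific TF biology, and any real TF identity.  Passing tests therefore
demonstrate that the machinery is correct and can recover planted
structure at screen-like imbalance — not that any biological claim
about real data is reproduced.

## Problem sizes and numerical choices

Repeated experiments (parameter recovery, baseline comparisons) run the
fast profile on the default ~20k-pair genome over 10 seeds; blocking
and graph-labeling property suites use 100 small genomes and 500 random
graphs respectively.  The synthetic genome's five chromosomes support
four outer folds but only two inner folds per outer training split; the
full 4×4 scheme applies to genomes with more chromosomes.  Ties are
always broken deterministically (element id, feature name, canonical
bin order); NMF tolerance 1e-7 relative, bisection tolerance 1e-10;
degenerate inputs (empty tables, single-class labels, zero denominators,
constant columns) either raise with a named cause or follow a
documented policy, never silently.

## Known limitations

* The built-in loop-significance rule is a stand-in for a proper loop
  caller and is only used to make the pipeline self-contained.
* Greedy fold packing approximates stratification; with very few groups
  a fold can end up without positives (warned, not fatal).
* The fast profile's fixed hyper-parameters are not tuned per dataset;
  it exists for repetition, not for peak performance.
* Feature columns are dense; genomes far larger than the defaults would
  want a sparse TF representation.
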