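# Methods

This note documents the models, algorithms and numerical choices behind
`ehrweights`, and what the synthetic experiments do and do not show.

## Temporal representation

Inputs are long-format event tables: one row per occurrence of a clinical
event (diagnosis, drug, or measurement code) with an integer day offset
counted backwards from the patient's index event. Offsets run from 0
(same calendar day) to a 90-day horizon; events further back are assumed
uninformative and are outside the data model.

The default window grid has upper boundaries at days
1, 2, 3, 4, 5, 6, 7, 14, 21, 30, 60, 90. Window *i* covers the half-open
interval (boundary_{i−1}, boundary_i] of day offsets, and day 0 is folded
into window 1. This makes the 12 windows a partition of all 91 day
offsets: daily resolution in the first week, then week-, then
month-scale. Same-day events are *included*; this is consistent with the
pre-assigned weighting convention that same-day events carry the maximum
weight 1, but it is a convention — a deployment that fears index-day
leakage can start the grid later.

Feature values are raw occurrence counts, never normalized per patient.
The binned matrix (patients × (code, window) columns) is stored sparse;
columns are sorted by (code, type, window) so the manifest order is
deterministic.

## Weighting

**Pre-assigned.** w = 1/n for an event n ≥ 1 days before the index event,
w = 1 on day 0. Aggregation applies this per occurrence at its exact day;
the sampling strategy needs window-level weights and uses each window's
*upper boundary* as its representative day (a deterministic choice; the
midpoint would be the natural alternative and changes little since both
are monotone in the window index).

**Learned.** A 500-tree forest with uniform candidate sampling is fitted
to the binned matrix; each column's weight is its normalized Gini
importance (total impurity decrease, averaged over trees, normalized to
sum 1). Granularity pooling takes arithmetic means of member columns —
per (type, window) or per window — which keeps all levels on a common
scale and preserves the mean column weight when expanded back onto the
manifest. Because learned weights use the labels, the evaluation harness
re-learns them inside every training fold; the pre-assigned weights use
no label information, so no leakage arises there.

**Application.**

* *Aggregation:* learned weights are max-scaled onto [0, 1] (mirroring
  the pre-assigned range) before the weighted window-collapse. The scale
  of the multipliers is otherwise arbitrary since trees are invariant to
  monotone per-feature transforms; max-scaling is chosen for
  interpretability.
* *Sampling:* weights are normalized to a probability simplex,
  prob_c = (w_c + floor)/Σ(w + floor), with floor = 0 by default so that
  zero-importance columns are never sampled. A positive floor is
  available for smoothing experiments.

## The weighted forest

A from-scratch binary CART/random-forest implementation (numba kernels):

* 500 trees by default, each on a size-n bootstrap replicate; mtry =
  ⌊√p⌋ candidates per node; trees fully grown (min node size 1).
* Candidates are drawn per **node**, without replacement, each successive
  draw proportional to the remaining probabilities. Internally this is
  rejection sampling against the fixed cumulative distribution (exactly
  the same distribution), with an O(p) renormalized fallback when the
  remaining mass is tiny. If fewer than mtry columns have nonzero
  probability, all of them are used.
* Splits maximize Gini impurity decrease; thresholds are midpoints
  between consecutive distinct sorted values (feature values are
  non-negative counts, so the zero block is handled implicitly). Ties are
  broken by the lower manifest column, then the lower threshold, making
  the tree a pure function of (data, probabilities, seed).
* Prediction: each tree votes its leaf's majority class (leaf tie →
  negative); the score is the fraction of positive votes and an exact
  0.5 vote tie classifies negative.
* Gini importance accumulates (n_node/n_root)·[G − (n_L/n_node)G_L −
  (n_R/n_node)G_R] per split onto the split feature, averaged over trees
  and normalized to sum 1.
* Randomness flows through splitmix64 substreams derived from
  (seed, tree index), so refits are bit-identical regardless of execution
  order.
* Diversity is reported as average individual-tree 0-1 error minus the
  voted ensemble 0-1 error on the evaluation set.

With uniform probabilities the algorithm is a standard random forest; the
test suite checks that its accuracy matches scikit-learn's
`RandomForestClassifier` with matched parameters within 3 points on the
default synthetic benchmark.

## Statistics

* AUC is the Mann–Whitney rank statistic (ties count ½), checked in the
  tests against exhaustive pairwise enumeration.
* AUPRC is average precision — the mean of the precision at each
  positive's rank in stable descending-score order — not the trapezoidal
  PR interpolation, which is over-optimistic.
* Wilcoxon signed-rank: zeros dropped, mid-ranks for ties; the null
  distribution of W⁺ is enumerated exactly (subset-sum DP over doubled
  ranks) for up to 25 nonzero differences, otherwise a tie-corrected
  normal approximation without continuity correction; two-sided p by
  doubling the smaller tail; p = 1 when all differences are zero.
* Friedman: within-row mid-ranks (higher metric → better/smaller rank),
  χ²_F = [12N/(m(m+1))]·Σ_j(R̄_j − (m+1)/2)², p from χ² with m−1 df.
* Bergmann–Hommel post-hoc for exactly three methods: pairwise z from
  average-rank differences, z = (R̄_i − R̄_j)/√(m(m+1)/(6N)); with three
  pairwise hypotheses the exhaustive sets are the full triple and each
  singleton (two equalities imply the third), so the adjustment scales
  the smallest raw p by 3, dominates the raw p-values and is monotone.

## Synthetic cohorts

The generator emulates the structure of restricted hospital ADE cohorts:
per (patient, code, window) the occurrence count is an independent
Poisson draw with mean `baseline_rate × (window days / 91)`, multiplied
by `effect_multiplier` for cases on the planted informative
(code, window) pairs; days are uniform within the window. Defaults: 600
patients, 30 % cases, 500 codes per event type (18 000 binned columns),
baseline_rate 0.3 (≈ 97 % zero cells, ~150 events per patient over 90
days), 20 informative pairs with rate ratio 3.

Informative pairs are planted in the month-scale windows 11–12 (days
31–90) by default. A design-time power analysis drove this choice: at
this cohort size, a day- or week-scale window carries so little baseline
mass (expected count ≤ 0.02 per patient) that a threefold rate increase
is statistically invisible, whereas the 30-day windows carry ~0.1
expected occurrences and the effect is reliably identifiable. This is
also the scientifically interesting regime: it is exactly where
recency-based reciprocal weights are smallest, i.e. where pre-assigned
weighting is most mismatched to true informativeness and learning
weights can help.

What the generator does **not** model: realistic code vocabularies and
their frequency skew, comorbidity correlations between codes, visit-level
clustering of events, over-dispersion, and time-varying baselines.
Passing tests therefore show that the method recovers planted
window-specific signal under independent sparse Poisson noise — not that
it will rank real clinical confounders correctly.

## Evaluation protocol and problem sizes

Stratified k-fold cross-validation deals shuffled class members
round-robin into folds with a pointer that continues across classes, so
fold sizes and per-fold class counts deviate from perfect balance by at
most one. The default protocol is 5 folds × 2 iterations. The package's
own benchmark experiments use desk-scale settings chosen once: 10
synthetic cohorts at the default configuration, 100-tree forests, and a
single 5-fold iteration; weight learning inside LWS/LWA folds uses the
same forest size as the final model. The statistical layer consumes
per-dataset means over folds.

## Degenerate inputs and numerical conventions

* All-zero weight vectors raise a degenerate-weights error rather than
  silently falling back to uniform.
* Split search requires a strictly positive decrease (> 1e-12) to avoid
  splitting on floating-point noise; nodes with no such candidate become
  leaves.
* Probability-tagged weight tables must sum to 1 within 1e-9 on read;
  weight CSVs store 17 significant digits so round trips are exact to
  double precision; forest JSON stores thresholds as hex floats for
  bit-exact round trips.
* Empty event tables are legal and produce all-zero feature rows;
  single-class label vectors are rejected everywhere modelling happens.

## Known limitations

* Binary classification only; no out-of-bag machinery, no permutation
  importance, no regression trees.
* Gini importance is the only weight-learning signal; biased toward
  high-cardinality features in general, though all features here are
  counts of similar cardinality.
* The Bergmann–Hommel implementation is specialized to three methods
  (the granularity comparison); larger method sets would need the general
  exhaustive-set enumeration.
* Dense matrices are used inside the forest for speed; cohorts far larger
  than the default (≫ 10⁴ patients × 10⁵ columns) would need a sparse
  node-evaluation path.
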