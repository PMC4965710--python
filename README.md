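# ehrweights

Temporal weighting of clinical events for adverse drug event (ADE)
detection in longitudinal electronic health records (EHRs).

ADEs are heavily under-reported in EHRs, and supervised classifiers can
flag records where an ADE should have been coded. The events feeding such
classifiers — diagnoses, drug administrations, clinical measurements — are
time-stamped, and *when* an event happened relative to the suspected ADE
matters. A common heuristic weights each event by recency, e.g. the
reciprocal w = f(n) = 1/n of the number of days *n* between the event and
the index event (same-day events get the maximum weight 1). This package
implements the alternative: **learning** a weight for every (event, time
window) pair from data, and applying the weights in two ways.

1. The 90-day history is split into 12 windows with upper boundaries at
   days 1, 2, 3, 4, 5, 6, 7, 14, 21, 30, 60, 90, and each (event code,
   window) pair becomes a separate occurrence-count feature (a *bag of
   binned events*).
2. A random forest with uniform feature sampling is fitted to this binned
   matrix, and each column's normalized Gini importance becomes its
   learned weight, optionally pooled to three granularity levels: per
   individual event (`all`), per event type per window (`type`), or per
   window (`time`).
3. The weights are applied either by **weighted aggregation** (collapse a
   code's windows into one feature via the weighted sum
   x_c = Σ_i w_{c,i} · count_{c,i}) or by **weighted sampling**: an
   enriched random forest in which the mtry candidate features at every
   tree node are drawn without replacement with probabilities
   proportional to the weights, so zero-importance features are never
   examined.

The four resulting strategies (PWA/LWA = pre-assigned/learned weights with
aggregation, PWS/LWS = with sampling) are compared under stratified 5-fold
cross-validation with accuracy, AUC and AUPRC, the tree-versus-ensemble
error decomposition (diversity = average individual-tree error − voted
ensemble error), and rank-based statistics: Wilcoxon signed-rank for
paired strategies, and the Friedman test with a Bergmann–Hommel post-hoc
for the three granularity levels.

Real ADE cohorts are ethics-restricted, so the package ships a synthetic
cohort generator that emulates their structure — thousands of sparse count
features, class imbalance, and a small set of planted informative
(code, window) pairs whose rate is multiplied in cases — which makes the
whole pipeline testable end to end with a known ground truth.

## Worked example

```python
from ehrweights import (SimulationConfig, generate_cohort, bin_events,
                        ForestParams, learn_event_weights, recovery_score,
                        stratified_cv, run_strategy, WindowGrid)

cfg = SimulationConfig(n_patients=300,
                       n_codes_per_type={"diagnosis": 100, "drug": 100,
                                         "measurement": 100},
                       n_informative=5, effect_multiplier=4.0, seed=7)
events, cohort, truth = generate_cohort(cfg)
bm = bin_events(events, cohort)
table = learn_event_weights(bm, cohort.labels, ForestParams(n_trees=300, seed=7))
print(recovery_score(table, truth, k=5))

plan = stratified_cv(cohort.labels, k=5, iterations=1, seed=7)
params = ForestParams(n_trees=100, seed=7)
for strategy, gran in (("PWS", "n/a"), ("LWS", "all")):
    df = run_strategy(strategy, gran, events, cohort, WindowGrid(), params, plan)
    print(strategy, df.accuracy.mean(), df.auc.mean(), df.auprc.mean())
```

Output (300 patients, 90 cases, 26 837 events, 300 × 2853 binned matrix
with 3 % nonzero cells):

```
  DIA0072 window 11  weight 0.0231 *
  MEA0013 window 12  weight 0.0182 *
  DIA0012 window 11  weight 0.0162 *
  MEA0084 window  9  weight 0.0118
  MEA0091 window 11  weight 0.0088 *
recovery@5: 0.80
PWS: acc 68.67%  AUC 0.594  AUPRC 0.415  diversity 0.052
LWS: acc 77.00%  AUC 0.791  AUPRC 0.695  diversity 0.085
```

Four of the five top learned weights (starred) are planted informative
pairs, and using them as sampling probabilities (LWS) clearly beats
recency-based pre-assigned sampling (PWS) — the planted signal sits in
the month-scale windows where the reciprocal weight is smallest.

## Command line

```bash
ehrweights simulate --config sim.yaml --out data/
ehrweights featurize --events data/events.csv --cohort data/cohort.csv --out feat/
ehrweights learn-weights --binned feat/binned.csv --cohort data/cohort.csv \
    --level all --seed 1 --out weights/
ehrweights evaluate --events data/events.csv --cohort data/cohort.csv \
    --strategy LWS --seed 1 --out eval/
ehrweights benchmark --config bench.yaml --out report/
```

Every run writes a `run_manifest.json` (config echo, seeds, version) so
it can be reproduced exactly.

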