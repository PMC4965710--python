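"""Evaluation harness: cross-validation, strategy pipelines, metrics and
rank-based statistical comparisons.

Four temporal-weighting strategies are evaluated under stratified k-fold
cross-validation (default 5 folds × 2 iterations):

* ``PWA`` — pre-assigned (reciprocal) weights, weighted aggregation;
* ``LWA`` — learned weights, weighted aggregation;
* ``PWS`` — pre-assigned window weights as feature-sampling probabilities;
* ``LWS`` — learned weights as feature-sampling probabilities.

Learned weights use the labels, so they are re-learned inside every
training fold; the pre-assigned strategies use no label information in
their weights.  Metrics are accuracy (%), AUC (probability that a random
case is ranked above a random control) and AUPRC (average precision),
plus the tree-versus-ensemble error decomposition.  Strategy comparisons
use the Wilcoxon signed-rank test (two strategies) or the Friedman test
with a Bergmann–Hommel post-hoc (three granularities); all tests are
two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ehr_data import CohortTable, EventTable
from .errors import StratificationError, ValidationError
from .synthetic_ehr import SimulationConfig, generate_cohort
from .temporal_features import (
    WindowGrid,
    aggregate_learned,
    aggregate_preassigned,
    bin_events,
)
from .weight_learning import (
    aggregate_weights,
    learn_event_weights,
    preassigned_window_weights,
    scale_for_aggregation,
    to_sampling_probs,
)
from .weighted_forest import ForestParams, WeightedRandomForestClassifier

STRATEGIES = ("PWA", "LWA", "PWS", "LWS")
GRANULARITIES = ("all", "type", "time")


@dataclass
class FoldPlan:
    """Stratified fold assignments: per iteration, a fold id per patient."""

    k: int
    iterations: int
    assignments: list[np.ndarray]
    seed: int

    def split(self, iteration: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for one (iteration, fold)."""
        fold_ids = self.assignments[iteration]
        test = np.flatnonzero(fold_ids == fold)
        train = np.flatnonzero(fold_ids != fold)
        return train, test


def stratified_cv(labels, k: int = 5, iterations: int = 2, seed: int = 0) -> FoldPlan:
    """Stratified fold plan: shuffle within class, deal round-robin into folds.

    Per-fold class counts deviate from perfect stratification by at most one.
    Deterministic given the seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise StratificationError(
                f"class {cls} has {(labels == cls).sum()} members, fewer than k={k}"
            )
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(iterations):
        fold_ids = np.empty(n, dtype=np.int64)
        pointer = 0  # continues across classes so fold sizes stay balanced
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            rng.shuffle(members)
            fold_ids[members] = (pointer + np.arange(len(members))) % k
            pointer = (pointer + len(members)) % k
        assignments.append(fold_ids)
    return FoldPlan(k=k, iterations=iterations, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(scores, labels) -> tuple[float, float, float]:
    """(accuracy %, AUC, AUPRC) from positive-class scores.

    Accuracy thresholds at score > 0.5 (a tie in the vote goes to the
    negative class).  AUC is the rank statistic
    ``(#concordant case-control pairs + ½·ties) / #pairs``.  AUPRC is
    average precision: the mean of the precision at each case's rank in
    descending-score order, ties broken by stable input order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute metrics")

    accuracy = 100.0 * float(((scores > 0.5).astype(np.int64) == labels).mean())

    ranks = stats.rankdata(scores)  # mid-ranks for ties
    auc = float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    hits = np.cumsum(sorted_labels)
    rank_idx = np.arange(1, len(labels) + 1)
    precision_at_pos = hits[sorted_labels == 1] / rank_idx[sorted_labels == 1]
    auprc = float(precision_at_pos.mean())
    return accuracy, auc, auprc


# ---------------------------------------------------------------------------
# strategy pipelines


def _fold_seed(base_seed: int, iteration: int, fold: int, salt: int = 0) -> int:
    return (base_seed * 1_000_003 + iteration * 101 + fold * 13 + salt) % (2**31)


def run_strategy(
    strategy: str,
    granularity: str,
    events: EventTable,
    cohort: CohortTable,
    grid: WindowGrid,
    params: ForestParams,
    plan: FoldPlan,
) -> pd.DataFrame:
    """Evaluate one strategy over a fold plan; one row per (iteration, fold).

    Learned-weight strategies (LWA/LWS) learn weights on the training fold's
    binned matrix only; ``granularity`` applies to them and is reported as
    ``n/a`` for the pre-assigned strategies.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy in ("LWA", "LWS") and granularity not in GRANULARITIES:
        raise ValidationError(f"unknown granularity {granularity!r}")
    labels = cohort.labels
    binned = bin_events(events, cohort, grid)
    if strategy == "PWA":
        X_pre = aggregate_preassigned(events, cohort, grid).to_dense()
    elif strategy == "PWS":
        probs_pre = to_sampling_probs(preassigned_window_weights(grid), binned.columns)
        X_bin = binned.to_dense()
    else:
        X_bin = binned.to_dense()

    rows = []
    for iteration in range(plan.iterations):
        for fold in range(plan.k):
            train, test = plan.split(iteration, fold)
            if len(np.unique(labels[train])) < 2 or len(np.unique(labels[test])) < 2:
                raise StratificationError(
                    f"iteration {iteration} fold {fold} has a single-class split"
                )
            seed = _fold_seed(params.seed, iteration, fold)
            fparams = ForestParams(
                params.n_trees, params.mtry, params.min_node_size, params.bootstrap, seed
            )

            if strategy == "PWA":
                X, probs = X_pre, None
            elif strategy == "PWS":
                X, probs = X_bin, probs_pre
            else:
                lparams = ForestParams(
                    params.n_trees,
                    params.mtry,
                    params.min_node_size,
                    params.bootstrap,
                    _fold_seed(params.seed, iteration, fold, salt=7),
                )
                table = learn_event_weights(
                    binned.row_subset(train), labels[train], lparams
                )
                table = aggregate_weights(table, granularity)
                if strategy == "LWS":
                    X = X_bin
                    probs = to_sampling_probs(table, binned.columns)
                else:  # LWA
                    scaled = scale_for_aggregation(table)
                    X = aggregate_learned(binned, scaled).to_dense()
                    probs = None

            forest = WeightedRandomForestClassifier(
                n_trees=fparams.n_trees,
                mtry=fparams.mtry,
                min_node_size=fparams.min_node_size,
                bootstrap=fparams.bootstrap,
                feature_probabilities=probs,
                random_state=fparams.seed,
            ).fit(X[train], labels[train])

            scores = forest.predict_proba(X[test])[:, 1]
            accuracy, auc, auprc = compute_metrics(scores, labels[test])
            avg_tree, ens, diversity = forest.decompose_error(X[test], labels[test])
            rows.append(
                {
                    "strategy": strategy,
                    "granularity": granularity if strategy in ("LWA", "LWS") else "n/a",
                    "iteration": iteration,
                    "fold": fold,
                    "accuracy": accuracy,
                    "auc": auc,
                    "auprc": auprc,
                    "avg_tree_error": avg_tree,
                    "ensemble_error": ens,
                    "diversity": diversity,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-based statistics


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The null distribution of W⁺ is enumerated exactly over all sign
    assignments when ≤ 25 nonzero differences remain, otherwise a normal
    approximation with tie correction (no continuity correction) is used.
    By convention the p-value is 1 when every difference is zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValidationError("paired vectors of equal length >= 1 required")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4
    if n <= 25:
        # exact: distribution of W+ over 2^n sign patterns via subset-sum DP
        # on doubled ranks (mid-ranks are multiples of 1/2)
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        dist = np.zeros(total + 1, dtype=np.float64)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(np.rint(2 * w_pos))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        return float(min(1.0, 2 * min(p_low, p_high)))
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    z = (w_pos - mean) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def friedman_test(results: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Friedman rank test over an N datasets × m methods matrix.

    Higher metric values are better and receive *smaller* (better) ranks;
    ties are mid-ranked.  Returns (χ²_F, p from χ²_{m−1}, average ranks).
    """
    results = np.asarray(results, dtype=np.float64)
    if results.ndim != 2 or results.shape[0] < 2 or results.shape[1] < 2:
        raise ValidationError("need an N>=2 by m>=2 results matrix")
    n, m = results.shape
    ranks = np.vstack([stats.rankdata(-row) for row in results])
    avg_ranks = ranks.mean(axis=0)
    chi2 = 12 * n / (m * (m + 1)) * float(((avg_ranks - (m + 1) / 2) ** 2).sum())
    p = float(stats.chi2.sf(chi2, df=m - 1)) if chi2 > 0 else 1.0
    return chi2, p, avg_ranks


def bergmann_hommel_posthoc(results: np.ndarray) -> dict[tuple[int, int], float]:
    """Bergmann–Hommel adjusted pairwise p-values after a Friedman test (m = 3).

    Pairwise z-statistics come from average-rank differences,
    ``z = (R̄_i − R̄_j) / sqrt(m(m+1)/(6N))``.  For three methods the
    exhaustive sets of simultaneously-true hypotheses are the full set of
    three pairwise hypotheses and each singleton (two equalities imply the
    third), giving adjusted p-values that dominate the raw ones and are
    monotone in them.
    """
    results = np.asarray(results, dtype=np.float64)
    if results.ndim != 2 or results.shape[1] != 3:
        raise ValidationError("the Bergmann-Hommel post-hoc is implemented for exactly 3 methods")
    n, m = results.shape
    _, _, avg_ranks = friedman_test(results)
    se = np.sqrt(m * (m + 1) / (6 * n))
    pairs = list(itertools.combinations(range(m), 2))
    raw = {}
    for i, j in pairs:
        z = (avg_ranks[i] - avg_ranks[j]) / se
        raw[(i, j)] = float(2 * stats.norm.sf(abs(z)))
    adj = bergmann_hommel_adjust([raw[p_] for p_ in pairs])
    return {pair: adj[h] for h, pair in enumerate(pairs)}


def bergmann_hommel_adjust(raw_p) -> list[float]:
    """Bergmann–Hommel adjustment of three pairwise raw p-values.

    With three methods the exhaustive sets of hypotheses that can hold
    simultaneously are the full set of three pairwise equalities and each
    singleton, so the smallest raw p is scaled by 3 while each hypothesis
    also competes with its own raw p; monotonicity in the raw ordering is
    enforced and values are capped at 1.
    """
    raw_p = list(map(float, raw_p))
    if len(raw_p) != 3:
        raise ValidationError("exactly 3 pairwise hypotheses expected")
    # exhaustive sets of hypothesis indices: {all three} and each singleton
    exhaustive = [(0, 1, 2), (0,), (1,), (2,)]
    v = [
        max(len(E) * min(raw_p[e] for e in E) for E in exhaustive if h in E)
        for h in range(3)
    ]
    order = sorted(range(3), key=lambda h: raw_p[h])
    adjusted = [0.0, 0.0, 0.0]
    running = 0.0
    for h in order:
        running = max(running, v[h])
        adjusted[h] = min(1.0, max(running, raw_p[h]))
    return adjusted


# ---------------------------------------------------------------------------
# benchmark harness


def make_benchmark_datasets(
    n_datasets: int, base_config: SimulationConfig | None = None, seed: int = 0
):
    """Generate a suite of synthetic cohorts differing only in their seed."""
    base_config = base_config or SimulationConfig()
    datasets = []
    for i in range(n_datasets):
        cfg_kwargs = {**base_config.__dict__, "seed": seed + 1000 * (i + 1)}
        cfg = SimulationConfig(**cfg_kwargs)
        events, cohort, truth = generate_cohort(cfg)
        datasets.append((f"synth{i:02d}", events, cohort, truth))
    return datasets


def benchmark(
    datasets,
    strategies,
    granularities,
    params: ForestParams,
    grid: WindowGrid | None = None,
    k: int = 5,
    iterations: int = 2,
    out_dir=None,
) -> dict:
    """Run strategies × granularities over a dataset suite and compare them.

    ``datasets`` is a sequence of (name, EventTable, CohortTable[, truth])
    tuples.  Returns a dict with the per-fold results, per-dataset summary,
    the tree-vs-ensemble error table, and the statistical comparisons:
    a Wilcoxon p per metric when exactly two arms are compared, a Friedman
    p plus Bergmann–Hommel adjusted pairwise p-values when three
    granularities are compared.  Writes CSV reports and a plain-text
    summary when ``out_dir`` is given.
    """
    grid = grid or WindowGrid()
    arms = []
    for strategy in strategies:
        if strategy in ("LWA", "LWS"):
            for g in granularities:
                arms.append((strategy, g))
        else:
            arms.append((strategy, "n/a"))
    if len(datasets) < 2 and len(arms) >= 2:
        raise ValidationError("statistical comparison requires at least 2 datasets")

    fold_frames = []
    for entry in datasets:
        name, events, cohort = entry[0], entry[1], entry[2]
        plan = stratified_cv(cohort.labels, k=k, iterations=iterations, seed=params.seed)
        for strategy, g in arms:
            df = run_strategy(strategy, g, events, cohort, grid, params, plan)
            df.insert(0, "dataset", name)
            fold_frames.append(df)
    folds = pd.concat(fold_frames, ignore_index=True)

    summary = (
        folds.groupby(["dataset", "strategy", "granularity"], sort=True)[
            ["accuracy", "auc", "auprc", "avg_tree_error", "ensemble_error", "diversity"]
        ]
        .mean()
        .reset_index()
    )
    diversity_table = (
        summary.groupby(["strategy", "granularity"], sort=True)[
            ["avg_tree_error", "ensemble_error", "diversity"]
        ]
        .mean()
        .reset_index()
    )

    statistics: list[dict] = []
    metrics = ("accuracy", "auc", "auprc")
    arm_names = [f"{s}/{g}" if g != "n/a" else s for s, g in arms]
    pivot = {}
    for (strategy, g), arm_name in zip(arms, arm_names):
        sub = summary[(summary["strategy"] == strategy) & (summary["granularity"] == g)]
        pivot[arm_name] = sub.set_index("dataset")
    if len(arms) == 2:
        a_name, b_name = arm_names
        for metric in metrics:
            a = pivot[a_name][metric].to_numpy()
            b = pivot[b_name][metric].to_numpy()
            statistics.append(
                {
                    "comparison": f"{a_name} vs {b_name}",
                    "metric": metric,
                    "test": "wilcoxon",
                    "p_value": wilcoxon_signed_rank(a, b),
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                }
            )
    elif len(arms) == 3:
        for metric in metrics:
            mat = np.column_stack([pivot[name][metric].to_numpy() for name in arm_names])
            chi2, p, avg_ranks = friedman_test(mat)
            statistics.append(
                {
                    "comparison": " vs ".join(arm_names),
                    "metric": metric,
                    "test": "friedman",
                    "p_value": p,
                    "chi2": chi2,
                    "avg_ranks": tuple(np.round(avg_ranks, 4)),
                }
            )
            adj = bergmann_hommel_posthoc(mat)
            for (i, j), ap in adj.items():
                statistics.append(
                    {
                        "comparison": f"{arm_names[i]} vs {arm_names[j]}",
                        "metric": metric,
                        "test": "bergmann-hommel",
                        "p_value": ap,
                    }
                )

    report = {
        "folds": folds,
        "summary": summary,
        "diversity": diversity_table,
        "statistics": pd.DataFrame(statistics),
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        folds.to_csv(out / "folds.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        diversity_table.to_csv(out / "diversity.csv", index=False)
        report["statistics"].to_csv(out / "statistics.csv", index=False)
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write("Benchmark summary (per-dataset means over folds)\n\n")
            fh.write(summary.to_string(index=False))
            fh.write("\n\nTree vs ensemble error (means over datasets)\n\n")
            fh.write(diversity_table.to_string(index=False))
            fh.write("\n\nStatistical comparisons\n\n")
            fh.write(report["statistics"].to_string(index=False))
            fh.write("\n")
    return report
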