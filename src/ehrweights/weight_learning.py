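"""Learning temporal weights from random-forest variable importance.

A forest with *uniform* candidate sampling is fitted on the bag-of-binned-
events matrix; the normalized Gini importance of each (event code, window)
column is its learned weight.  Weights can then be re-aggregated to three
granularity levels — per individual event (``all``), per event type per
window (``type``), per window (``time``) — and converted either into
candidate-sampling probabilities (weighted sampling) or into unit-interval
multipliers for window-collapsing aggregation (weighted aggregation).

Weight learning uses the labels, so within an evaluation protocol it must
run on training folds only.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ehr_data import WILDCARD, WeightTable
from .errors import DegenerateWeightsError, ValidationError
from .temporal_features import BinnedMatrix, WindowGrid, preassigned_weight
from .weighted_forest import ForestParams, WeightedRandomForestClassifier


class TemporalWeightLearner(BaseEstimator):
    """Learn per-(event, window) weights via Gini importance of a uniform forest.

    Parameters mirror :class:`WeightedRandomForestClassifier`; ``level``
    selects the granularity the learned table is aggregated to.

    Attributes
    ----------
    weight_table_ : WeightTable at the requested level.
    event_weight_table_ : WeightTable at level ``all`` (before aggregation).
    importances_ : ndarray, normalized Gini importance per binned column.
    """

    def __init__(
        self,
        level: str = "all",
        n_trees: int = 500,
        mtry: int | None = None,
        min_node_size: int = 1,
        bootstrap: bool = True,
        random_state: int = 0,
    ):
        self.level = level
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, binned: BinnedMatrix, y):
        if self.level not in ("all", "type", "time"):
            raise ValidationError(f"unknown granularity level {self.level!r}")
        forest = WeightedRandomForestClassifier(
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            bootstrap=self.bootstrap,
            feature_probabilities=None,  # uniform sampling for weight learning
            random_state=self.random_state,
        ).fit(binned.X, y)
        imp = forest.feature_importances_
        entries = {
            (code, window): float(imp[j])
            for j, (code, _etype, window) in enumerate(binned.columns)
        }
        code_types = {code: etype for code, etype, _ in binned.columns}
        self.importances_ = imp
        self.forest_ = forest
        self.event_weight_table_ = WeightTable(
            level="all",
            entries=entries,
            normalization_tag="raw_importance",
            code_types=code_types,
        )
        self.weight_table_ = aggregate_weights(self.event_weight_table_, self.level)
        return self

    def transform(self, binned: BinnedMatrix) -> np.ndarray:
        """Expanded per-column weights for ``binned``'s manifest."""
        check_is_fitted(self, "weight_table_")
        return expand_to_columns(self.weight_table_, binned.columns)


def learn_event_weights(binned: BinnedMatrix, labels, params: ForestParams) -> WeightTable:
    """Weights per individual (code, window) column = normalized Gini importance."""
    learner = TemporalWeightLearner(
        level="all",
        n_trees=params.n_trees,
        mtry=params.mtry,
        min_node_size=params.min_node_size,
        bootstrap=params.bootstrap,
        random_state=params.seed,
    ).fit(binned, labels)
    return learner.event_weight_table_


def aggregate_weights(table: WeightTable, target_level: str) -> WeightTable:
    """Re-aggregate an individual-event weight table to a coarser level.

    Group weights are arithmetic means of their member columns, which keeps
    all levels on a common scale; expanding a table back onto its columns
    preserves the overall mean weight.
    """
    if target_level not in ("all", "type", "time"):
        raise ValidationError(f"unknown granularity level {target_level!r}")
    if table.level != "all":
        if table.level == target_level:
            return table
        raise ValidationError(
            f"can only aggregate from level 'all', got {table.level!r}"
        )
    if target_level == "all":
        return table
    groups: dict[tuple[str, int], list[float]] = {}
    for (code, window), w in table.entries.items():
        if target_level == "type":
            try:
                key = table.code_types[code]
            except KeyError:
                raise ValidationError(
                    f"event type of code {code!r} is unknown; cannot aggregate to 'type'"
                ) from None
        else:
            key = WILDCARD
        groups.setdefault((key, window), []).append(w)
    entries = {k: float(np.mean(v)) for k, v in groups.items()}
    return WeightTable(
        level=target_level,
        entries=entries,
        normalization_tag=table.normalization_tag,
        code_types=dict(table.code_types),
    )


def expand_to_columns(table: WeightTable, columns: list[tuple[str, str, int]]) -> np.ndarray:
    """Per-column weight vector for a binned manifest (granularity expansion)."""
    from .errors import CoverageError

    w = np.empty(len(columns), dtype=np.float64)
    missing = []
    for j, (code, etype, window) in enumerate(columns):
        try:
            w[j] = table.weight_for(code, etype, window)
        except KeyError:
            missing.append((code, etype, window))
    if missing:
        raise CoverageError(missing)
    return w


def to_sampling_probs(
    table: WeightTable, binned_manifest: list[tuple[str, str, int]], floor: float = 0.0
) -> np.ndarray:
    """Convert weights into a feature-sampling probability vector.

    ``prob_c = (w_c + floor) / Σ(w + floor)``.  With the default floor of 0,
    zero-weight columns get probability 0 and are never sampled, honoring
    the convention that zero importance marks a useless or never-selected
    variable.
    """
    if floor < 0:
        raise ValidationError("floor must be >= 0")
    w = expand_to_columns(table, binned_manifest) + floor
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero and floor is 0")
    return w / total


def scale_for_aggregation(table: WeightTable) -> WeightTable:
    """Max-scale weights onto [0, 1] to mirror the pre-assigned weight range."""
    if not table.entries:
        raise DegenerateWeightsError("empty weight table")
    top = max(table.entries.values())
    if top <= 0:
        raise DegenerateWeightsError("all weights are zero; cannot scale")
    return WeightTable(
        level=table.level,
        entries={k: w / top for k, w in table.entries.items()},
        normalization_tag="unit_interval",
        code_types=dict(table.code_types),
    )


def preassigned_window_weights(grid: WindowGrid | None = None) -> WeightTable:
    """Window-level reciprocal weights for the pre-assigned sampling strategy.

    Each window's representative day is its upper boundary, so the weights
    are 1, 1/2, ..., 1/90 over the default grid and strictly decreasing.
    """
    grid = grid or WindowGrid()
    entries = {
        (WILDCARD, i + 1): preassigned_weight(b, grid.horizon)
        for i, b in enumerate(grid.boundaries)
    }
    return WeightTable(level="time", entries=entries, normalization_tag="unit_interval")
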