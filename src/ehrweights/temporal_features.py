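"""Temporal binning and feature construction.

The patient history (90 days before the index event by default) is segmented
into 12 time windows whose upper boundaries are days
1, 2, 3, 4, 5, 6, 7, 14, 21, 30, 60, 90.  Window *i* covers the half-open
day interval (boundary_{i-1}, boundary_i], with day 0 (same calendar day as
the index event) folded into window 1.  Treating each (event code, window)
pair as a separate count feature gives the bag-of-binned-events matrix;
collapsing windows with per-occurrence or per-window weights gives the
aggregated (bag-of-weighted-events) matrix.

Feature values are raw occurrence counts, never normalized per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ehr_data import CohortTable, EventTable, WeightTable
from .errors import CoverageError, ValidationError

DEFAULT_BOUNDARIES = (1, 2, 3, 4, 5, 6, 7, 14, 21, 30, 60, 90)


@dataclass(frozen=True)
class WindowGrid:
    """Ordered upper boundaries (in days) of the temporal windows."""

    boundaries: tuple[int, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) == 0 or b[0] < 1 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValidationError("window boundaries must be strictly increasing and start >= 1")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)

    @property
    def horizon(self) -> int:
        return self.boundaries[-1]

    def window_days(self, window: int) -> tuple[int, int]:
        """Inclusive (first, last) day offsets covered by 1-based ``window``."""
        lo = 0 if window == 1 else self.boundaries[window - 2] + 1
        return lo, self.boundaries[window - 1]


def assign_window(day_offset: int, grid: WindowGrid | None = None) -> int:
    """Map a day offset to its 1-based window index.

    Returns the smallest *i* with ``day_offset <= boundaries[i-1]``; day 0
    falls in window 1.
    """
    grid = grid or WindowGrid()
    if day_offset < 0 or day_offset > grid.horizon:
        raise ValidationError(f"day_offset {day_offset} outside [0, {grid.horizon}]")
    return int(np.searchsorted(grid.boundaries, day_offset, side="left")) + 1


def assign_windows(day_offsets: np.ndarray, grid: WindowGrid | None = None) -> np.ndarray:
    """Vectorized :func:`assign_window`."""
    grid = grid or WindowGrid()
    day_offsets = np.asarray(day_offsets)
    if day_offsets.size and (day_offsets.min() < 0 or day_offsets.max() > grid.horizon):
        raise ValidationError("day offsets outside the grid horizon")
    return np.searchsorted(grid.boundaries, day_offsets, side="left") + 1


def preassigned_weight(day_offset: int, horizon: int = 90) -> float:
    """Reciprocal temporal weight: 1 for day 0 (same-day convention), 1/n for n >= 1.

    Monotonically non-increasing in the day offset and bounded in (0, 1].
    """
    if day_offset < 0 or day_offset > horizon:
        raise ValidationError(f"day_offset {day_offset} outside [0, {horizon}]")
    return 1.0 if day_offset == 0 else 1.0 / day_offset


@dataclass
class BinnedMatrix:
    """Sparse patient × (code, type, window) occurrence-count matrix.

    Rows follow the cohort's patient order; columns are sorted by
    (code, type, window) and the order is deterministic.  Only nonzero cells
    are materialized (CSR storage).
    """

    patients: list[str]
    columns: list[tuple[str, str, int]]
    X: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense(), dtype=np.float64)

    def row_subset(self, indices: np.ndarray) -> "BinnedMatrix":
        return BinnedMatrix(
            [self.patients[i] for i in indices], self.columns, self.X[indices]
        )


@dataclass
class AggregatedMatrix:
    """Patient × (code, type) matrix with windows collapsed by weighted sums."""

    patients: list[str]
    columns: list[tuple[str, str]]
    X: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense(), dtype=np.float64)


def _check_patients(events: EventTable, cohort: CohortTable) -> dict[str, int]:
    row_of = {p: i for i, p in enumerate(cohort.patients)}
    if len(events):
        unknown = set(events.df["patient"]) - set(row_of)
        if unknown:
            raise ValidationError(
                f"events reference patients not in the cohort: {sorted(unknown)[:5]}"
            )
    return row_of


def bin_events(
    events: EventTable, cohort: CohortTable, grid: WindowGrid | None = None
) -> BinnedMatrix:
    """Build the bag-of-binned-events count matrix.

    ``cell[p, (c, t, i)]`` is the number of occurrences of code ``c`` for
    patient ``p`` whose day offset falls in window ``i``.  Patients without
    events get all-zero rows; the grand total of the matrix equals the number
    of event records.
    """
    grid = grid or WindowGrid()
    row_of = _check_patients(events, cohort)
    if len(events) == 0:
        return BinnedMatrix(cohort.patients, [], sp.csr_matrix((len(cohort), 0), dtype=np.int64))
    df = events.df
    windows = assign_windows(df["day_offset"].to_numpy(), grid)
    keys = pd.DataFrame(
        {"code": df["code"], "type": df["type"], "window": windows, "row": df["patient"].map(row_of)}
    )
    counts = keys.groupby(["code", "type", "window", "row"], sort=True).size()
    col_keys = sorted({(c, t, int(w)) for c, t, w, _ in counts.index})
    col_of = {k: j for j, k in enumerate(col_keys)}
    rows = np.fromiter((r for _, _, _, r in counts.index), dtype=np.int64, count=len(counts))
    cols = np.fromiter(
        (col_of[(c, t, int(w))] for c, t, w, _ in counts.index), dtype=np.int64, count=len(counts)
    )
    X = sp.csr_matrix(
        (counts.to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(cohort), len(col_keys)),
    )
    return BinnedMatrix(cohort.patients, col_keys, X)


def aggregate_preassigned(
    events: EventTable, cohort: CohortTable, grid: WindowGrid | None = None
) -> AggregatedMatrix:
    """Bag-of-weighted-events with reciprocal pre-assigned weights.

    Each occurrence contributes ``preassigned_weight(day_offset)`` — its exact
    day, not a window representative — to its (code, type) cell.
    """
    grid = grid or WindowGrid()
    row_of = _check_patients(events, cohort)
    if len(events) == 0:
        return AggregatedMatrix(
            cohort.patients, [], sp.csr_matrix((len(cohort), 0), dtype=np.float64)
        )
    df = events.df
    offs = df["day_offset"].to_numpy()
    if offs.min() < 0 or offs.max() > grid.horizon:
        raise ValidationError("day offsets outside the grid horizon")
    w = np.where(offs == 0, 1.0, 1.0 / np.maximum(offs, 1))
    keys = pd.DataFrame({"code": df["code"], "type": df["type"], "row": df["patient"].map(row_of)})
    keys["w"] = w
    sums = keys.groupby(["code", "type", "row"], sort=True)["w"].sum()
    col_keys = sorted({(c, t) for c, t, _ in sums.index})
    col_of = {k: j for j, k in enumerate(col_keys)}
    rows = np.fromiter((r for _, _, r in sums.index), dtype=np.int64, count=len(sums))
    cols = np.fromiter((col_of[(c, t)] for c, t, _ in sums.index), dtype=np.int64, count=len(sums))
    X = sp.csr_matrix(
        (sums.to_numpy(dtype=np.float64), (rows, cols)), shape=(len(cohort), len(col_keys))
    )
    return AggregatedMatrix(cohort.patients, col_keys, X)


def aggregate_learned(binned: BinnedMatrix, weights: WeightTable) -> AggregatedMatrix:
    """Collapse the binned matrix over windows with learned per-window weights.

    ``cell[p, (c, t)] = Σ_i weight(c, t, i) · count[p, (c, t, i)]``.  The
    weight table must address every binned column (after granularity
    expansion); weights are expected on the unit interval (max-scaled).
    """
    missing = []
    w = np.empty(len(binned.columns), dtype=np.float64)
    for j, (code, etype, window) in enumerate(binned.columns):
        try:
            w[j] = weights.weight_for(code, etype, window)
        except KeyError:
            missing.append((code, etype, window))
            w[j] = 0.0
    if missing:
        raise CoverageError(missing)
    agg_keys = sorted({(c, t) for c, t, _ in binned.columns})
    agg_of = {k: j for j, k in enumerate(agg_keys)}
    col_map = np.fromiter(
        (agg_of[(c, t)] for c, t, _ in binned.columns), dtype=np.int64, count=len(binned.columns)
    )
    # X_agg = X_binned · diag(w) · S, with S the (binned col → agg col) indicator
    n_b, n_a = len(binned.columns), len(agg_keys)
    S = sp.csr_matrix(
        (w, (np.arange(n_b), col_map)), shape=(n_b, n_a)
    )
    X = (binned.X.astype(np.float64) @ S).tocsr()
    return AggregatedMatrix(binned.patients, agg_keys, X)


# ---------------------------------------------------------------------------
# triplet CSV export of sparse matrices (external interface)


def write_sparse_matrix(matrix: BinnedMatrix | AggregatedMatrix, values_path, manifest_path) -> None:
    """Write a sparse matrix as triplets (patient, column index, value) plus a
    column manifest fixing the column order."""
    coo = matrix.X.tocoo()
    pd.DataFrame(
        {
            "patient": [matrix.patients[i] for i in coo.row],
            "column": coo.col,
            "value": coo.data,
        }
    ).to_csv(values_path, index=False)
    if matrix.columns and len(matrix.columns[0]) == 3:
        man = pd.DataFrame(matrix.columns, columns=["code", "type", "window"])
    else:
        man = pd.DataFrame(matrix.columns, columns=["code", "type"])
    man.insert(0, "column", np.arange(len(matrix.columns)))
    man.to_csv(manifest_path, index=False)


def read_binned_matrix(values_path, manifest_path, patients: list[str]) -> BinnedMatrix:
    man = pd.read_csv(manifest_path, dtype={"code": str, "type": str})
    columns = [(r.code, r.type, int(r.window)) for r in man.itertuples(index=False)]
    trip = pd.read_csv(values_path, dtype={"patient": str})
    row_of = {p: i for i, p in enumerate(patients)}
    unknown = set(trip["patient"]) - set(row_of)
    if unknown:
        raise ValidationError(f"triplet rows reference unknown patients: {sorted(unknown)[:5]}")
    X = sp.csr_matrix(
        (
            trip["value"].to_numpy(dtype=np.int64),
            (trip["patient"].map(row_of).to_numpy(), trip["column"].to_numpy(dtype=np.int64)),
        ),
        shape=(len(patients), len(columns)),
    )
    return BinnedMatrix(list(patients), columns, X)
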