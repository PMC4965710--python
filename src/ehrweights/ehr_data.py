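"""Domain data model and CSV readers/writers for event, cohort and weight tables.

The raw-data abstraction is deliberately small: a long-format table of
time-stamped clinical events per patient (diagnoses, drug administrations,
clinical measurements), a binary cohort label table (1 = case with the target
adverse drug event reported), and a table of temporal weights per
(event, time-window) at one of three granularity levels.

All files are comma-separated UTF-8 with a mandatory header row.  Day offsets
are integer days *before* the patient's index event; 0 means the same calendar
day.  Repeated (patient, code, day) rows are meaningful repeated occurrences
and are never deduplicated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

EVENT_TYPES = ("diagnosis", "drug", "measurement")
WEIGHT_LEVELS = ("all", "type", "time")
NORMALIZATION_TAGS = ("raw_importance", "unit_interval", "probability")

DEFAULT_HORIZON = 90

#: wildcard key used by window-level ("time") weight entries
WILDCARD = "*"


@dataclass(frozen=True)
class EventRecord:
    """One occurrence of a clinical event ``day_offset`` days before the index event."""

    patient_id: str
    event_code: str
    event_type: str
    day_offset: int


@dataclass
class EventTable:
    """Long-format table of time-stamped clinical events.

    Wraps a :class:`pandas.DataFrame` with columns
    ``patient, code, type, day_offset``; row order is preserved from the
    source and repetitions are kept.
    """

    df: pd.DataFrame
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_events(self.df, self.horizon)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[EventRecord]:
        for row in self.df.itertuples(index=False):
            yield EventRecord(row.patient, row.code, row.type, int(row.day_offset))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.horizon == other.horizon and self.df.equals(other.df)


@dataclass
class CohortTable:
    """Patient id → binary label (1 = case with the target ADE)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patients(self) -> list[str]:
        return list(self.df["patient"])

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=np.int64)

    @property
    def n_positive(self) -> int:
        return int(self.df["label"].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class WeightTable:
    """Temporal weights per (key, window) at a given granularity level.

    ``level`` selects what the key means: ``"all"`` — an individual event
    code; ``"type"`` — an event type; ``"time"`` — the wildcard ``"*"`` (one
    weight per time window).  ``code_types`` optionally records each code's
    event type for level ``"all"`` tables, which is required to re-aggregate
    them to the ``"type"`` level.
    """

    level: str
    entries: dict[tuple[str, int], float]
    normalization_tag: str = "raw_importance"
    code_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.level not in WEIGHT_LEVELS:
            raise ValidationError(f"unknown weight level {self.level!r}")
        if self.normalization_tag not in NORMALIZATION_TAGS:
            raise ValidationError(f"unknown normalization tag {self.normalization_tag!r}")
        for (key, window), w in self.entries.items():
            if w < 0:
                raise ValidationError(f"negative weight {w} for ({key!r}, window {window})")
            if self.level == "time" and key != WILDCARD:
                raise ValidationError(f"time-level entries must use the wildcard key, got {key!r}")
            if self.level == "type" and key not in EVENT_TYPES:
                raise ValidationError(f"type-level key {key!r} is not an event type")
        if self.normalization_tag == "unit_interval":
            for (key, window), w in self.entries.items():
                if w > 1.0:
                    raise ValidationError(
                        f"unit-interval weight {w} > 1 for ({key!r}, window {window})"
                    )
        if self.normalization_tag == "probability":
            total = float(sum(self.entries.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"probability weights sum to {total}, expected 1")

    def weight_for(self, code: str, event_type: str, window: int) -> float:
        """Weight addressed to the binned column (code, event_type, window)."""
        if self.level == "all":
            return self.entries[(code, window)]
        if self.level == "type":
            return self.entries[(event_type, window)]
        return self.entries[(WILDCARD, window)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightTable):
            return NotImplemented
        if (self.level, self.normalization_tag) != (other.level, other.normalization_tag):
            return False
        if set(self.entries) != set(other.entries):
            return False
        return all(
            abs(self.entries[k] - other.entries[k]) <= 1e-12 * max(1.0, abs(self.entries[k]))
            for k in self.entries
        ) and self.code_types == other.code_types


# ---------------------------------------------------------------------------
# validation helpers


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} file is missing required column {col!r}")


def _validate_events(df: pd.DataFrame, horizon: int) -> None:
    _require_columns(df, ("patient", "code", "type", "day_offset"), "event")
    offsets = df["day_offset"]
    if not np.issubdtype(offsets.dtype, np.integer):
        as_float = pd.to_numeric(offsets, errors="coerce")
        if as_float.isna().any() or (as_float % 1 != 0).any():
            bad = int(np.argmax(as_float.isna() | (as_float % 1 != 0)))
            raise ValidationError(f"row {bad}: day_offset must be an integer")
        df["day_offset"] = as_float.astype(np.int64)
        offsets = df["day_offset"]
    out = (offsets < 0) | (offsets > horizon)
    if out.any():
        bad = int(np.argmax(out.to_numpy()))
        raise ValidationError(
            f"row {bad}: day_offset {offsets.iloc[bad]} outside [0, {horizon}]"
        )
    if (df["code"].astype(str).str.len() == 0).any() or df["code"].isna().any():
        bad = int(np.argmax((df["code"].astype(str).str.len() == 0) | df["code"].isna()))
        raise ValidationError(f"row {bad}: empty event code")
    unknown = ~df["type"].isin(EVENT_TYPES)
    if unknown.any():
        bad = int(np.argmax(unknown.to_numpy()))
        raise ValidationError(
            f"row {bad}: unknown event type {df['type'].iloc[bad]!r}; "
            f"expected one of {EVENT_TYPES}"
        )


def _validate_cohort(df: pd.DataFrame) -> None:
    _require_columns(df, ("patient", "label"), "cohort")
    if df["patient"].duplicated().any():
        dup = df["patient"][df["patient"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate patient id {dup!r} in cohort table")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or ~labels.isin([0, 1]).all():
        bad = df["label"][labels.isna() | ~labels.isin([0, 1])].iloc[0]
        raise ValidationError(f"cohort label {bad!r} is not in {{0, 1}}")
    df["label"] = labels.astype(np.int64)


# ---------------------------------------------------------------------------
# readers / writers


def read_events(path, horizon: int = DEFAULT_HORIZON) -> EventTable:
    """Read a long-format event CSV (columns patient, code, type, day_offset)."""
    df = pd.read_csv(path, dtype={"patient": str, "code": str, "type": str})
    return EventTable(df, horizon=horizon)


def write_events(table: EventTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (columns patient, label; label ∈ {0,1}, 1 = ADE case)."""
    df = pd.read_csv(path, dtype={"patient": str})
    return CohortTable(df)


def write_cohort(table: CohortTable, path) -> None:
    table.df.to_csv(path, index=False)


_WEIGHT_META_PREFIX = "#normalization_tag="


def write_weight_table(table: WeightTable, path) -> None:
    """Write a weight CSV: one metadata line, then level,key,window,weight rows.

    Weights are written with 17 significant digits so the round trip is exact
    to double precision.  Level-``all`` tables additionally carry each code's
    event type in an ``event_type`` column when known.
    """
    buf = io.StringIO()
    buf.write(f"{_WEIGHT_META_PREFIX}{table.normalization_tag}\n")
    has_types = bool(table.code_types)
    cols = "level,key,window,weight" + (",event_type" if has_types else "")
    buf.write(cols + "\n")
    for (key, window), w in sorted(table.entries.items()):
        line = f"{table.level},{key},{window},{w:.17g}"
        if has_types:
            line += f",{table.code_types.get(key, '')}"
        buf.write(line + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_weight_table(path) -> WeightTable:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith(_WEIGHT_META_PREFIX):
            raise FormatError("weight file is missing the normalization_tag metadata line")
        tag = first[len(_WEIGHT_META_PREFIX):]
        df = pd.read_csv(fh, dtype={"key": str, "level": str})
    _require_columns(df, ("level", "key", "window", "weight"), "weight")
    if df.empty:
        raise FormatError("weight file has no entries")
    levels = df["level"].unique()
    if len(levels) != 1:
        raise ValidationError(f"weight file mixes levels {sorted(levels)}")
    entries = {
        (str(row.key), int(row.window)): float(row.weight)
        for row in df.itertuples(index=False)
    }
    code_types: dict[str, str] = {}
    if "event_type" in df.columns:
        code_types = {
            str(row.key): str(row.event_type)
            for row in df.itertuples(index=False)
            if isinstance(row.event_type, str) and row.event_type
        }
    return WeightTable(
        level=str(levels[0]),
        entries=entries,
        normalization_tag=tag,
        code_types=code_types,
    )


def cohort_from_arrays(patients, labels) -> CohortTable:
    return CohortTable(pd.DataFrame({"patient": list(patients), "label": list(labels)}))


def events_from_records(records, horizon: int = DEFAULT_HORIZON) -> EventTable:
    df = pd.DataFrame(
        [(r.patient_id, r.event_code, r.event_type, r.day_offset) for r in records],
        columns=["patient", "code", "type", "day_offset"],
    )
    if df.empty:
        df = df.astype({"patient": str, "code": str, "type": str, "day_offset": np.int64})
    return EventTable(df, horizon=horizon)
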