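"""Patient-level data model, censoring semantics and delimited-file I/O.

A cohort is a collection of women treated surgically for early invasive breast
cancer, followed until first recurrence (local, metastatic or a second primary
— one composite end point), death from an unrelated cause, or loss to
follow-up.  Death without recurrence and loss to follow-up are both plain
right-censoring on the recurrence time scale.  Times are stored in days; a
year is 365.25 days for reporting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ER",
    "Event",
    "HorizonStatus",
    "PatientRecord",
    "Cohort",
    "DAYS_PER_YEAR",
    "read_cohort",
    "write_cohort",
    "horizon_status",
]

DAYS_PER_YEAR = 365.25

#: canonical CSV column order
COLUMNS = [
    "id", "age", "nodes", "grade", "size_cm", "er",
    "radiotherapy", "hormone", "chemo", "time_days", "event",
]


class ER(enum.Enum):
    POSITIVE = "pos"
    NEGATIVE = "neg"
    MISSING = ""


class Event(enum.IntEnum):
    CENSORED = 0
    RECURRENCE = 1


class HorizonStatus(enum.Enum):
    """Recurrence status of a patient at a fixed horizon."""

    EVENT_BY_HORIZON = "event_by_horizon"
    EVENT_FREE_AT_HORIZON = "event_free_at_horizon"
    UNOBSERVABLE = "unobservable"


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class RowParseError(ValueError):
    """A row failed numeric parsing or violated a record invariant."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class PatientRecord:
    """One woman's prognostic factors, adjuvant treatments and follow-up.

    ``time_days`` counts from initial surgery to first recurrent event or
    censoring.  Treatment indicators are ``True``/``False`` or ``None`` when
    unrecorded; ER is a tri-state.  Missing values are preserved as missing —
    imputation is an explicit upstream step, never a side effect of I/O.
    """

    id: str
    age: float
    nodes: int
    grade: int
    size_cm: float
    er: ER
    radiotherapy: bool | None
    hormone: bool | None
    chemo: bool | None
    time_days: float
    event: Event

    def __post_init__(self) -> None:
        if not (self.age > 0):
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.nodes < 0:
            raise ValueError(f"nodes must be >= 0, got {self.nodes}")
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be in {{1,2,3}}, got {self.grade}")
        if not (self.size_cm > 0):
            raise ValueError(f"size_cm must be > 0, got {self.size_cm}")
        if not (self.time_days > 0):
            raise ValueError(f"time_days must be > 0, got {self.time_days}")

    @property
    def time_years(self) -> float:
        return self.time_days / DAYS_PER_YEAR

    def with_(self, **kw) -> "PatientRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def n_events(self) -> int:
        return sum(r.event is Event.RECURRENCE for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (missing cells as NA / empty ER)."""
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id,
                "age": r.age,
                "nodes": r.nodes,
                "grade": r.grade,
                "size_cm": r.size_cm,
                "er": r.er.value,
                "radiotherapy": _bool_out(r.radiotherapy),
                "hormone": _bool_out(r.hormone),
                "chemo": _bool_out(r.chemo),
                "time_days": r.time_days,
                "event": int(r.event),
            })
        return pd.DataFrame(rows, columns=COLUMNS)


def _bool_out(v: bool | None):
    return "" if v is None else int(v)


def _parse_bool(cell, row: int, col: str) -> bool | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    s = str(cell).strip().lower()
    if s in ("1", "1.0", "true", "yes"):
        return True
    if s in ("0", "0.0", "false", "no"):
        return False
    raise RowParseError(row, f"cannot parse {col}={cell!r} as a binary indicator")


def _parse_er(cell) -> ER:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ER.MISSING
    s = str(cell).strip().lower()
    if s in ("", "nan"):
        return ER.MISSING
    if s in ("pos", "positive", "+"):
        return ER.POSITIVE
    if s in ("neg", "negative", "-"):
        return ER.NEGATIVE
    raise ValueError(f"cannot parse ER value {cell!r}")


def _parse_float(cell, row: int, col: str) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise RowParseError(row, f"non-numeric {col}={cell!r}") from None


def read_cohort(path, dialect: Mapping[str, str] | None = None, name: str | None = None) -> Cohort:
    """Read a cohort from a delimited file.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    dialect : mapping, optional
        Maps canonical column names (``id``, ``age``, ``nodes``, ``grade``,
        ``size_cm``, ``er``, ``radiotherapy``, ``hormone``, ``chemo``,
        ``time_days``, ``event``) to the file's actual headers.  Columns not
        mentioned keep their canonical name.  Extra file columns (for example
        an event-subtype annotation) are ignored by all computations.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in COLUMNS}
    if dialect:
        colmap.update(dialect)
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"required column {actual!r} (for {canon!r}) missing from {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            rec = PatientRecord(
                id=str(row[colmap["id"]]),
                age=_parse_float(row[colmap["age"]], i, "age"),
                nodes=int(_parse_float(row[colmap["nodes"]], i, "nodes")),
                grade=int(_parse_float(row[colmap["grade"]], i, "grade")),
                size_cm=_parse_float(row[colmap["size_cm"]], i, "size_cm"),
                er=_parse_er(row[colmap["er"]]),
                radiotherapy=_parse_bool(row[colmap["radiotherapy"]], i, "radiotherapy"),
                hormone=_parse_bool(row[colmap["hormone"]], i, "hormone"),
                chemo=_parse_bool(row[colmap["chemo"]], i, "chemo"),
                time_days=_parse_float(row[colmap["time_days"]], i, "time_days"),
                event=Event(int(_parse_float(row[colmap["event"]], i, "event"))),
            )
        except RowParseError:
            raise
        except ValueError as e:
            raise RowParseError(i, str(e)) from e
        records.append(rec)
    return Cohort(records, name=name or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as canonical CSV; read_cohort round-trips it losslessly."""
    cohort.to_frame().to_csv(path, index=False)


def horizon_status(record: PatientRecord, horizon: float) -> HorizonStatus:
    """Classify a patient's recurrence status at a fixed horizon (days).

    A recurrence on or before the horizon is an event; any patient still under
    observation at the horizon (follow-up time >= horizon with no earlier
    event) is event-free at it; a patient censored strictly before the horizon
    has unobservable status — all such women were recurrence free when last
    seen, but their status at the horizon is unknown.
    """
    if not (horizon > 0):
        raise ValueError("horizon must be > 0")
    if record.event is Event.RECURRENCE and record.time_days <= horizon:
        return HorizonStatus.EVENT_BY_HORIZON
    if record.time_days >= horizon:
        return HorizonStatus.EVENT_FREE_AT_HORIZON
    return HorizonStatus.UNOBSERVABLE
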