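"""Cohort data model and CSV interchange.

A cohort is a set of subjects, their longitudinal anthropometry points
(stature in cm, weight in kg, head circumference in cm) and their
treatment / neurosurgery events.  Ages are stored in days; curve grids
are indexed in months using a fixed mean-Gregorian-month conversion so
that monthly grids are reproducible regardless of calendar dates.

Interchange format
------------------
* cohort CSV: one row per measurement with subject metadata repeated —
  columns ``subject_id, sex, gestational_age_weeks, birth_decade,
  measure, age_days, value, position``;
* events CSV: ``subject_id, event_kind, age_days``;
* reference-table CSV: one row per grid point with columns
  ``index, mean, sd_upper, sd_lower, p5, p25, p50, p75, p95`` preceded
  by a ``#`` metadata line carrying sex / measure / index kind.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvariantError, LinkageError, SchemaError

DAYS_PER_MONTH = 30.4375  # mean Gregorian month

SEXES = ("male", "female")
MEASURES = ("stature", "weight", "head_circumference")
POSITIONS = ("supine", "standing", "unknown")
DECADES = ("pre1980", "1980s", "1990s", "2000s", "2010s")
TREATMENT_KINDS = ("limb_lengthening", "growth_hormone", "pharma_trial")
NEURO_KINDS = ("cmd", "shunt")
PERCENTILE_LEVELS = (5, 25, 50, 75, 95)

POINT_COLUMNS = [
    "subject_id", "sex", "gestational_age_weeks", "birth_decade",
    "measure", "age_days", "value", "position",
]
EVENT_COLUMNS = ["subject_id", "event_kind", "age_days"]


def age_days_to_months(age_days) -> np.ndarray:
    return np.asarray(age_days, dtype=float) / DAYS_PER_MONTH


def age_months_to_days(age_months) -> np.ndarray:
    return np.asarray(age_months, dtype=float) * DAYS_PER_MONTH


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject; gestational age is NaN when unknown."""

    subject_id: str
    sex: str
    gestational_age_weeks: float = float("nan")
    birth_decade: str | None = None
    treatment_events: tuple = ()   # (kind, age_days)
    neuro_events: tuple = ()       # (kind, age_days)

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise InvariantError(f"{self.subject_id}: bad sex {self.sex!r}")
        ga = self.gestational_age_weeks
        if np.isfinite(ga) and not (20.0 <= ga <= 45.0):
            raise InvariantError(
                f"{self.subject_id}: gestational age {ga} outside [20, 45] weeks"
            )
        if self.birth_decade is not None and self.birth_decade not in DECADES:
            raise InvariantError(
                f"{self.subject_id}: bad birth decade {self.birth_decade!r}"
            )
        for kind, age in self.treatment_events:
            if kind not in TREATMENT_KINDS or age < 0:
                raise InvariantError(f"{self.subject_id}: bad treatment event {kind}@{age}")
        for kind, age in self.neuro_events:
            if kind not in NEURO_KINDS or age < 0:
                raise InvariantError(f"{self.subject_id}: bad neuro event {kind}@{age}")


@dataclass(frozen=True)
class AnthroPoint:
    """A single measurement of one type on one subject at one age."""

    subject_id: str
    measure: str
    age_days: float
    value: float
    position: str | None = None  # stature only

    def validate(self) -> None:
        if self.measure not in MEASURES:
            raise InvariantError(f"bad measure {self.measure!r}")
        if not self.value > 0:
            raise InvariantError(f"{self.subject_id}: non-positive value {self.value}")
        if self.age_days < 0:
            raise InvariantError(f"{self.subject_id}: negative age {self.age_days}")
        if self.measure != "stature" and self.position is not None:
            raise InvariantError("position is meaningful only for stature")


@dataclass
class Cohort:
    """Subjects + measurement points + events, as aligned DataFrames.

    ``subjects`` — one row per subject_id (sex, gestational_age_weeks,
    birth_decade); ``points`` — POINT_COLUMNS minus the metadata that
    lives on subjects; ``events`` — EVENT_COLUMNS.
    """

    subjects: pd.DataFrame
    points: pd.DataFrame
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        self.events = self.events.reindex(columns=EVENT_COLUMNS)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.subjects["subject_id"].duplicated().any():
            dup = self.subjects.loc[self.subjects["subject_id"].duplicated(), "subject_id"]
            raise InvariantError(f"duplicate subject ids: {sorted(set(dup))}")
        known = set(self.subjects["subject_id"])
        for name, frame in (("points", self.points), ("events", self.events)):
            if len(frame):
                orphan = set(frame["subject_id"]) - known
                if orphan:
                    raise LinkageError(
                        f"{name} reference unknown subject ids: {sorted(orphan)[:5]}"
                    )
        if len(self.points):
            if (self.points["value"] <= 0).any():
                bad = self.points.index[self.points["value"] <= 0][:5].tolist()
                raise InvariantError(f"non-positive measurement values at rows {bad}")
            if (self.points["age_days"] < 0).any():
                bad = self.points.index[self.points["age_days"] < 0][:5].tolist()
                raise InvariantError(f"negative ages at rows {bad}")
        if len(self.events) and (self.events["age_days"] < 0).any():
            raise InvariantError("negative event ages")

    def n_subjects(self) -> int:
        return len(self.subjects)

    def n_points(self) -> int:
        return len(self.points)

    def sorted_points(self) -> pd.DataFrame:
        """Points sorted per subject per measure by age (stable)."""
        return self.points.sort_values(
            ["subject_id", "measure", "age_days"], kind="mergesort"
        ).reset_index(drop=True)

    def merged_points(self) -> pd.DataFrame:
        """Points joined with subject metadata (sex, GA, decade)."""
        return self.points.merge(self.subjects, on="subject_id", how="left")

    def copy(self) -> "Cohort":
        return Cohort(self.subjects.copy(), self.points.copy(), self.events.copy())


@dataclass
class ReferenceTable:
    """Per-grid-point mean, upper/lower SD and smoothed percentiles.

    ``data`` columns: ``index, mean, sd_upper, sd_lower, p5, p25, p50,
    p75, p95``, one row per grid point.  For symmetric measures
    ``sd_upper == sd_lower``.
    """

    sex: str
    measure: str
    index_kind: str  # "age_months" | "height_cm"
    data: pd.DataFrame

    PCT_COLS = [f"p{v}" for v in PERCENTILE_LEVELS]
    COLUMNS = ["index", "mean", "sd_upper", "sd_lower"] + PCT_COLS

    def validate(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"reference table missing columns {missing}")
        grid = self.data["index"].to_numpy(float)
        if len(grid) == 0:
            raise InvariantError("empty reference table")
        if not np.all(np.diff(grid) > 0):
            i = int(np.flatnonzero(np.diff(grid) <= 0)[0])
            raise InvariantError(f"grid not strictly ascending at index {grid[i + 1]}")
        pct = self.data[self.PCT_COLS].to_numpy(float)
        bad = np.diff(pct, axis=1) <= 0
        if bad.any():
            row = int(np.argwhere(bad)[0][0])
            raise InvariantError(
                f"percentiles not strictly increasing at grid point {grid[row]}"
            )
        if (self.data[["sd_upper", "sd_lower"]].to_numpy(float) <= 0).any():
            raise InvariantError("non-positive SD values in reference table")

    @property
    def grid(self) -> np.ndarray:
        return self.data["index"].to_numpy(float)


# ----------------------------------------------------------------------
# cohort CSV I/O
# ----------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns {missing}")


def read_cohort(path, events_path=None, schema: dict | None = None) -> Cohort:
    """Read a cohort CSV (and optional events CSV) into a validated Cohort.

    ``schema`` maps required column names to the names actually used in
    the file.  Rows failing type checks are reported (with 1-based data
    row numbers) in a single SchemaError rather than silently dropped.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _check_columns(df, POINT_COLUMNS[:-1], "cohort CSV")  # position optional
    if "position" not in df.columns:
        df["position"] = np.nan

    problems: list[str] = []
    for col in ("age_days", "value", "gestational_age_weeks"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        for i in df.index[bad]:
            problems.append(f"row {i + 1}: unparseable {col} {df.at[i, col]!r}")
        df[col] = coerced
    for i in df.index[~df["sex"].isin(SEXES)]:
        problems.append(f"row {i + 1}: bad sex {df.at[i, 'sex']!r}")
    for i in df.index[~df["measure"].isin(MEASURES)]:
        problems.append(f"row {i + 1}: bad measure {df.at[i, 'measure']!r}")
    numeric_ok = df["value"].notna() & df["age_days"].notna()
    for i in df.index[numeric_ok & (df["value"] <= 0)]:
        problems.append(f"row {i + 1}: non-positive value {df.at[i, 'value']}")
    for i in df.index[numeric_ok & (df["age_days"] < 0)]:
        problems.append(f"row {i + 1}: negative age {df.at[i, 'age_days']}")
    if problems:
        raise SchemaError("cohort CSV has invalid rows:\n" + "\n".join(problems[:50]))

    meta_cols = ["subject_id", "sex", "gestational_age_weeks", "birth_decade"]
    subjects = df[meta_cols].drop_duplicates(subset="subject_id").reset_index(drop=True)
    conflicting = df[meta_cols].drop_duplicates()
    if len(conflicting) != len(subjects):
        raise SchemaError("inconsistent subject metadata across rows")

    points = df[["subject_id", "measure", "age_days", "value", "position"]].copy()

    if events_path is not None:
        events = pd.read_csv(events_path, dtype={"subject_id": str},
                             float_precision="round_trip")
        _check_columns(events, EVENT_COLUMNS, "events CSV")
        events = events[EVENT_COLUMNS]
        orphan = set(events["subject_id"]) - set(subjects["subject_id"])
        if orphan:
            raise LinkageError(f"events reference unknown subjects: {sorted(orphan)[:5]}")
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    cohort = Cohort(subjects, points, events)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path, events_path=None) -> None:
    cohort.validate()
    df = cohort.points.merge(cohort.subjects, on="subject_id", how="left")
    df = df[POINT_COLUMNS]
    # default (shortest round-trip) float repr + the round_trip parser in
    # read_cohort keeps write -> read bit-exact
    df.to_csv(path, index=False)
    if events_path is not None:
        cohort.events.to_csv(events_path, index=False)


# ----------------------------------------------------------------------
# reference-table CSV I/O
# ----------------------------------------------------------------------

def write_reference_table(table: ReferenceTable, path) -> None:
    """Write a validated reference table with >= 6 significant digits."""
    table.validate()
    buf = io.StringIO()
    buf.write(
        f"# sex={table.sex} measure={table.measure} index_kind={table.index_kind}\n"
    )
    table.data[ReferenceTable.COLUMNS].to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_reference_table(path) -> ReferenceTable:
    meta = {"sex": "unknown", "measure": "unknown", "index_kind": "age_months"}
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise SchemaError(f"{path}: empty reference-table file")
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k in meta:
                        meta[k] = v
        else:
            break
    body = "\n".join(lines[body_start:])
    try:
        df = pd.read_csv(io.StringIO(body))
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no tabular data in reference-table file")
    _check_columns(df, ReferenceTable.COLUMNS, "reference-table CSV")
    if len(df) == 0:
        raise SchemaError(f"{path}: reference table has a header but no rows")
    table = ReferenceTable(meta["sex"], meta["measure"], meta["index_kind"], df)
    table.validate()
    return table
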