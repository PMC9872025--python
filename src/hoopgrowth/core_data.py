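"""Domain types, table I/O and validation for longitudinal athlete testing records.

The central container is :class:`ObservationTable`, a thin wrapper over a tidy
:class:`pandas.DataFrame` with one row per player x assessment occasion.  Each
row carries anthropometry (stature in cm, body mass in kg), the self-reported
specialization-onset age, and three basketball-specific fitness tests:
countermovement jump (cm), line-drill time (s) and yo-yo IR1 distance (m).
Any outcome may be missing on any occasion; missingness is preserved, never
imputed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("female", "male")
PHASES = ("pre", "mid", "end")
PHASE_ORDER = {p: i for i, p in enumerate(PHASES)}
AGE_GROUPS = ("U13", "U15", "U17")

#: shuttle length of one out-and-back yo-yo IR1 bout (2 x 20 m)
YOYO_SHUTTLE_M = 40.0

#: canonical column names and dtypes of the tidy observation schema
SCHEMA: dict[str, str] = {
    "player_id": "string",
    "sex": "string",
    "birth_date": "date",
    "assessment_date": "date",
    "chronological_age": "float",
    "season_year": "int",
    "phase": "string",
    "age_group": "string",
    "stature": "float",
    "body_mass": "float",
    "specialization_onset_age": "float",
    "cmj": "float",
    "line_drill": "float",
    "yoyo_ir1": "float",
}

MANDATORY_COLUMNS = ("player_id", "sex", "phase")
NUMERIC_COLUMNS = (
    "chronological_age",
    "stature",
    "body_mass",
    "specialization_onset_age",
    "cmj",
    "line_drill",
    "yoyo_ir1",
)
MISSING_MARKERS = ("", "NA", "N/A")

#: default mapping from file headers onto the schema (identity); user-configurable
DEFAULT_COLUMN_MAP: dict[str, str] = {name: name for name in SCHEMA}


class SchemaError(ValueError):
    """A delimited file does not provide the mandatory columns."""


@dataclasses.dataclass
class ObservationTable:
    """Tidy longitudinal records of players x occasions.

    Parameters
    ----------
    df
        One row per (player_id, season_year, phase) with the columns of
        :data:`SCHEMA` (missing optional columns are added as all-missing).
    provenance
        Free-text origin note, e.g. ``"synthetic"`` or the source file path.
    """

    df: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, kind in SCHEMA.items():
            if col not in df.columns:
                df[col] = pd.NA
            if kind == "float":
                df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
            elif kind == "int":
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
            elif kind == "string":
                df[col] = df[col].astype("string")
        self.df = df[list(SCHEMA)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.df.copy(), self.provenance)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def players(self) -> pd.Index:
        return pd.Index(self.df["player_id"].dropna().unique())


@dataclasses.dataclass
class ValidationIssue:
    rule: str
    severity: str  # "error" | "warning"
    rows: list[int]
    message: str


@dataclasses.dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rule": i.rule,
                    "severity": i.severity,
                    "n_rows": len(i.rows),
                    "message": i.message,
                }
                for i in self.issues
            ],
            columns=["rule", "severity", "n_rows", "message"],
        )


def decimal_age(birth_date: _dt.date, test_date: _dt.date) -> float:
    """Chronological age in decimal years from calendar dates.

    Ages are conventionally reported to the nearest 0.1 years; this returns
    the unrounded value and callers round for display.
    """
    return (test_date - birth_date).days / 365.25


def derive_age_group(birth_year: int, season_year: int) -> str:
    """Competition age group from the age attained during the season's calendar year.

    A player completing 13 years (or fewer) in the season year is under-13,
    one completing 14 or 15 is under-15, and 16 or 17 is under-17.
    """
    attained = season_year - birth_year
    if attained < 9:
        raise ValueError(
            f"implausible input: age attained in season year is {attained} (< 9)"
        )
    if attained > 17:
        raise ValueError(
            f"age attained in season year is {attained}: outside the scope of "
            "youth competition age groups (U13/U15/U17)"
        )
    if attained <= 13:
        return "U13"
    if attained <= 15:
        return "U15"
    return "U17"


def _read_delimited(path: str | Path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_MARKERS),
        skipinitialspace=True,
    )


def load_observations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> ObservationTable:
    """Read a delimited observation file into an :class:`ObservationTable`.

    Parameters
    ----------
    path
        CSV (or other delimited text) file with a header row.
    column_map
        Mapping from schema names to file header names.  Defaults to the
        identity mapping (:data:`DEFAULT_COLUMN_MAP`).
    delimiter
        Field separator; default comma.

    Unparseable numeric cells become missing with a warning rather than
    silent zeros.  A missing mandatory column (player_id, sex, phase, and
    at least one of chronological_age / birth_date) raises
    :class:`SchemaError` naming the columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = _read_delimited(path, delimiter)

    missing = [c for c in MANDATORY_COLUMNS if cmap[c] not in raw.columns]
    has_age = cmap["chronological_age"] in raw.columns
    has_bd = cmap["birth_date"] in raw.columns
    if not (has_age or has_bd):
        missing.append("chronological_age|birth_date")
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    data: dict[str, pd.Series] = {}
    for name in SCHEMA:
        src = cmap[name]
        if src in raw.columns:
            data[name] = raw[src]
        else:
            data[name] = pd.Series([pd.NA] * len(raw), dtype="string")
    df = pd.DataFrame(data)

    for col in NUMERIC_COLUMNS + ("season_year",):
        given = df[col].notna()
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = given & parsed.isna()
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} unparseable value(s) in column '{col}' "
                f"set to missing (rows {list(df.index[bad])})",
                stacklevel=2,
            )
        df[col] = parsed

    for col in ("birth_date", "assessment_date"):
        if df[col].notna().any():
            df[col] = pd.to_datetime(df[col], errors="coerce").dt.date

    # dates take precedence over a stored decimal age: when both calendar
    # dates are present the age is recomputed from them, with a warning if it
    # disagrees with the stored value by more than 0.1 y
    both = df["birth_date"].notna() & df["assessment_date"].notna()
    if both.any():
        recomputed = pd.Series(
            [decimal_age(b, t) for b, t in zip(df.loc[both, "birth_date"],
                                               df.loc[both, "assessment_date"])],
            index=df.index[both], dtype=float)
        stored = df.loc[both, "chronological_age"]
        conflict = stored.notna() & ((stored - recomputed).abs() > 0.1)
        if conflict.any():
            warnings.warn(
                f"{int(conflict.sum())} row(s) where the stored decimal age "
                "differs from the date-derived age by more than 0.1 y; "
                "dates take precedence",
                stacklevel=2,
            )
        df.loc[both, "chronological_age"] = recomputed

    return ObservationTable(df, provenance=str(path))


def validate_table(table: ObservationTable) -> ValidationReport:
    """Check every schema invariant; never raises, always reports.

    Range violations, non-positive times, duplicated occasions and
    inconsistent player sex are errors; a yo-yo distance that is not a
    multiple of the 40 m shuttle is only a warning since recording
    granularity varies between testers.
    """
    df = table.df
    issues: list[ValidationIssue] = []

    def check(mask: pd.Series, rule: str, severity: str, message: str) -> None:
        rows = list(df.index[mask.fillna(False)])
        if rows:
            issues.append(ValidationIssue(rule, severity, rows, message))

    age = df["chronological_age"]
    check(age.notna() & ~age.between(8, 20), "age_range", "error",
          "chronological_age outside [8, 20] years")
    check(df["stature"].notna() & ~df["stature"].between(120, 220),
          "stature_range", "error", "stature outside [120, 220] cm")
    check(df["body_mass"].notna() & ~df["body_mass"].between(25, 130),
          "body_mass_range", "error", "body_mass outside [25, 130] kg")
    check(df["line_drill"].notna() & (df["line_drill"] <= 0),
          "line_drill_positive", "error", "line_drill must be strictly positive")
    check(df["yoyo_ir1"].notna() & (df["yoyo_ir1"] < 0),
          "yoyo_nonnegative", "error", "yoyo_ir1 must be non-negative")
    yy = df["yoyo_ir1"]
    frac = (yy / YOYO_SHUTTLE_M) % 1.0
    check(yy.notna() & (np.minimum(frac, 1.0 - frac) > 1e-9),
          "yoyo_granularity", "warning",
          f"yoyo_ir1 not a multiple of the {YOYO_SHUTTLE_M:.0f} m shuttle")
    onset = df["specialization_onset_age"]
    check(onset.notna() & ~onset.between(3, 18), "onset_range", "error",
          "specialization_onset_age outside [3, 18] years")
    check(df["sex"].notna() & ~df["sex"].isin(SEXES), "sex_labels", "error",
          f"sex not in {SEXES}")
    check(df["phase"].notna() & ~df["phase"].isin(PHASES), "phase_labels", "error",
          f"phase not in {PHASES}")
    check(df["age_group"].notna() & ~df["age_group"].isin(AGE_GROUPS),
          "age_group_labels", "error", f"age_group not in {AGE_GROUPS}")

    key = ["player_id", "season_year", "phase"]
    complete = df[key].notna().all(axis=1)
    dup = df.duplicated(subset=key, keep=False) & complete
    check(dup, "occasion_unique", "error",
          "duplicated (player_id, season_year, phase) occasion")

    sex_counts = df.dropna(subset=["player_id", "sex"]).groupby("player_id")["sex"].nunique()
    bad_players = set(sex_counts.index[sex_counts > 1])
    check(df["player_id"].isin(bad_players), "sex_consistent", "error",
          "player_id recorded with more than one sex")

    return ValidationReport(issues)


def schema_description() -> str:
    """JSON description of the observation schema, for documentation."""
    desc = {
        "columns": SCHEMA,
        "mandatory": list(MANDATORY_COLUMNS) + ["chronological_age or birth_date"],
        "missing_markers": list(MISSING_MARKERS),
        "units": {
            "chronological_age": "years (decimal)",
            "stature": "cm",
            "body_mass": "kg",
            "specialization_onset_age": "years",
            "cmj": "cm",
            "line_drill": "s",
            "yoyo_ir1": "m",
        },
    }
    return json.dumps(desc, indent=2)
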