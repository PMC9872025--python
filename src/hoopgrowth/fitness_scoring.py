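"""Pooled z-scores, the composite fitness score and 2-SD standardization.

The overall fitness score is the sum of the z-scores of countermovement jump,
line drill and yo-yo IR1, where each test is standardized against the pooled
mean/SD over *all* non-missing observations (both sexes, every age group and
occasion) and the line-drill z-score is sign-reversed because lower times are
better.  For modelling, outcomes (and body mass) are standardized by
subtracting the mean and dividing by two standard deviations, so coefficients
of binary predictors are directly comparable to standardized continuous ones.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ObservationTable

OUTCOMES = ("cmj", "line_drill", "yoyo_ir1")
#: outcomes for which a larger raw value means better performance
HIGHER_IS_BETTER = {"cmj": True, "line_drill": False, "yoyo_ir1": True}


class DegenerateScaleError(ValueError):
    """An outcome has zero variance (or too few values) and cannot be standardized."""


@dataclasses.dataclass(frozen=True)
class ScalingRecord:
    """Mean/SD pair fixing a standardization so it can be inverted and reused."""

    name: str
    mean: float
    sd: float
    divisor: float  # 1.0 for plain z-scores, 2.0 for 2-SD standardization

    def transform(self, values: np.ndarray | pd.Series) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / (self.divisor * self.sd)

    def inverse(self, standardized: np.ndarray | pd.Series) -> np.ndarray:
        return np.asarray(standardized, dtype=float) * (self.divisor * self.sd) + self.mean

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pooled_stats(values: pd.Series, name: str) -> tuple[float, float]:
    x = pd.to_numeric(values, errors="coerce").dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise DegenerateScaleError(f"outcome '{name}' has fewer than 2 non-missing values")
    sd = float(np.std(x, ddof=1))  # n-1 denominator by convention
    if sd == 0.0:
        raise DegenerateScaleError(f"outcome '{name}' has zero variance")
    return float(np.mean(x)), sd


def standardize_2sd(values: np.ndarray | pd.Series, name: str = "x") -> tuple[np.ndarray, ScalingRecord]:
    """Center and divide by two sample SDs; the output sample SD is 0.5."""
    mean, sd = _pooled_stats(pd.Series(np.asarray(values, dtype=float)), name)
    rec = ScalingRecord(name=name, mean=mean, sd=sd, divisor=2.0)
    return rec.transform(values), rec


@dataclasses.dataclass
class ScoredTable:
    """ObservationTable augmented with z-scores, the composite, and 2-SD columns."""

    table: ObservationTable
    scalings: dict[str, ScalingRecord]

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def write_scalings(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: v.to_dict() for k, v in self.scalings.items()}, indent=2)
        )


def pooled_zscores(
    table: ObservationTable,
    scalings: dict[str, ScalingRecord] | None = None,
) -> ScoredTable:
    """Score a table: per-test pooled z-scores, the composite, and 2-SD columns.

    Passing ``scalings`` from a previous fit reuses its stored means/SDs, so new
    data are scored on the same scale rather than re-standardized.

    Adds columns ``z_cmj``, ``z_linedrill_reversed``, ``z_yoyo``,
    ``fitness_score`` (missing whenever any of the three inputs is missing),
    plus ``y_std_<outcome>``, ``y_std_fitness_score`` and ``body_mass_std``
    (2-SD standardized) for the modelling modules.
    """
    df = table.df.copy()
    recs: dict[str, ScalingRecord] = dict(scalings) if scalings else {}

    def record(name: str, series: pd.Series, divisor: float) -> ScalingRecord:
        if name not in recs:
            mean, sd = _pooled_stats(series, name)
            recs[name] = ScalingRecord(name=name, mean=mean, sd=sd, divisor=divisor)
        return recs[name]

    zcols = {}
    for outcome in OUTCOMES:
        rec = record(f"z_{outcome}", df[outcome], divisor=1.0)
        z = rec.transform(df[outcome])
        if not HIGHER_IS_BETTER[outcome]:
            z = -z
        zcols[outcome] = z
    df["z_cmj"] = zcols["cmj"]
    df["z_linedrill_reversed"] = zcols["line_drill"]
    df["z_yoyo"] = zcols["yoyo_ir1"]
    df["fitness_score"] = df["z_cmj"] + df["z_linedrill_reversed"] + df["z_yoyo"]

    for outcome in OUTCOMES:
        rec = record(f"std_{outcome}", df[outcome], divisor=2.0)
        df[f"y_std_{outcome}"] = rec.transform(df[outcome])
    rec = record("std_fitness_score", df["fitness_score"], divisor=2.0)
    df["y_std_fitness_score"] = rec.transform(df["fitness_score"])
    if df["body_mass"].notna().sum() >= 2:
        rec = record("std_body_mass", df["body_mass"], divisor=2.0)
        df["body_mass_std"] = rec.transform(df["body_mass"])
    else:
        df["body_mass_std"] = np.nan

    out = table.copy()
    out.df = df
    return ScoredTable(table=out, scalings=recs)
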