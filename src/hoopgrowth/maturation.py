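"""Somatic maturation: maturity offset, age at peak height velocity, status.

The maturity offset is the predicted time (years) from the current
measurement occasion to peak height velocity (PHV); it is negative before
PHV.  We use the sex-specific age-and-stature prediction equations

    offset = intercept_sex + slope_sex * (age * stature)

with age in decimal years and stature in cm.  Subtracting the offset from
chronological age gives each player's estimated age at PHV (aPHV), the
timing milestone against which maturity status is classified:

* ``early``   - estimated aPHV more than six months below the sex reference,
* ``average`` - within plus/minus six months of the reference,
* ``late``    - more than six months above it.

The offset equations lose validity away from the ages around PHV, so the
classifier only applies to under-13 females and under-13/under-15 males;
everyone else is ``not_classified``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .core_data import ObservationTable, PHASE_ORDER

MATURITY_STATUSES = ("early", "average", "late", "not_classified")

#: (sex, age_group) combinations for which offset-based status is considered valid
APPLICABLE_GROUPS = {("female", "U13"), ("male", "U13"), ("male", "U15")}


@dataclasses.dataclass(frozen=True)
class OffsetCoefficients:
    """Per-sex intercept (years) and slope (years per year*cm) of the offset model."""

    female_intercept: float = -7.709133
    female_slope: float = 0.0042232
    male_intercept: float = -7.999994
    male_slope: float = 0.0036124

    def __post_init__(self) -> None:
        if self.female_slope <= 0 or self.male_slope <= 0:
            raise ValueError("offset slope must be positive for both sexes")

    def for_sex(self, sex: str) -> tuple[float, float]:
        if sex == "female":
            return self.female_intercept, self.female_slope
        if sex == "male":
            return self.male_intercept, self.male_slope
        raise ValueError(f"unknown sex label: {sex!r}")


@dataclasses.dataclass(frozen=True)
class ReferenceMilestones:
    """Sex-specific reference ages (years) of pubertal-growth onset and PHV.

    Point estimates with 95% intervals from meta-analysis of longitudinal
    growth studies in the general population; consumed here as constants.
    """

    female_onset: float = 9.4
    female_onset_ci: tuple[float, float] = (9.0, 9.8)
    female_aphv: float = 11.9
    female_aphv_ci: tuple[float, float] = (11.8, 12.0)
    male_onset: float = 11.1
    male_onset_ci: tuple[float, float] = (10.8, 11.5)
    male_aphv: float = 13.9
    male_aphv_ci: tuple[float, float] = (13.8, 14.0)

    def __post_init__(self) -> None:
        if not (self.female_onset < self.female_aphv and self.male_onset < self.male_aphv):
            raise ValueError("pubertal-growth onset must precede PHV within each sex")
        if not self.female_aphv < self.male_aphv:
            raise ValueError("female reference aPHV must precede male reference aPHV")

    def onset(self, sex: str) -> float:
        return {"female": self.female_onset, "male": self.male_onset}[sex]

    def aphv(self, sex: str) -> float:
        return {"female": self.female_aphv, "male": self.male_aphv}[sex]


@dataclasses.dataclass
class MaturityAssessment:
    player_id: str
    estimated_offset: float | None
    estimated_aphv: float | None
    status: str
    rule_note: str


def maturity_offset(
    sex: str,
    chronological_age: float | np.ndarray,
    stature: float | np.ndarray,
    coeffs: OffsetCoefficients | None = None,
) -> float | np.ndarray:
    """Predicted years from the measurement occasion to PHV (negative = pre-PHV)."""
    coeffs = coeffs or OffsetCoefficients()
    intercept, slope = coeffs.for_sex(sex)
    return intercept + slope * (np.asarray(chronological_age, dtype=float) * np.asarray(stature, dtype=float))


def age_at_phv(
    sex: str,
    chronological_age: float | np.ndarray,
    stature: float | np.ndarray,
    coeffs: OffsetCoefficients | None = None,
) -> float | np.ndarray:
    """Estimated age at PHV = chronological age minus the maturity offset."""
    return np.asarray(chronological_age, dtype=float) - maturity_offset(
        sex, chronological_age, stature, coeffs
    )


def classify_maturity(
    sex: str,
    age_group: str,
    estimated_aphv: float | None,
    refs: ReferenceMilestones | None = None,
    tolerance_years: float = 0.5,
    player_id: str = "",
    ci_aware: bool = False,
) -> MaturityAssessment:
    """Classify maturity timing against the sex reference aPHV.

    Boundary-inclusive: a difference of exactly +/- ``tolerance_years``
    (six months by default) is ``average``.  With ``ci_aware`` the player is
    demoted to ``average`` whenever the difference interval implied by the
    reference 95% CI overlaps zero; off by default since classification on
    point estimates is the conventional rule.
    """
    refs = refs or ReferenceMilestones()
    if (sex, age_group) not in APPLICABLE_GROUPS:
        return MaturityAssessment(
            player_id, None, estimated_aphv, "not_classified",
            "offset estimation not considered valid for this sex/age group",
        )
    if estimated_aphv is None or not np.isfinite(estimated_aphv):
        return MaturityAssessment(player_id, None, None, "not_classified", "missing estimate")

    ref = refs.aphv(sex)
    delta = estimated_aphv - ref
    if ci_aware:
        lo, hi = {"female": refs.female_aphv_ci, "male": refs.male_aphv_ci}[sex]
        if estimated_aphv - hi <= tolerance_years and estimated_aphv - lo >= -tolerance_years:
            return MaturityAssessment(
                player_id, None, estimated_aphv, "average",
                f"CI-aware: delta interval overlaps +/-{tolerance_years} band",
            )
    if delta < -tolerance_years:
        status = "early"
    elif delta > tolerance_years:
        status = "late"
    else:
        status = "average"
    return MaturityAssessment(
        player_id, None, estimated_aphv, status,
        f"delta to reference aPHV ({ref:.1f} y) = {delta:+.2f} y",
    )


def assess_players(
    table: ObservationTable,
    coeffs: OffsetCoefficients | None = None,
    refs: ReferenceMilestones | None = None,
    tolerance_years: float = 0.5,
) -> pd.DataFrame:
    """Per-player maturity assessment from the pre-season occasion.

    The earliest available occasion (pre-season when present) of a player's
    first observed season supplies the age and stature from which the offset
    and aPHV are estimated; status is then a player-level constant for all
    downstream models.  Returns a tidy frame with one row per player.
    """
    coeffs = coeffs or OffsetCoefficients()
    refs = refs or ReferenceMilestones()
    df = table.df.copy()
    df["_phase_ord"] = df["phase"].map(PHASE_ORDER)
    df = df.sort_values(["player_id", "season_year", "_phase_ord"])

    rows = []
    for pid, grp in df.groupby("player_id", sort=True):
        first = grp.iloc[0]
        sex = first["sex"]
        age_group = first["age_group"]
        age, stat = first["chronological_age"], first["stature"]
        if pd.isna(age) or pd.isna(stat) or pd.isna(sex):
            offset = aphv = None
        else:
            offset = float(maturity_offset(str(sex), age, stat, coeffs))
            aphv = float(age - offset)
        assessment = classify_maturity(
            str(sex) if pd.notna(sex) else "",
            str(age_group) if pd.notna(age_group) else "",
            aphv, refs, tolerance_years, player_id=str(pid),
        )
        rows.append(
            {
                "player_id": pid,
                "sex": sex,
                "age_group": age_group,
                "estimated_offset": offset,
                "estimated_aphv": round(aphv, 1) if aphv is not None else np.nan,
                "maturity_status": assessment.status,
                "rule_note": assessment.rule_note,
            }
        )
    return pd.DataFrame(rows)
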