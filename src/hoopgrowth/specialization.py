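"""Classify specialization onset relative to pubertal-growth milestones.

Specialization is the self-reported age at which a player began exclusive,
year-round, coach-supervised basketball participation.  Relative to the
sex-specific reference ages of pubertal-growth onset and PHV:

* ``pre_puberty``  - onset before the reference onset of pubertal growth
                     (early specialization),
* ``mid_puberty``  - onset within [onset reference, PHV reference]
                     (closed interval; ties at either boundary are mid),
* ``late_puberty`` - onset after the reference age at PHV,
* ``unknown``      - no onset age reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_data import ObservationTable
from .maturation import ReferenceMilestones

SPECIALIZATION_CATEGORIES = ("pre_puberty", "mid_puberty", "late_puberty", "unknown")


@dataclasses.dataclass
class SpecializationAssessment:
    player_id: str
    onset_age: float | None
    category: str
    rule_note: str


def classify_specialization(
    sex: str,
    onset_age: float | None,
    refs: ReferenceMilestones | None = None,
    player_id: str = "",
) -> SpecializationAssessment:
    """Pure rule application; no rounding of the stored onset age."""
    refs = refs or ReferenceMilestones()
    if onset_age is None or (isinstance(onset_age, float) and not np.isfinite(onset_age)):
        return SpecializationAssessment(player_id, None, "unknown", "onset age not reported")
    if not 3.0 <= onset_age <= 18.0:
        raise ValueError(f"implausible specialization onset age: {onset_age!r} (expected [3, 18] y)")
    onset_ref = refs.onset(sex)
    aphv_ref = refs.aphv(sex)
    if onset_age < onset_ref:
        cat, note = "pre_puberty", f"onset {onset_age:g} < growth-spurt onset reference {onset_ref:g}"
    elif onset_age <= aphv_ref:
        cat, note = "mid_puberty", f"onset {onset_age:g} within [{onset_ref:g}, {aphv_ref:g}]"
    else:
        cat, note = "late_puberty", f"onset {onset_age:g} > PHV reference {aphv_ref:g}"
    return SpecializationAssessment(player_id, float(onset_age), cat, note)


def assess_players(
    table: ObservationTable,
    refs: ReferenceMilestones | None = None,
) -> pd.DataFrame:
    """Per-player specialization classification (one row per player).

    The onset age is a player-level constant; if multiple occasions report it,
    the first non-missing value is used.
    """
    refs = refs or ReferenceMilestones()
    rows = []
    for pid, grp in table.df.groupby("player_id", sort=True):
        sex = grp["sex"].dropna().iloc[0] if grp["sex"].notna().any() else ""
        onsets = grp["specialization_onset_age"].dropna()
        onset = float(onsets.iloc[0]) if len(onsets) else None
        a = classify_specialization(str(sex), onset, refs, player_id=str(pid))
        rows.append(
            {
                "player_id": pid,
                "sex": sex,
                "onset_age": a.onset_age,
                "specialization": a.category,
                "rule_note": a.rule_note,
            }
        )
    return pd.DataFrame(rows)
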