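"""Classify maturity status and specialization onset for the simulated cohort.

Reads results/cohort.csv (run 01_simulate_cohort.py first), applies the
maturity-offset pathway (pre-season age and stature -> estimated age at PHV
-> early/average/late against the sex reference) and the specialization rule
(self-reported onset age against the pubertal-growth milestones), and writes
per-player classifications plus the category cross-tabulation by age group
and sex.
"""

from pathlib import Path

import pandas as pd

from hoopgrowth import maturation, specialization
from hoopgrowth.core_data import load_observations

OUT = Path("results")


def main() -> None:
    table = load_observations(OUT / "cohort.csv")
    mat = maturation.assess_players(table)
    spc = specialization.assess_players(table)
    merged = mat.merge(spc[["player_id", "onset_age", "specialization"]], on="player_id")
    merged.to_csv(OUT / "classifications.csv", index=False)

    print("maturity status counts:")
    print(mat.maturity_status.value_counts().to_string())
    xtab = (merged.groupby(["age_group", "sex", "specialization"]).size()
            .unstack(fill_value=0))
    xtab.to_csv(OUT / "specialization_by_group.csv")
    print("\nspecialization by age group and sex:")
    print(xtab.to_string())


if __name__ == "__main__":
    main()
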