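import numpy as np
import pandas as pd
import pytest

from hoopgrowth.core_data import ObservationTable
from hoopgrowth.hierarchical_models import SamplerSettings, build_season_model, fit
from hoopgrowth.pipeline import build_analysis_frame
from hoopgrowth.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (the study conditions), shared read-only."""
    table, truth = simulate_cohort(SimulationConfig())
    return table, truth


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    table, _ = default_cohort
    frame, scalings = build_analysis_frame(table)
    return frame, scalings


@pytest.fixture(scope="session")
def small_season_fit(analysis_frame):
    """A cheap but real season-model fit shared by summary-level tests."""
    frame, _ = analysis_frame
    spec = build_season_model("fitness_score")
    settings = SamplerSettings(chains=2, iterations=400, warmup=200, seed=42,
                               scale_sweeps=1)
    return fit(spec, frame, settings)


@pytest.fixture()
def tiny_table():
    """Six hand-written observations covering both sexes and all phases."""
    rows = [
        dict(player_id="A", sex="female", chronological_age=12.5, season_year=2019,
             phase="pre", age_group="U13", stature=155.0, body_mass=48.0,
             specialization_onset_age=8.0, cmj=24.0, line_drill=37.0, yoyo_ir1=360.0),
        dict(player_id="A", sex="female", chronological_age=12.9, season_year=2019,
             phase="mid", age_group="U13", stature=156.0, body_mass=49.0,
             specialization_onset_age=8.0, cmj=25.0, line_drill=36.5, yoyo_ir1=400.0),
        dict(player_id="A", sex="female", chronological_age=13.2, season_year=2019,
             phase="end", age_group="U13", stature=156.5, body_mass=49.5,
             specialization_onset_age=8.0, cmj=25.5, line_drill=36.2, yoyo_ir1=440.0),
        dict(player_id="B", sex="male", chronological_age=14.3, season_year=2019,
             phase="pre", age_group="U15", stature=176.0, body_mass=64.0,
             specialization_onset_age=12.0, cmj=35.0, line_drill=33.5, yoyo_ir1=880.0),
        dict(player_id="B", sex="male", chronological_age=14.7, season_year=2019,
             phase="mid", age_group="U15", stature=177.0, body_mass=65.0,
             specialization_onset_age=12.0, cmj=36.0, line_drill=33.2, yoyo_ir1=920.0),
        dict(player_id="C", sex="male", chronological_age=16.1, season_year=2019,
             phase="pre", age_group="U17", stature=186.0, body_mass=79.0,
             specialization_onset_age=None, cmj=39.0, line_drill=31.8, yoyo_ir1=1200.0),
    ]
    return ObservationTable(pd.DataFrame(rows), provenance="fixture")
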