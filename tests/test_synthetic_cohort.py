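import numpy as np
import pandas as pd
import pytest

from hoopgrowth.synthetic_cohort import (
    SimulationConfig,
    default_config,
    growth_curve,
    inject_specialization_effect,
    simulate_cohort,
)

# pre-season descriptive references: sex, age group -> (mean, SD)
REFERENCE_CELLS = {
    ("female", "U13"): {"stature": (163.3, 9.5), "cmj": (24.3, 3.9),
                        "line_drill": (37.36, 1.88), "yoyo_ir1": (372.7, 82.2)},
    ("male", "U13"): {"stature": (165.4, 11.0), "cmj": (31.7, 6.7),
                      "line_drill": (34.71, 3.37), "yoyo_ir1": (516.4, 305.6)},
    ("female", "U15"): {"stature": (164.3, 5.6), "cmj": (25.0, 3.9),
                        "line_drill": (35.67, 1.93), "yoyo_ir1": (516.2, 175.7)},
    ("male", "U15"): {"stature": (176.6, 11.0), "cmj": (35.6, 5.8),
                      "line_drill": (33.57, 3.70), "yoyo_ir1": (899.2, 382.8)},
    ("female", "U17"): {"stature": (167.7, 3.9), "cmj": (25.7, 4.1),
                        "line_drill": (36.29, 1.82), "yoyo_ir1": (528.0, 171.6)},
    ("male", "U17"): {"stature": (186.5, 7.5), "cmj": (38.9, 6.0),
                      "line_drill": (31.70, 3.09), "yoyo_ir1": (1203.3, 348.0)},
}


def _noise_free(**kw):
    zero = {"cmj": 0.0, "line_drill": 0.0, "yoyo_ir1": 0.0}
    return SimulationConfig(
        player_intercept_sd=dict(zero), player_slope_sd=dict(zero),
        season_sd=dict(zero), residual_sd=dict(zero),
        stature_error_cm=0.0, mass_error_kg=0.0, mass_player_cv=0.0,
        quantize=False, **kw)


class TestSimulateCohort:
    def test_same_seed_identical_tables(self):
        t1, _ = simulate_cohort(SimulationConfig(seed=5))
        t2, _ = simulate_cohort(SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_different_seed_differs(self):
        t1, _ = simulate_cohort(SimulationConfig(seed=5))
        t2, _ = simulate_cohort(SimulationConfig(seed=6))
        assert not t1.df.equals(t2.df)

    def test_noise_free_limit_equals_the_mean_function(self):
        cfg = _noise_free(seed=3, n_female=10, n_male=10)
        table, _ = simulate_cohort(cfg)
        # reconstruct each row's deterministic mean; player/maturity context
        # comes from the generated columns themselves
        from hoopgrowth.specialization import classify_specialization
        from hoopgrowth.maturation import ReferenceMilestones
        refs = ReferenceMilestones()
        for _, row in table.df.iterrows():
            onset = None if pd.isna(row.specialization_onset_age) else float(
                row.specialization_onset_age)
            cat = classify_specialization(str(row.sex), onset).category
            for o in ("cmj", "line_drill", "yoyo_ir1"):
                # default maturity/specialization effects are all zero, so the
                # status arguments cannot change the expected value
                mu = cfg.mean_outcome(o, str(row.sex), float(row.chronological_age),
                                      str(row.phase), "average", cat)
                assert row[o] == pytest.approx(mu, abs=1e-9)

    def test_cell_means_match_the_mean_function_at_large_n(self):
        # season effects are drawn once per season (they do not average out
        # over players), so they are switched off for this law-of-large-numbers
        # check of the player-level mean structure
        cfg = SimulationConfig(seed=11, n_female=1000, n_male=1000,
                               season_sd={"cmj": 0.0, "line_drill": 0.0,
                                          "yoyo_ir1": 0.0})
        table, _ = simulate_cohort(cfg)
        df = table.df
        for sex in ("female", "male"):
            for phase in ("pre", "mid", "end"):
                cell = df[(df.sex == sex) & (df.phase == phase)]
                mu = np.array([
                    cfg.mean_outcome("cmj", sex, a, phase)
                    for a in cell.chronological_age])
                total_sd = np.sqrt(cfg.player_intercept_sd["cmj"] ** 2
                                   + cfg.player_slope_sd["cmj"] ** 2
                                   + cfg.season_sd["cmj"] ** 2
                                   + cfg.residual_sd["cmj"] ** 2)
                se = total_sd / np.sqrt(len(cell))
                assert abs(cell.cmj.mean() - mu.mean()) < 3 * se + 0.5  # + quantization

    def test_stature_is_nondecreasing_within_player(self, default_cohort):
        table, _ = default_cohort
        df = table.df.sort_values(["player_id", "chronological_age"])
        for _, grp in df.groupby("player_id"):
            assert (np.diff(grp.stature.to_numpy()) >= -1e-9).all()

    def test_growth_curve_is_monotone_and_sigmoidal(self):
        cfg = default_config()
        ages = np.linspace(8, 20, 200)
        for sex in ("female", "male"):
            h = growth_curve(cfg, sex, ages)
            assert (np.diff(h) > 0).all()
            v = np.diff(h) / np.diff(ages)
            peak_age = ages[np.argmax(v)]
            assert peak_age == pytest.approx(cfg.growth[sex]["aphv_mean"], abs=0.2)

    def test_female_aphv_earlier_than_male(self):
        cfg = default_config()
        assert cfg.growth["female"]["aphv_mean"] < cfg.growth["male"]["aphv_mean"]

    def test_default_cohort_resembles_the_published_descriptives(self, default_cohort):
        table, _ = default_cohort
        pre = table.df[table.df.phase == "pre"]
        assert 150 <= len(table.players) <= 210
        for (sex, ag), cells in REFERENCE_CELLS.items():
            sub = pre[(pre.sex == sex) & (pre.age_group == ag)]
            for var, (mean, sd) in cells.items():
                assert abs(sub[var].mean() - mean) < sd, (sex, ag, var)

    def test_yoyo_distances_are_shuttle_multiples(self, default_cohort):
        table, _ = default_cohort
        yy = table.df["yoyo_ir1"].dropna()
        assert ((yy % 40.0) == 0).all()

    def test_onset_categories_roughly_match_configured_mixture(self, default_cohort):
        from hoopgrowth.specialization import assess_players
        table, _ = default_cohort
        out = assess_players(table)
        freqs = out.specialization.value_counts(normalize=True)
        cfg = default_config()
        # late-puberty demotions make this a loose check
        assert freqs.get("pre_puberty", 0) == pytest.approx(
            cfg.onset_category_probs["pre_puberty"], abs=0.15)
        assert freqs.get("unknown", 0) == pytest.approx(
            cfg.onset_category_probs["unknown"], abs=0.10)


class TestConfig:
    def test_round_trips_through_serialization(self):
        cfg = default_config()
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again == cfg
        import json
        assert SimulationConfig.from_dict(json.loads(cfg.to_json())) == cfg

    def test_invalid_fields_are_listed_collectively(self):
        with pytest.raises(ValueError) as err:
            SimulationConfig(p_second_season=1.5, stature_error_cm=-1.0)
        assert "p_second_season" in str(err.value)
        assert "measurement error" in str(err.value)


class TestInjectSpecializationEffect:
    def test_zero_effect_leaves_config_equal(self):
        cfg = default_config()
        assert inject_specialization_effect(cfg, "pre_puberty", 0.0) == cfg

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError, match="category"):
            inject_specialization_effect(default_config(), "nope", 0.5)

    def test_negative_effects_are_symmetric(self):
        up = inject_specialization_effect(default_config(), "mid_puberty", 0.4)
        down = inject_specialization_effect(default_config(), "mid_puberty", -0.4)
        assert up.specialization_effects["mid_puberty"] == pytest.approx(0.4)
        assert down.specialization_effects["mid_puberty"] == pytest.approx(-0.4)

    def test_injected_gap_appears_at_large_n(self):
        cfg = SimulationConfig(seed=21, n_female=600, n_male=600)
        cfg = inject_specialization_effect(cfg, "pre_puberty", 0.5)
        table, _ = simulate_cohort(cfg)
        from hoopgrowth.specialization import assess_players
        spc = assess_players(table)
        df = table.df.merge(spc[["player_id", "specialization"]], on="player_id")
        pre_grp = df[df.specialization == "pre_puberty"]
        late_grp = df[df.specialization == "late_puberty"]
        # compare same-sex, same-phase means to isolate the injected shift
        sub = df[(df.sex == "male") & (df.phase == "pre")]
        gap = (sub[sub.specialization == "pre_puberty"].cmj.mean()
               - sub[sub.specialization == "mid_puberty"].cmj.mean())
        expected = 0.5 * cfg.outcome_scales["cmj"]
        assert gap == pytest.approx(expected, abs=1.2)
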