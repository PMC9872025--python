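import numpy as np
import pandas as pd
import pytest

from hoopgrowth.hierarchical_models import (
    ModelSpec,
    PriorSet,
    SamplerSettings,
    build_design,
    build_growth_model,
    build_season_model,
    fit,
    sample_prior,
)


class TestModelSpecs:
    @pytest.mark.parametrize("outcome,has_mass", [
        ("cmj", False), ("line_drill", False),
        ("yoyo_ir1", True), ("fitness_score", True),
    ])
    def test_body_mass_term_only_for_endurance_and_composite(self, outcome, has_mass):
        spec = build_season_model(outcome)
        assert ("body_mass_std" in spec.population_terms) == has_mass

    def test_season_model_grouping_structure(self):
        spec = build_season_model("cmj")
        names = {g.name: g for g in spec.group_terms}
        assert set(names) == {"player", "season", "spec_sex", "agegrp_sex", "maturity_sex"}
        assert names["player"].coefs == ("Intercept", "phase_mid", "phase_end")
        assert names["season"].coefs == ("Intercept",)

    def test_growth_model_has_quadratic_age_and_specialization_level3(self):
        spec = build_growth_model("cmj")
        assert "age_c2" in spec.population_terms
        assert any(g.name == "spec_onset" and "age_c2" in g.coefs for g in spec.group_terms)
        assert spec.age_center == 14.0  # centering constant recorded in the spec

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            build_season_model("bench_press")

    def test_priors_serialize_verbatim(self):
        p = PriorSet()
        d = p.to_dict()
        assert d["population_sd"] == 5.0
        assert d["group_sd_rate"] == 1.0
        assert (d["residual_df"], d["residual_scale"]) == (3.0, 2.5)
        assert d["correlation"] == "independent"

    def test_spec_serializes_to_json(self):
        import json
        spec = build_season_model("yoyo_ir1")
        parsed = json.loads(spec.to_json())
        assert parsed["outcome"] == "yoyo_ir1"
        assert parsed["priors"]["population_sd"] == 5.0


class TestSamplerSettings:
    def test_warmup_must_be_shorter(self):
        with pytest.raises(ValueError):
            SamplerSettings(iterations=100, warmup=100)

    def test_at_least_two_chains(self):
        with pytest.raises(ValueError):
            SamplerSettings(chains=1)


class TestDesign:
    def test_one_row_per_nonmissing_observation(self, analysis_frame):
        frame, _ = analysis_frame
        frame = frame.copy()
        frame.loc[frame.index[:7], "cmj"] = np.nan
        spec = build_season_model("cmj")
        design = build_design(spec, frame)
        assert len(design.frame) == frame["cmj"].notna().sum()
        # no listwise deletion across outcomes: other outcomes' missingness irrelevant
        frame2 = frame.copy()
        frame2.loc[frame2.index[10:20], "yoyo_ir1"] = np.nan
        assert len(build_design(spec, frame2).frame) == len(design.frame)

    def test_unknown_levels_are_retained_as_factor_levels(self, analysis_frame):
        frame, _ = analysis_frame
        design = build_design(build_season_model("cmj"), frame)
        assert any("unknown" in lv for lv in design.levels_map["spec_sex"])
        assert any("not_classified" in lv for lv in design.levels_map["maturity_sex"])


def _intercept_only_spec():
    return ModelSpec(outcome="y", kind="season", population_terms=("Intercept",),
                     group_terms=(), standardize=False, big_block=None)


class TestFit:
    def test_intercept_only_matches_the_analytic_posterior(self):
        # under Normal(0,5) the posterior mean is within a whisker of the
        # sample mean for n = 500
        rng = np.random.default_rng(4)
        y = rng.normal(2.0, 1.0, 500)
        df = pd.DataFrame({"y": y})
        draws = fit(_intercept_only_spec(), df,
                    SamplerSettings(chains=2, iterations=400, warmup=200, seed=1))
        post = draws.get("Intercept").mean()
        assert 1.9 <= post <= 2.1
        # the weak prior leaves the posterior mean within Monte-Carlo error of
        # the sample mean
        assert post == pytest.approx(y.mean(), abs=0.01)
        assert draws.get("sigma").mean() == pytest.approx(y.std(ddof=1), abs=0.05)

    def test_identical_seeds_give_bit_identical_draws(self, analysis_frame):
        frame, _ = analysis_frame
        spec = build_season_model("cmj")
        settings = SamplerSettings(chains=2, iterations=120, warmup=60, seed=9,
                                   scale_sweeps=1)
        a = fit(spec, frame, settings)
        b = fit(spec, frame, settings)
        for p in a.parameters:
            np.testing.assert_array_equal(a.get(p), b.get(p))

    def test_draw_count_and_fit_log(self, small_season_fit):
        d = small_season_fit
        assert d.n_chains == d.settings.chains
        assert d.n_draws == d.settings.iterations - d.settings.warmup
        log = d.fit_log()
        assert log["priors"]["population_sd"] == 5.0
        assert log["n_obs"] == d.n_obs
        assert log["divergences"] == 0
        for term in d.spec.population_terms:
            assert d.get(term).shape == (d.n_chains, d.n_draws)

    def test_too_few_rows_raises(self):
        df = pd.DataFrame({"y": np.arange(10.0)})
        with pytest.raises(ValueError, match="rows"):
            fit(_intercept_only_spec(), df)

    def test_nonfinite_outcome_raises(self):
        df = pd.DataFrame({"y": np.r_[np.full(50, 1.0), np.inf]})
        with pytest.raises(ValueError, match="non-finite|finite"):
            fit(_intercept_only_spec(), df)

    def test_pooling_limit_collapses_group_effects(self, analysis_frame):
        # pin every spec_sex SD at ~0: its fitted effects must vanish, i.e.
        # group predictions collapse onto the population line
        frame, _ = analysis_frame
        spec = build_season_model("cmj")
        pinned = {f"sd_spec_sex__{c}": 1e-8 for c in ("Intercept", "phase_mid", "phase_end")}
        draws = fit(spec, frame,
                    SamplerSettings(chains=2, iterations=200, warmup=100, seed=4,
                                    scale_sweeps=1),
                    fixed_tau=pinned)
        for lv in draws.group_levels["spec_sex"]:
            for c in ("Intercept", "phase_mid", "phase_end"):
                assert np.abs(draws.random_effect("spec_sex", lv, c)).max() < 1e-6


class TestPriorOnly:
    def test_population_coefficients_have_the_prior_scale(self):
        spec = build_season_model("cmj")
        draws = sample_prior(spec, SamplerSettings(chains=4, iterations=2000,
                                                   warmup=1000, seed=11))
        for t in spec.population_terms:
            assert draws.get(t).std() == pytest.approx(5.0, rel=0.1)
        # group SDs are exponential(1): mean 1
        sds = [v.mean() for v in draws.group_sds().values()]
        assert np.mean(sds) == pytest.approx(1.0, abs=0.1)


class TestRecovery:
    def test_season_model_recovers_phase_and_interaction_effects(self, default_cohort):
        # population-level truth (natural units) converted to the fitted 2-SD
        # standardized scale via the scaling record
        table, truth = default_cohort
        from hoopgrowth.pipeline import build_analysis_frame
        frame, _ = build_analysis_frame(table)
        draws = fit(build_season_model("cmj"), frame,
                    SamplerSettings(chains=2, iterations=600, warmup=300, seed=13,
                                    scale_sweeps=1))
        t = truth.season_model_truth("cmj")
        denom = 2.0 * draws.scaling.sd
        for term in ("phase_mid", "phase_end", "sex_male:phase_mid", "sex_male:phase_end"):
            post = draws.get(term)
            z = (post.mean() - t[term] / denom) / post.std()
            assert abs(z) < 3.0, term

    def test_group_level_sds_recovered_on_a_large_cohort(self):
        from hoopgrowth.pipeline import build_analysis_frame
        from hoopgrowth.synthetic_cohort import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(seed=31, n_female=100, n_male=200)
        table, truth = simulate_cohort(cfg)
        frame, _ = build_analysis_frame(table)
        draws = fit(build_season_model("cmj"), frame,
                    SamplerSettings(chains=2, iterations=600, warmup=300, seed=14,
                                    scale_sweeps=1))
        t = truth.season_model_truth("cmj")
        denom = 2.0 * draws.scaling.sd
        est = draws.get("sd_player__Intercept").mean()
        assert est == pytest.approx(t["sd_player__Intercept"] / denom, rel=0.25)
        est_sigma = draws.get("sigma").mean()
        assert est_sigma == pytest.approx(t["sigma"] / denom, rel=0.25)
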