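"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the structure of a multi-season youth-basketball
testing programme: ~180 players (female:male roughly 40:141) in under-13 /
under-15 / under-17 age groups, up to three occasions (pre/mid/end) per
season over consecutive seasons with phase-level completely-at-random
missingness, sex-dimorphic stature growth with player-level age at peak
height velocity, allometric body mass, and three fitness tests whose means
follow smooth age functions calibrated to published pre-season descriptives.
Measurement error uses the documented technical errors (0.25 cm stature,
0.42 kg body mass).

Ground truth (every fixed effect and variance component actually used) is
returned alongside the table so that model fits can be scored for parameter
recovery.  Specialization and maturity effects default to zero - the null
world in which early specialization confers no fitness advantage - and can
be injected in units of per-outcome reference SDs for power/recovery
scenarios.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from typing import Iterable

import numpy as np
import pandas as pd

from .core_data import ObservationTable, PHASES, derive_age_group
from .maturation import ReferenceMilestones

OUTCOMES = ("cmj", "line_drill", "yoyo_ir1")
#: +1 if a larger raw value is better performance, -1 otherwise
OUTCOME_DIRECTION = {"cmj": 1.0, "line_drill": -1.0, "yoyo_ir1": 1.0}
#: calendar position of each phase within the season year
PHASE_FRACTION = {"pre": 0.17, "mid": 0.58, "end": 0.92}
_AGE_ANCHOR = 12.5  # years; age at which the outcome mean polynomials are anchored


def _default_growth() -> dict:
    # logistic-velocity stature curve: H(a) = adult - gain / (1 + exp(tempo*(a - aPHV)))
    # peak height velocity = tempo * gain / 4  (~7-8 cm/y at the defaults)
    return {
        "female": {"adult_mean": 169.0, "adult_sd": 5.5, "aphv_mean": 11.4,
                   "aphv_sd": 0.5, "tempo": 0.9, "pubertal_gain": 29.0},
        "male": {"adult_mean": 189.0, "adult_sd": 7.0, "aphv_mean": 13.1,
                 "aphv_sd": 0.55, "tempo": 0.8, "pubertal_gain": 39.4},
    }


def _default_outcome_means() -> dict:
    # quadratic in (age - 12.5) years, separately by sex
    return {
        "cmj": {"female": (24.0, 0.35, 0.0), "male": (31.5, 2.18, 0.0)},
        "line_drill": {"female": (37.4, -0.85, 0.13), "male": (34.8, -0.91, 0.0)},
        "yoyo_ir1": {"female": (390.0, 85.0, -10.0), "male": (495.0, 208.0, 0.0)},
    }


def _default_phase_effects() -> dict:
    # (mid, end) shifts in natural units: females improve slightly across the
    # season, males maintain their level
    return {
        "cmj": {"female": (0.5, 0.8), "male": (0.0, 0.0)},
        "line_drill": {"female": (-0.15, -0.25), "male": (0.0, 0.0)},
        "yoyo_ir1": {"female": (25.0, 45.0), "male": (0.0, 0.0)},
    }


@dataclasses.dataclass
class SimulationConfig:
    """Everything the cohort generator uses; the defaults are the study conditions."""

    seed: int = 20230110
    n_female: int = 40
    n_male: int = 141
    first_season: int = 2017
    n_seasons: int = 3
    p_second_season: float = 0.35
    phase_completion: dict = dataclasses.field(
        default_factory=lambda: {"pre": 0.85, "mid": 0.85, "end": 0.68})
    attained_age_weights: dict = dataclasses.field(
        default_factory=lambda: {12: 0.21, 13: 0.21, 14: 0.20, 15: 0.20, 16: 0.09, 17: 0.09})
    growth: dict = dataclasses.field(default_factory=_default_growth)
    stature_error_cm: float = 0.25
    mass_error_kg: float = 0.42
    mass_allometry: dict = dataclasses.field(
        default_factory=lambda: {"coefficient": 13.4, "exponent": 2.9})
    mass_player_cv: float = 0.10
    outcome_means: dict = dataclasses.field(default_factory=_default_outcome_means)
    phase_effects: dict = dataclasses.field(default_factory=_default_phase_effects)
    player_intercept_sd: dict = dataclasses.field(
        default_factory=lambda: {"cmj": 3.8, "line_drill": 1.6, "yoyo_ir1": 150.0})
    player_slope_sd: dict = dataclasses.field(
        default_factory=lambda: {"cmj": 0.8, "line_drill": 0.3, "yoyo_ir1": 30.0})
    season_sd: dict = dataclasses.field(
        default_factory=lambda: {"cmj": 0.5, "line_drill": 0.3, "yoyo_ir1": 20.0})
    residual_sd: dict = dataclasses.field(
        default_factory=lambda: {"cmj": 1.5, "line_drill": 0.8, "yoyo_ir1": 60.0})
    #: reference SDs defining the unit of injected maturity/specialization effects
    outcome_scales: dict = dataclasses.field(
        default_factory=lambda: {"cmj": 7.0, "line_drill": 2.8, "yoyo_ir1": 390.0,
                                 "fitness_score": 2.5})
    maturity_effects: dict = dataclasses.field(
        default_factory=lambda: {"early": 0.0, "average": 0.0, "late": 0.0})
    specialization_effects: dict = dataclasses.field(
        default_factory=lambda: {"pre_puberty": 0.0, "mid_puberty": 0.0,
                                 "late_puberty": 0.0, "unknown": 0.0})
    onset_category_probs: dict = dataclasses.field(
        default_factory=lambda: {"pre_puberty": 0.46, "mid_puberty": 0.33,
                                 "late_puberty": 0.07, "unknown": 0.14})
    quantize: bool = True

    def __post_init__(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is mandatory")
        for name in ("player_intercept_sd", "player_slope_sd", "season_sd", "residual_sd"):
            if any(v < 0 for v in getattr(self, name).values()):
                problems.append(f"{name} must be non-negative")
        if any(not 0 <= p <= 1 for p in self.phase_completion.values()):
            problems.append("phase_completion probabilities must be in [0, 1]")
        if not 0 <= self.p_second_season <= 1:
            problems.append("p_second_season must be in [0, 1]")
        if self.stature_error_cm < 0 or self.mass_error_kg < 0:
            problems.append("measurement error SDs must be non-negative")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    # ------------------------------------------------------------------
    def mean_outcome(self, outcome: str, sex: str, age: float, phase: str,
                     maturity_status: str = "average",
                     specialization: str = "unknown") -> float:
        """Deterministic population mean function (no noise, no player effects)."""
        c0, c1, c2 = self.outcome_means[outcome][sex]
        d = age - _AGE_ANCHOR
        mu = c0 + c1 * d + c2 * d * d
        if phase != "pre":
            mu += self.phase_effects[outcome][sex][0 if phase == "mid" else 1]
        direction = OUTCOME_DIRECTION[outcome]
        scale = self.outcome_scales[outcome]
        mu += direction * scale * self.maturity_effects.get(maturity_status, 0.0)
        mu += direction * scale * self.specialization_effects.get(specialization, 0.0)
        return mu

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = copy.deepcopy(d)
        d["attained_age_weights"] = {int(k): v for k, v in d["attained_age_weights"].items()}
        for field in ("outcome_means", "phase_effects"):
            d[field] = {o: {sex: tuple(v) for sex, v in by_sex.items()}
                        for o, by_sex in d[field].items()}
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def default_config() -> SimulationConfig:
    return SimulationConfig()


def inject_specialization_effect(config: SimulationConfig, category: str,
                                 effect_size: float) -> SimulationConfig:
    """Shift one specialization category's outcomes by ``effect_size`` reference SDs.

    The shift is applied in the performance direction of each outcome (a
    positive effect lowers line-drill times) so a positive value is an
    advantage across the board.  Negative effects are allowed and symmetric.
    """
    if category not in config.specialization_effects:
        raise ValueError(f"unknown specialization category: {category!r}")
    new = SimulationConfig.from_dict(config.to_dict())
    new.specialization_effects[category] += effect_size
    return new


@dataclasses.dataclass
class SimulationTruth:
    """Flattened ground-truth parameters for recovery scoring."""

    params: dict

    def season_model_truth(self, outcome: str) -> dict:
        """Truth for the season-model population terms (natural units) and SDs."""
        p = self.params
        return {
            "phase_mid": p[f"{outcome}.phase_mid.female"],
            "phase_end": p[f"{outcome}.phase_end.female"],
            "sex_male:phase_mid": p[f"{outcome}.phase_mid.male"] - p[f"{outcome}.phase_mid.female"],
            "sex_male:phase_end": p[f"{outcome}.phase_end.male"] - p[f"{outcome}.phase_end.female"],
            "sd_player__Intercept": p[f"{outcome}.sd_player_intercept"],
            "sd_player__phase": p[f"{outcome}.sd_player_slope"],
            "sd_season__Intercept": p[f"{outcome}.sd_season"],
            "sigma": p[f"{outcome}.sd_residual"],
        }

    def to_json(self) -> str:
        return json.dumps(self.params, indent=2, sort_keys=True)


def _growth_curve(adult: float, gain: float, tempo: float, aphv: float,
                  ages: np.ndarray) -> np.ndarray:
    return adult - gain / (1.0 + np.exp(tempo * (np.asarray(ages) - aphv)))


def growth_curve(config: SimulationConfig, sex: str, ages: Iterable[float],
                 adult_stature: float | None = None, aphv: float | None = None) -> np.ndarray:
    """Latent (noise-free) stature curve for one player; monotone in age."""
    g = config.growth[sex]
    return _growth_curve(
        adult_stature if adult_stature is not None else g["adult_mean"],
        g["pubertal_gain"], g["tempo"],
        aphv if aphv is not None else g["aphv_mean"],
        np.asarray(list(ages), dtype=float),
    )


def _draw_onset(rng: np.random.Generator, sex: str, first_age: float,
                probs: dict, refs: ReferenceMilestones) -> float | None:
    cats = list(probs)
    cat = rng.choice(cats, p=np.array([probs[c] for c in cats]) / sum(probs.values()))
    if cat == "unknown":
        return None
    onset_ref, aphv_ref = refs.onset(sex), refs.aphv(sex)
    if cat == "late_puberty":
        hi = min(first_age - 0.3, 16.0)
        if hi <= aphv_ref + 0.1:
            cat = "mid_puberty"  # a young player cannot yet be a late specializer
        else:
            return float(rng.uniform(aphv_ref + 0.1, hi))
    if cat == "mid_puberty":
        return float(rng.uniform(onset_ref, aphv_ref))
    return float(rng.uniform(5.0, onset_ref - 0.2))


def simulate_cohort(config: SimulationConfig | None = None,
                    refs: ReferenceMilestones | None = None,
                    ) -> tuple[ObservationTable, SimulationTruth]:
    """Generate one cohort; same seed, same table, bit for bit."""
    config = config or default_config()
    refs = refs or ReferenceMilestones()
    rng = np.random.default_rng(config.seed)

    seasons = list(range(config.first_season, config.first_season + config.n_seasons))
    season_effects = {
        (o, s): rng.normal(0.0, config.season_sd[o]) for o in OUTCOMES for s in seasons
    }

    attained_vals = sorted(config.attained_age_weights)
    attained_p = np.array([config.attained_age_weights[a] for a in attained_vals], dtype=float)
    attained_p /= attained_p.sum()

    rows: list[dict] = []
    truth_params: dict = {}
    idx = 0
    for sex, n in (("female", config.n_female), ("male", config.n_male)):
        g = config.growth[sex]
        for _ in range(n):
            pid = f"P{idx:04d}"
            idx += 1
            attained = int(rng.choice(attained_vals, p=attained_p))
            first_season = int(rng.choice(seasons))
            birth_year = first_season - attained
            birth_frac = float(rng.uniform())
            adult = rng.normal(g["adult_mean"], g["adult_sd"])
            aphv_true = rng.normal(g["aphv_mean"], g["aphv_sd"])
            mass_mult = np.exp(rng.normal(0.0, config.mass_player_cv))

            delta = aphv_true - refs.aphv(sex)
            if delta < -0.5:
                maturity = "early"
            elif delta > 0.5:
                maturity = "late"
            else:
                maturity = "average"

            first_age = attained + PHASE_FRACTION["pre"] - birth_frac
            onset = _draw_onset(rng, sex, first_age, config.onset_category_probs, refs)
            if onset is None:
                spec_cat = "unknown"
            elif onset < refs.onset(sex):
                spec_cat = "pre_puberty"
            elif onset <= refs.aphv(sex):
                spec_cat = "mid_puberty"
            else:
                spec_cat = "late_puberty"

            p_int = {o: rng.normal(0.0, config.player_intercept_sd[o]) for o in OUTCOMES}
            p_mid = {o: rng.normal(0.0, config.player_slope_sd[o]) for o in OUTCOMES}
            p_end = {o: rng.normal(0.0, config.player_slope_sd[o]) for o in OUTCOMES}

            player_seasons = [first_season]
            if (rng.uniform() < config.p_second_season
                    and first_season + 1 in seasons
                    and attained + 1 <= 17):
                player_seasons.append(first_season + 1)

            prev_stature = -np.inf
            for season in player_seasons:
                age_group = derive_age_group(birth_year, season)
                for phase in PHASES:
                    if rng.uniform() >= config.phase_completion[phase]:
                        continue
                    # ages are recorded to the nearest 0.1 y; the rounded value
                    # is used throughout so the table is self-consistent
                    age = round(season + PHASE_FRACTION[phase] - (birth_year + birth_frac), 1)
                    stature_true = float(_growth_curve(
                        adult, g["pubertal_gain"], g["tempo"], aphv_true, np.array([age]))[0])
                    stature = stature_true + rng.normal(0.0, config.stature_error_cm)
                    stature = max(stature, prev_stature)  # measured stature never shrinks
                    prev_stature = stature
                    mass = (config.mass_allometry["coefficient"]
                            * (stature_true / 100.0) ** config.mass_allometry["exponent"]
                            * mass_mult
                            + rng.normal(0.0, config.mass_error_kg))
                    row = {
                        "player_id": pid, "sex": sex,
                        "chronological_age": age,
                        "season_year": season, "phase": phase, "age_group": age_group,
                        "stature": round(stature, 1), "body_mass": round(mass, 1),
                        "specialization_onset_age": round(onset, 1) if onset is not None else np.nan,
                    }
                    for o in OUTCOMES:
                        mu = config.mean_outcome(o, sex, age, phase, maturity, spec_cat)
                        val = (mu + p_int[o]
                               + (p_mid[o] if phase == "mid" else 0.0)
                               + (p_end[o] if phase == "end" else 0.0)
                               + season_effects[(o, season)]
                               + rng.normal(0.0, config.residual_sd[o]))
                        if config.quantize:
                            if o == "cmj":
                                val = round(val)
                            elif o == "yoyo_ir1":
                                val = max(40.0 * round(val / 40.0), 0.0)
                            elif o == "line_drill":
                                val = round(val, 2)
                        row[o] = val
                    rows.append(row)

    for o in OUTCOMES:
        for sex in ("female", "male"):
            mid, end = config.phase_effects[o][sex]
            truth_params[f"{o}.phase_mid.{sex}"] = mid
            truth_params[f"{o}.phase_end.{sex}"] = end
        truth_params[f"{o}.sd_player_intercept"] = config.player_intercept_sd[o]
        truth_params[f"{o}.sd_player_slope"] = config.player_slope_sd[o]
        truth_params[f"{o}.sd_season"] = config.season_sd[o]
        truth_params[f"{o}.sd_residual"] = config.residual_sd[o]
    for cat, eff in config.specialization_effects.items():
        truth_params[f"spec_effect.{cat}"] = eff
    for st, eff in config.maturity_effects.items():
        truth_params[f"maturity_effect.{st}"] = eff
    for o, s in config.outcome_scales.items():
        truth_params[f"outcome_scale.{o}"] = s

    table = ObservationTable(pd.DataFrame(rows), provenance="synthetic")
    return table, SimulationTruth(truth_params)


def simulate_quadratic_trajectories(
    n_players: int = 120,
    coefs_female: tuple[float, float, float] = (20.0, 1.5, -0.15),
    coefs_male: tuple[float, float, float] = (25.0, 2.5, 0.20),
    player_sd: tuple[float, float, float] = (2.0, 0.3, 0.05),
    noise_sd: float = 0.5,
    age_center: float = 14.0,
    n_occasions: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Pure quadratic growth data for recovery-testing the growth model.

    Each player's trajectory is ``c0 + c1*(age-center) + c2*(age-center)^2``
    (sex-specific population coefficients plus player-level deviations on all
    three) observed at ``n_occasions`` ages spread over 11-17 y, with i.i.d.
    Gaussian noise.  Returns a model-ready frame (the trajectory is stored in the ``cmj``
    column so it can be fitted with ``build_growth_model("cmj")``) and the
    truth dict keyed by population term name.
    """
    rng = np.random.default_rng(seed)
    cats = ("pre_puberty", "mid_puberty", "late_puberty", "unknown")
    rows = []
    for i in range(n_players):
        sex = "female" if i < n_players // 3 else "male"
        c = np.array(coefs_female if sex == "female" else coefs_male, dtype=float)
        c = c + rng.normal(0.0, player_sd, size=3)
        ages = np.sort(rng.uniform(11.0, 17.0, size=n_occasions))
        cat = cats[i % len(cats)]  # exchangeable across categories, zero true effects
        for a in ages:
            d = a - age_center
            y = c[0] + c[1] * d + c[2] * d * d + rng.normal(0.0, noise_sd)
            rows.append({
                "player_id": f"Q{i:04d}", "sex": sex, "chronological_age": a,
                "specialization": cat, "season_year": 2019, "phase": "pre",
                "age_group": "U15", "cmj": y,
            })
    truth = {
        "Intercept": coefs_female[0],
        "age_c": coefs_female[1],
        "age_c2": coefs_female[2],
        "sex_male": coefs_male[0] - coefs_female[0],
        "sex_male:age_c": coefs_male[1] - coefs_female[1],
        "sex_male:age_c2": coefs_male[2] - coefs_female[2],
        "sigma": noise_sd,
    }
    return pd.DataFrame(rows), truth
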