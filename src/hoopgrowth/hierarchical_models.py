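"""Declarative model structures and Bayesian fitting.

Two model families are supported:

* **Season model** - varying-intercept / varying-slope cross-classified model
  of within-season change.  Phase is coded as two treatment indicators
  (mid, end) against the pre-season baseline; sex and sex x phase are
  population-level terms; players, seasons, specialization x sex,
  age-group x sex and maturity x sex carry group-level intercepts (and phase
  slopes for all but season).  For yo-yo IR1 and the composite fitness score,
  2-SD-standardized body mass enters as a population-level covariate; the
  short-maximal outputs (CMJ, line drill) omit it since the influence of body
  size on them is negligible once maturity and age group are in the model.
* **Growth model** - three-level polynomial growth curve: centered
  chronological age and age^2 as population terms (with sex interactions),
  varying intercept/age/age^2 by player (level 2) and by specialization-onset
  group (level 3).

Outcomes are standardized by two standard deviations before fitting;
"unknown" and "not_classified" are ordinary factor levels, partially pooled
like any other.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import gibbs
from .core_data import PHASES
from .fitness_scoring import ScalingRecord, ScoredTable, standardize_2sd
from .specialization import SPECIALIZATION_CATEGORIES
from .maturation import MATURITY_STATUSES

SEASON_OUTCOMES = ("cmj", "line_drill", "yoyo_ir1", "fitness_score")
#: outcomes whose season/growth models carry the standardized body-mass term
BODY_MASS_OUTCOMES = ("yoyo_ir1", "fitness_score")

DEFAULT_AGE_CENTER = 14.0  # years; midrange of the 11-17 developmental window


@dataclasses.dataclass(frozen=True)
class PriorSet:
    """Weakly informative priors, reported verbatim in every fit log."""

    population_sd: float = 5.0          # Normal(0, 5) per population coefficient
    group_sd_rate: float = 1.0          # Exponential(1) per group-level SD
    residual_df: float = 3.0            # half-Student-t(3, 0, 2.5) residual scale
    residual_scale: float = 2.5
    correlation: str = "independent"    # group-level intercept/slope correlation structure

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    backend: str = "hoopgrowth-gibbs"
    #: collapsed scale-update sweeps per coefficient draw; the default mixes
    #: every SD parameter well, 1 is a cheaper choice for large replication
    #: studies where only posterior means/intervals of contrasts are consumed
    scale_sweeps: int = 3

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warm-up must be shorter than the iteration count")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-chain diagnostics")

    @property
    def kept_draws(self) -> int:
        return self.iterations - self.warmup


@dataclasses.dataclass(frozen=True)
class GroupTerm:
    """One grouping factor with its varying coefficients."""

    name: str
    factors: tuple[str, ...]          # data columns whose combination defines levels
    coefs: tuple[str, ...]            # within-block regressors, "Intercept" first


@dataclasses.dataclass
class ModelSpec:
    outcome: str
    kind: str                          # "season" | "growth"
    population_terms: tuple[str, ...]
    group_terms: tuple[GroupTerm, ...]
    priors: PriorSet = dataclasses.field(default_factory=PriorSet)
    standardize: bool = True
    age_center: float = DEFAULT_AGE_CENTER
    big_block: str | None = "player"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_season_model(outcome: str, priors: PriorSet | None = None) -> ModelSpec:
    """Within-season varying-intercept/varying-slope cross-classified model."""
    if outcome not in SEASON_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {SEASON_OUTCOMES}")
    pop = ["Intercept", "phase_mid", "phase_end", "sex_male",
           "sex_male:phase_mid", "sex_male:phase_end"]
    if outcome in BODY_MASS_OUTCOMES:
        pop.append("body_mass_std")
    phase_coefs = ("Intercept", "phase_mid", "phase_end")
    groups = (
        GroupTerm("player", ("player_id",), phase_coefs),
        GroupTerm("season", ("season_year",), ("Intercept",)),
        GroupTerm("spec_sex", ("specialization", "sex"), phase_coefs),
        GroupTerm("agegrp_sex", ("age_group", "sex"), phase_coefs),
        GroupTerm("maturity_sex", ("maturity_status", "sex"), phase_coefs),
    )
    return ModelSpec(outcome=outcome, kind="season", population_terms=tuple(pop),
                     group_terms=groups, priors=priors or PriorSet())


def build_growth_model(outcome: str, priors: PriorSet | None = None,
                       age_center: float = DEFAULT_AGE_CENTER) -> ModelSpec:
    """Three-level quadratic growth model of developmental change."""
    if outcome not in SEASON_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {SEASON_OUTCOMES}")
    pop = ["Intercept", "age_c", "age_c2", "sex_male", "sex_male:age_c", "sex_male:age_c2"]
    if outcome in BODY_MASS_OUTCOMES:
        pop.append("body_mass_std")
    age_coefs = ("Intercept", "age_c", "age_c2")
    groups = (
        GroupTerm("player", ("player_id",), age_coefs),
        GroupTerm("spec_onset", ("specialization",), age_coefs),
    )
    return ModelSpec(outcome=outcome, kind="growth", population_terms=tuple(pop),
                     group_terms=groups, priors=priors or PriorSet(),
                     age_center=age_center)


# ----------------------------------------------------------------------
# design construction

def _term_column(term: str, df: pd.DataFrame, age_center: float) -> np.ndarray:
    n = len(df)
    if term == "Intercept":
        return np.ones(n)
    if ":" in term:
        a, b = term.split(":", 1)
        return _term_column(a, df, age_center) * _term_column(b, df, age_center)
    if term == "phase_mid":
        return (df["phase"] == "mid").to_numpy(dtype=float)
    if term == "phase_end":
        return (df["phase"] == "end").to_numpy(dtype=float)
    if term == "sex_male":
        return (df["sex"] == "male").to_numpy(dtype=float)
    if term == "age_c":
        return df["chronological_age"].to_numpy(dtype=float) - age_center
    if term == "age_c2":
        return (df["chronological_age"].to_numpy(dtype=float) - age_center) ** 2
    if term == "body_mass_std":
        return df["body_mass_std"].to_numpy(dtype=float)
    raise ValueError(f"unknown model term: {term!r}")


def _group_levels(term: GroupTerm, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if len(term.factors) == 1:
        labels = df[term.factors[0]].astype(str)
    else:
        labels = df[list(term.factors)].astype(str).agg(":".join, axis=1)
    levels = sorted(labels.unique())
    index = {lv: i for i, lv in enumerate(levels)}
    return labels.map(index).to_numpy(dtype=int), levels


def model_frame(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``data`` usable by ``spec``: outcome (and required covariates) present."""
    needed = [spec.outcome]
    if "body_mass_std" in spec.population_terms:
        needed.append("body_mass_std")
    if spec.kind == "growth":
        needed.append("chronological_age")
    df = data.dropna(subset=needed).reset_index(drop=True)
    return df


@dataclasses.dataclass
class Design:
    """Assembled numeric design for one spec on one data frame."""

    y_raw: np.ndarray
    X: np.ndarray
    x_names: list[str]
    blocks: list
    levels_map: dict[str, list[str]]
    frame: pd.DataFrame


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Numeric design matrices for ``spec`` on the usable rows of ``data``."""
    df = model_frame(spec, data)
    y_raw = df[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack([
        _term_column(t, df, spec.age_center) for t in spec.population_terms
    ])
    blocks = []
    levels_map: dict[str, list[str]] = {}
    for term in spec.group_terms:
        groups, levels = _group_levels(term, df)
        cov = np.column_stack([_term_column(c, df, spec.age_center) for c in term.coefs])
        blocks.append(gibbs.RandomBlockDesign(
            name=term.name, levels=levels, groups=groups,
            covariates=cov, coef_names=list(term.coefs),
        ))
        levels_map[term.name] = levels
    return Design(y_raw=y_raw, X=X, x_names=list(spec.population_terms),
                  blocks=blocks, levels_map=levels_map, frame=df)


@dataclasses.dataclass
class PosteriorDraws:
    """Labelled posterior samples plus everything needed to interpret them."""

    spec: ModelSpec
    settings: SamplerSettings
    draws: dict[str, np.ndarray]            # parameter -> (chains, draws)
    group_levels: dict[str, list[str]]      # block name -> level labels
    scaling: ScalingRecord | None           # outcome standardization (None if disabled)
    n_obs: int
    divergences: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def population(self) -> dict[str, np.ndarray]:
        return {t: self.draws[t] for t in self.spec.population_terms}

    def group_sds(self) -> dict[str, np.ndarray]:
        return {p: v for p, v in self.draws.items() if p.startswith("sd_")}

    def random_effect(self, block: str, level: str, coef: str) -> np.ndarray:
        key = f"r_{block}[{level},{coef}]"
        if key not in self.draws:
            raise KeyError(
                f"no fitted effect for level {level!r} of block {block!r} (coef {coef!r})"
            )
        return self.draws[key]

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws table: (chain, draw, parameter, value)."""
        frames = []
        for name, arr in self.draws.items():
            c, d = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "draw": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def fit_log(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "kind": self.spec.kind,
            "priors": self.spec.priors.to_dict(),
            "settings": dataclasses.asdict(self.settings),
            "n_obs": self.n_obs,
            "n_parameters": len(self.draws),
            "divergences": self.divergences,
            "scaling": self.scaling.to_dict() if self.scaling else None,
            "warnings": list(self.warnings),
        }


def fit(
    spec: ModelSpec,
    data: ScoredTable | pd.DataFrame,
    settings: SamplerSettings | None = None,
    min_rows: int = 30,
    fixed_tau: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Fit a model spec by MCMC and return labelled posterior draws.

    ``data`` must carry the outcome column plus the factor columns named by the
    spec's group terms (``specialization`` and ``maturity_status`` are added by
    the classification step).  Identical seed, settings and data give
    bit-identical draws.
    """
    settings = settings or SamplerSettings()
    df = data.df if isinstance(data, ScoredTable) else data
    design = build_design(spec, df)
    if len(design.frame) < min_rows:
        raise ValueError(
            f"outcome {spec.outcome!r} present in only {len(design.frame)} rows (< {min_rows})"
        )
    y_raw = design.y_raw
    if not np.all(np.isfinite(y_raw)):
        raise ValueError("non-finite outcome values")
    scaling = None
    y = y_raw
    if spec.standardize:
        y, scaling = standardize_2sd(y_raw, name=spec.outcome)

    big = spec.big_block if any(b.name == spec.big_block for b in design.blocks) else None
    sampler = gibbs.GibbsLMM(
        design.X, design.x_names, design.blocks, y,
        big_block=big, fixed_tau=fixed_tau, scale_sweeps=settings.scale_sweeps,
    )
    raw = sampler.sample(
        n_chains=settings.chains, n_iter=settings.iterations,
        n_warmup=settings.warmup, seed=settings.seed,
    )
    return PosteriorDraws(
        spec=spec, settings=settings, draws=raw, group_levels=design.levels_map,
        scaling=scaling, n_obs=len(design.frame),
    )


def sample_prior(spec: ModelSpec, settings: SamplerSettings | None = None) -> PosteriorDraws:
    """Draws from the prior alone (no likelihood), for prior predictive checks."""
    settings = settings or SamplerSettings()
    rng = np.random.default_rng(settings.seed)
    shape = (settings.chains, settings.kept_draws)
    p = spec.priors
    draws: dict[str, np.ndarray] = {}
    for t in spec.population_terms:
        draws[t] = rng.normal(0.0, p.population_sd, size=shape)
    for term in spec.group_terms:
        for c in term.coefs:
            draws[f"sd_{term.name}__{c}"] = rng.exponential(1.0 / p.group_sd_rate, size=shape)
    draws["sigma"] = np.abs(p.residual_scale * rng.standard_t(p.residual_df, size=shape))
    return PosteriorDraws(
        spec=spec, settings=settings, draws=draws, group_levels={},
        scaling=None, n_obs=0,
    )
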