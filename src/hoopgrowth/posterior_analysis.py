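"""Inferential surfaces: group predictions, contrasts, diagnostics, PPCs.

Predictions are expectations of the linear predictor (epistemic uncertainty
of the group mean, not posterior-predictive spread), summarized by the median
and the central 68% interval - the 16th/84th percentiles, comparable to
plus/minus one standard deviation under approximate normality.  Contrasts
between specialization levels are computed draw-wise, preserving the joint
posterior correlation.  All summaries are pure functions of stored draws;
nothing here resamples.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import PHASES
from .hierarchical_models import (
    Design,
    ModelSpec,
    PosteriorDraws,
    build_design,
    model_frame,
)

#: central interval quantile pairs
Q68 = (0.16, 0.84)
Q90 = (0.05, 0.95)


def _pop_term_value(term: str, factors: dict, age_center: float) -> float:
    if term == "Intercept":
        return 1.0
    if ":" in term:
        a, b = term.split(":", 1)
        return _pop_term_value(a, factors, age_center) * _pop_term_value(b, factors, age_center)
    if term == "phase_mid":
        return 1.0 if factors.get("phase") == "mid" else 0.0
    if term == "phase_end":
        return 1.0 if factors.get("phase") == "end" else 0.0
    if term == "sex_male":
        return 1.0 if factors.get("sex") == "male" else 0.0
    if term == "age_c":
        return float(factors["chronological_age"]) - age_center
    if term == "age_c2":
        return (float(factors["chronological_age"]) - age_center) ** 2
    if term == "body_mass_std":
        # covariate held at the pooled mean (0 on the 2-SD standardized scale)
        return float(factors.get("body_mass_std", 0.0))
    raise ValueError(f"unknown model term: {term!r}")


def _expectation_draws(draws: PosteriorDraws, factors: dict) -> np.ndarray:
    """Posterior draws of the expected (standardized) outcome at one grid point.

    Population terms are evaluated at the grid point; the specialization
    grouping block contributes its fitted effects, all other grouping factors
    are held at their population level (0).
    """
    spec = draws.spec
    eta = np.zeros((draws.n_chains, draws.n_draws))
    for term in spec.population_terms:
        x = _pop_term_value(term, factors, spec.age_center)
        if x != 0.0:
            eta = eta + x * draws.get(term)
    for gt in spec.group_terms:
        if not all(f in factors for f in gt.factors):
            continue
        level = ":".join(str(factors[f]) for f in gt.factors)
        if level not in draws.group_levels.get(gt.name, []):
            raise ValueError(
                f"factor level {level!r} of block {gt.name!r} was not seen in the fit"
            )
        for ci, coef in enumerate(gt.coefs):
            x = _pop_term_value(coef, factors, spec.age_center) if coef != "Intercept" else 1.0
            if x != 0.0:
                eta = eta + x * draws.random_effect(gt.name, level, coef)
    return eta


def build_prediction_grid(draws: PosteriorDraws,
                          ages: Sequence[float] | None = None) -> pd.DataFrame:
    """Every retained sex x specialization combination, crossed with phases
    (season model) or an age grid (growth model)."""
    spec = draws.spec
    block = "spec_sex" if spec.kind == "season" else "spec_onset"
    levels = draws.group_levels[block]
    rows = []
    for lv in levels:
        if spec.kind == "season":
            s, sex = lv.split(":")
            for phase in PHASES:
                rows.append({"sex": sex, "specialization": s, "phase": phase})
        else:
            for a in (ages if ages is not None else np.arange(11.0, 17.01, 0.5)):
                for sex in ("female", "male"):
                    rows.append({"sex": sex, "specialization": lv,
                                 "chronological_age": float(a)})
    return pd.DataFrame(rows)


def predict_expected(draws: PosteriorDraws, grid: pd.DataFrame) -> pd.DataFrame:
    """Median and central 68% interval of the expected outcome per grid point.

    Returns the grid with ``median/lo68/hi68`` on the standardized scale and,
    when a scaling record is attached, ``median_nat/lo68_nat/hi68_nat`` in
    natural units.
    """
    out = grid.copy().reset_index(drop=True)
    med, lo, hi = [], [], []
    for _, row in out.iterrows():
        eta = _expectation_draws(draws, row.to_dict()).reshape(-1)
        med.append(np.median(eta))
        lo.append(np.quantile(eta, Q68[0]))
        hi.append(np.quantile(eta, Q68[1]))
    out["median"], out["lo68"], out["hi68"] = med, lo, hi
    if draws.scaling is not None:
        for col in ("median", "lo68", "hi68"):
            out[f"{col}_nat"] = draws.scaling.inverse(out[col].to_numpy())
    return out


@dataclasses.dataclass
class ContrastResult:
    """Draw-wise difference between two specialization levels within sex."""

    sex: str
    level_a: str
    level_b: str
    points: list            # phases (season model) or ages (growth model)
    diff_draws: np.ndarray  # (n_points, chains, draws), standardized scale
    natural_scale: float    # multiplier from standardized to natural units

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, pt in enumerate(self.points):
            d = self.diff_draws[i].reshape(-1)
            rows.append({
                "sex": self.sex, "level_a": self.level_a, "level_b": self.level_b,
                "at": pt,
                "mean": d.mean(),
                "lo68": np.quantile(d, Q68[0]), "hi68": np.quantile(d, Q68[1]),
                "lo90": np.quantile(d, Q90[0]), "hi90": np.quantile(d, Q90[1]),
                "p_gt0": float(np.mean(d > 0)),
                "mean_nat": d.mean() * self.natural_scale,
                "lo90_nat": np.quantile(d, Q90[0]) * self.natural_scale,
                "hi90_nat": np.quantile(d, Q90[1]) * self.natural_scale,
            })
        return pd.DataFrame(rows)


def contrast_specialization(
    draws: PosteriorDraws,
    sex: str,
    level_a: str,
    level_b: str,
    ages: Sequence[float] | None = None,
) -> ContrastResult:
    """Difference (a minus b) of expected outcomes, computed per draw."""
    spec = draws.spec
    if spec.kind == "season":
        points: list = list(PHASES)
        factor_sets = [
            ({"sex": sex, "specialization": lv, "phase": ph}, ph)
            for ph in points for lv in (level_a, level_b)
        ]
    else:
        points = list(ages if ages is not None else (12.0, 14.0, 16.0))
        factor_sets = [
            ({"sex": sex, "specialization": lv, "chronological_age": a}, a)
            for a in points for lv in (level_a, level_b)
        ]
    diffs = []
    for i in range(0, len(factor_sets), 2):
        fa, _ = factor_sets[i]
        fb, _ = factor_sets[i + 1]
        diffs.append(_expectation_draws(draws, fa) - _expectation_draws(draws, fb))
    natural = 2.0 * draws.scaling.sd if draws.scaling is not None else 1.0
    return ContrastResult(sex=sex, level_a=level_a, level_b=level_b, points=points,
                          diff_draws=np.stack(diffs), natural_scale=natural)


def plot_predictions(predictions: pd.DataFrame, outcome: str = "", ax=None):
    """Sex-faceted ribbon plot of expected outcomes by specialization.

    ``predictions`` is the output of :func:`predict_expected`; the x axis is
    the phase (season model) or chronological age (growth model).  Returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    xcol = "phase" if "phase" in predictions.columns else "chronological_age"
    ycols = ("median_nat", "lo68_nat", "hi68_nat") if "median_nat" in predictions \
        else ("median", "lo68", "hi68")
    sexes = sorted(predictions["sex"].unique())
    fig, axes = plt.subplots(1, len(sexes), figsize=(4.5 * len(sexes), 3.5),
                             sharey=True, squeeze=False)
    for ax_, sex in zip(axes[0], sexes):
        sub = predictions[predictions.sex == sex]
        for cat, grp in sub.groupby("specialization"):
            if xcol == "phase":
                grp = grp.set_index(xcol).loc[["pre", "mid", "end"]].reset_index()
                x = np.arange(3)
                ax_.set_xticks(x, ["pre", "mid", "end"])
            else:
                grp = grp.sort_values(xcol)
                x = grp[xcol].to_numpy()
            line, = ax_.plot(x, grp[ycols[0]], marker="o", ms=3, label=cat)
            ax_.fill_between(x, grp[ycols[1]], grp[ycols[2]],
                             alpha=0.2, color=line.get_color())
        ax_.set_title(sex)
        ax_.set_xlabel("phase" if xcol == "phase" else "chronological age (y)")
    axes[0][0].set_ylabel(outcome or "expected outcome")
    axes[0][-1].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    return fig


# ----------------------------------------------------------------------
# convergence diagnostics

@dataclasses.dataclass
class DiagnosticsReport:
    table: pd.DataFrame          # parameter, rhat, ess_bulk
    divergences: int
    rhat_threshold: float
    ess_threshold: float

    @property
    def passed(self) -> bool:
        ok = (self.table["rhat"] < self.rhat_threshold) & (
            self.table["ess_bulk"] > self.ess_threshold)
        return bool(ok.all()) and self.divergences == 0

    def failures(self) -> pd.DataFrame:
        bad = (self.table["rhat"] >= self.rhat_threshold) | (
            self.table["ess_bulk"] <= self.ess_threshold)
        return self.table[bad]


def diagnostics(
    draws: PosteriorDraws | dict[str, np.ndarray],
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
    parameters: Sequence[str] | None = None,
) -> DiagnosticsReport:
    """Split-chain R-hat and bulk effective sample size per parameter.

    Requires at least two chains.  Computed with arviz from the stored draws
    only; never refits.
    """
    import arviz as az

    raw = draws.draws if isinstance(draws, PosteriorDraws) else dict(draws)
    if parameters is not None:
        raw = {p: raw[p] for p in parameters}
    n_chains = next(iter(raw.values())).shape[0]
    if n_chains < 2:
        raise ValueError("split-chain diagnostics require at least 2 chains")
    idata = az.from_dict(posterior=raw)
    rhat = az.rhat(idata)
    ess = az.ess(idata, method="bulk")
    rows = [
        {"parameter": p, "rhat": float(rhat[p].values), "ess_bulk": float(ess[p].values)}
        for p in raw
    ]
    div = draws.divergences if isinstance(draws, PosteriorDraws) else 0
    return DiagnosticsReport(pd.DataFrame(rows), div, rhat_threshold, ess_threshold)


# ----------------------------------------------------------------------
# posterior predictive checks

@dataclasses.dataclass
class PPCResult:
    table: pd.DataFrame   # statistic, observed, rep_mean, rep_lo95, rep_hi95, tail_prob
    n_replicates: int

    def calibrated(self, lo: float = 0.05, hi: float = 0.95) -> pd.Series:
        return self.table["tail_prob"].between(lo, hi)


def posterior_predictive_check(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_replicates: int = 200,
    seed: int = 0,
) -> PPCResult:
    """Simulate replicate datasets from the posterior and compare summaries.

    Statistics: grand mean, grand SD, and per-(sex, phase or sex) group means
    of the outcome, each with the tail probability P(replicate >= observed).
    """
    spec = draws.spec
    design = build_design(spec, data)
    y_obs = design.y_raw
    if draws.scaling is not None:
        y_obs = draws.scaling.transform(y_obs)
    n = y_obs.size

    total = draws.n_chains * draws.n_draws
    n_rep = min(n_replicates, total)
    sel = np.linspace(0, total - 1, n_rep).astype(int)
    rng = np.random.default_rng(seed)

    beta = np.stack([draws.get(t).reshape(-1)[sel] for t in spec.population_terms], axis=1)
    eta = design.X @ beta.T  # (n, n_rep)
    for b in design.blocks:
        u = np.zeros((len(b.levels), b.n_coefs, n_rep))
        for gi, lv in enumerate(b.levels):
            for ci, coef in enumerate(b.coef_names):
                u[gi, ci] = draws.random_effect(b.name, lv, coef).reshape(-1)[sel]
        eta += np.einsum("nk,nkr->nr", b.covariates, u[b.groups])
    sigma = draws.get("sigma").reshape(-1)[sel]
    y_rep = eta + sigma[None, :] * rng.standard_normal((n, n_rep))

    frame = design.frame
    groups: dict[str, np.ndarray] = {"mean": np.ones(n, dtype=bool)}
    if "sex" in frame.columns:
        for sex in frame["sex"].dropna().unique():
            key = (frame["sex"] == sex).to_numpy()
            if spec.kind == "season" and "phase" in frame.columns:
                for ph in frame.loc[key, "phase"].dropna().unique():
                    groups[f"mean[{sex},{ph}]"] = key & (frame["phase"] == ph).to_numpy()
            else:
                groups[f"mean[{sex}]"] = key

    rows = []
    stats_obs = {"mean": y_obs.mean(), "sd": y_obs.std(ddof=1)}
    stats_rep = {"mean": y_rep.mean(axis=0), "sd": y_rep.std(axis=0, ddof=1)}
    for gname, mask in groups.items():
        if gname == "mean":
            continue
        stats_obs[gname] = y_obs[mask].mean()
        stats_rep[gname] = y_rep[mask].mean(axis=0)
    for name, obs in stats_obs.items():
        rep = stats_rep[name]
        rows.append({
            "statistic": name, "observed": float(obs),
            "rep_mean": float(rep.mean()),
            "rep_lo95": float(np.quantile(rep, 0.025)),
            "rep_hi95": float(np.quantile(rep, 0.975)),
            "tail_prob": float(np.mean(rep >= obs)),
        })
    return PPCResult(pd.DataFrame(rows), n_rep)
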