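# Methods

This note documents the statistical machinery in `hoopgrowth`: the models and
their assumptions, the defaults and why they were chosen, what the synthetic
cohort does and does not emulate, and the numerical decisions a maintainer
would want to know about.

## Maturation pathway

The maturity offset is the predicted time to peak height velocity (PHV) from
the sex-specific age-and-stature linear model

    offset = intercept_sex + slope_sex * (age * stature)        [years]

with the widely used coefficients (female: −7.709133, 0.0042232; male:
−7.999994, 0.0036124) stored in a versioned config block
(`OffsetCoefficients`) so they are auditable and swappable.  Estimated age at
PHV is `age − offset`, reported to 0.1 y.  Three worked examples at published
group means (U13 female 12.5 y/163.3 cm → 11.6 y; U13 male 12.6/165.4 → 13.1;
U15 male 14.2/176.6 → 13.1) serve as regression tests of the frozen
coefficients.

Maturity status compares the estimate with sex reference ages at PHV from
meta-analysis of longitudinal growth studies (11.9 y female, 13.9 y male,
consumed as constants with their 95% intervals).  "Six months" is implemented
as 0.5 decimal years with *inclusive* boundaries: a difference of exactly
±0.5 y is `average`, reading "within plus/minus six months" as a closed
interval.  The offset equations are biased away from the ages around PHV, so
classification is restricted to U13 females and U13/U15 males; all others are
`not_classified` (kept as an ordinary factor level downstream).  The
reference CIs are stored but unused by the default point classifier; an
optional CI-aware mode (classify `average` whenever the difference interval
overlaps the tolerance band) exists but is off, because classification on
point estimates is the conventional rule.  Which assessment occasion defines
a player's status is an open choice; the pre-season (earliest) occasion is
used so that status is a player-level constant in the models.

## Specialization pathway

Onset ages are classified against the reference milestones: before the
growth-spurt onset reference → `pre_puberty`; in the closed interval
[onset reference, PHV reference] → `mid_puberty`; after → `late_puberty`;
missing → `unknown`.  Ties at either boundary fall to `mid_puberty` (the
symmetric reading of "before / between / after").  No rounding is applied:
the classifier is a pure function of the stored value, and values outside
[3, 18] y are rejected as implausible.

## Fitness scoring

The composite is the sum of z-scores of CMJ, line drill (sign-reversed; lower
times are better) and yo-yo IR1.  The z-score reference population is **all
observations pooled** across sex, age group and occasion.  The source
descriptives only make sense under pooled standardization — every female
cell's composite is strongly negative while male composites rise with age —
so this choice is an inference, flagged here as an assumption.  Sample SDs
use the n−1 denominator.  Scoring new data against a fitted pipeline reuses
the stored means/SDs (no re-standardization).

For modelling, outcomes and body mass are standardized by *two* SDs
(output SD exactly 0.5) so binary-predictor coefficients are comparable to
standardized continuous ones; each transform's mean/SD pair is kept in a
`ScalingRecord` for exact back-transformation.

## The two model families

Both are Gaussian hierarchical linear models on the 2-SD standardized scale.

**Season model.**  Phase is coded as two treatment indicators (mid, end)
against the pre-season baseline rather than a linear trend, because the
within-season change need not be monotone and predictions are displayed per
phase.  Population terms: intercept, phase indicators, sex, sex × phase, and
(for yo-yo IR1 and the composite only) standardized body mass.  Group terms,
realized as separate additive cross-classified blocks rather than nested
indices: player (intercept + phase slopes), season (intercept),
specialization × sex, age-group × sex and maturity × sex (each intercept +
phase slopes).  `unknown` and `not_classified` are ordinary levels, partially
pooled like any other.

**Growth model.**  Three levels: occasions within players within
specialization-onset groups.  Population terms: centered age and age², sex,
and sex × age interactions (the sex terms are an assumption — developmental
displays are sex-faceted, and single-sex fits would otherwise be
unidentified); group terms: intercept/age/age² varying by player and by
specialization group.  Age is centered at 14.0 y (midrange of the 11–17
window) to decorrelate the linear and quadratic terms; the centering constant
is recorded in the spec.

**Priors** (reported verbatim in every fit log): Normal(0, 5) per population
coefficient (read as independent margins), Exponential(1) per group-level SD,
half-Student-t(3, 0, 2.5) for the residual scale.  Group-level covariance is
**diagonal**: each varying coefficient has its own SD and intercept/slope
correlations are fixed at zero.  A correlation prior would be the
conventional companion, but the package's conjugate blocked sampler updates
each SD from its collapsed conditional, and the inferential targets (group
expectations and their contrasts) are insensitive to this choice under
weakly informative priors; the `PriorSet` records
`correlation: "independent"` so the assumption is visible in fit logs.

## The sampler

The fitting engine is a blocked Gibbs sampler for Gaussian mixed models
(`hoopgrowth.gibbs`):

1. one exact joint Gaussian draw of *all* coefficients per sweep — the player
   block's precision is block-diagonal (its levels partition rows), so the
   draw uses a Schur complement with batched per-player Cholesky factors and
   the dense solve stays at the size of the remaining design (~80 columns);
2. collapsed scale updates: for each grouping factor, its effects are
   integrated out analytically (Woodbury per level) and each SD is
   slice-sampled from its marginal conditional, then the effects are redrawn
   exactly — a partially collapsed Gibbs step that eliminates the
   funnel-shaped SD/effect coupling entirely.  Rank-one updates (for each SD)
   and a per-level eigendecomposition (for σ) make every slice evaluation
   O(levels) scalar work;
3. σ is updated with the player block marginalized, since those effects
   dominate its coupling.

Default settings are 4 chains × 2,000 iterations with 1,000 warm-up and
3 scale sweeps per coefficient draw, which delivers R̂ < 1.01 and bulk
ESS > 400 for every parameter of the season model at n ≈ 500.  Replication
studies that only consume posterior means and interval endpoints of
contrasts use `scale_sweeps=1` (about 2.5× faster at ~10% efficiency for the
slowest SD).  There is no trajectory integration, hence no divergences; the
reported divergence count is identically zero, and the configured >1%
divergence warning threshold applies only to backends that produce them.
Determinism: one integer seed; chain c draws from
`SeedSequence([seed, c])`; identical seed + settings + data give
bit-identical draws.

Numerical choices: scale parameters are slice-sampled on the log scale
(stepping-out width 1.0, shrinkage; Neal 2003); SDs are floored at 1e-12
when inverted; eigenvalues of the per-level Gram matrices are clipped at
zero; a pinned SD (`fixed_tau`) bypasses its update, which is how the
complete-pooling limit is verified.

## Posterior analysis

Predictions are **expectation** ribbons: posterior draws of the linear
predictor at a grid point, summarized by the median and the central 68%
interval (16th/84th percentiles, ≈ ±1 SD under normality) — epistemic
uncertainty of the group mean, not posterior-predictive spread.  The grid
covers every retained sex × specialization level; other grouping factors are
held at their population level and standardized body mass at 0 (the pooled
mean), the conventional mean-covariate display.  Contrasts are computed
draw-wise (preserving posterior correlation), never from marginal summaries,
and carry 68%/90% intervals, P(Δ > 0), and natural-scale equivalents via the
scaling records.  Diagnostics (split-chain R̂, bulk ESS via ArviZ) and
posterior predictive checks (replicate mean/SD/group-mean tail
probabilities) are pure functions of stored draws.

One caveat on the ±1 SD ≈ 68% reading: in the cross-classified season model
the population intercept and phase terms trade off against the
group-intercept blocks, so their marginals are mixture-shaped; the
equivalence holds for well-identified coefficients (verified on the
body-mass term and on intercept-only fits).

## Synthetic cohort

The generator (`synthetic_cohort`) emulates the *structure* the analysis
assumes: ~180 players (40 female / 141 male) across U13/U15/U17, three phases
per season over 2017–2019, a 35% chance of a second season, and phase
completion probabilities (0.85/0.85/0.68) giving ≈500 observations with the
kind of imbalance multi-season testing produces.  Stature follows a
logistic-velocity sigmoid `H − gain/(1 + exp(tempo·(age − aPHV)))` — the
simplest monotone family with an identifiable PHV — with per-player adult
stature and aPHV; defaults (female 169 ± 5.5 cm adult, aPHV 11.4 ± 0.5 y,
tempo 0.9, gain 29 cm; male 189 ± 7, 13.1 ± 0.55, 0.8, 39.4) give realistic
peak velocities of 6.5–8 cm/y and pre-season cell means within 1 SD of the
published descriptives.  Body mass is allometric
(13.4 · (stature/m)^2.9 · lognormal player multiplier).  Measurement error
uses the documented technical errors (0.25 cm, 0.42 kg); measured stature is
made non-decreasing within player (the latent curve is monotone and the
0.25 cm error would otherwise produce spurious shrinking).  Ages are recorded
to 0.1 y and the rounded value feeds the mean functions, so the stored table
is exactly self-consistent in the noise-free limit.

Outcome means are quadratics in age per sex, calibrated to the published
pre-season cells (e.g. male CMJ 31.5 + 2.18·(age − 12.5) cm); female phase
effects encode the observed slight within-season improvement (e.g. CMJ
+0.5/+0.8 cm at mid/end) while male phase effects are zero (maintenance) —
the study conditions.  Specialization and maturity effects default to zero
(the null world).  Variance components (e.g. CMJ: player intercept SD 3.8,
phase-slope SD 0.8, season SD 0.5, residual SD 1.5 cm) are chosen for
testability — the source reports no within-player correlation estimates, so
these are *not* estimates of the real components.  CMJ is quantized to 1 cm,
line drill to 0.01 s and yo-yo to the 40 m shuttle, matching recording
practice; quantization can be disabled, which is how the noise-free identity
with the mean function is tested.  Onset ages are drawn from a category
mixture (46/33/7/14% pre/mid/late/unknown) with uniform ages inside each
category's window; a "late" draw for a player too young to be past PHV is
demoted to mid — which is why late-puberty U13 males never occur, as in the
real sample.

Injected effects (`inject_specialization_effect`) are expressed in units of
per-outcome reference SDs (`outcome_scales`: CMJ 7 cm, line drill 2.8 s,
yo-yo 390 m, composite 2.5), applied in the performance direction of each
test, and recovery is scored in the same units.  The realized pooled SD of a
cohort also contains age-driven spread, so these reference scales — not the
realized SDs — define the injection unit, keeping the
simulate → fit → contrast loop exactly self-consistent.

What passing tests on this generator do **not** show about real data: the
generator is conditionally Gaussian with completely-at-random missingness,
linear-in-indicator phase effects and no specialization–maturation–fitness
confounding beyond what the classifier induces, so recovery results certify
the *pipeline*, not the realism of those assumptions; informative dropout,
multi-sport histories and physiology-level structure are out of scope.

## Problem sizes

The null-coverage study uses 20 replicate cohorts at the default size with
4 chains × 1,000 iterations (500 warm-up, `scale_sweeps=1`) per fit; the
injected-effect study uses one 300-player cohort at the same sampler
settings; the diagnostics contract is checked at the full default
4 × 2,000/1,000.  These sizes were chosen so the whole validation suite runs
on a single CPU in well under half an hour while keeping every check at the
stated statistical strength.

## Known limitations

* Group-level correlations are not modelled (diagonal covariance, above).
* The maturity-offset equations themselves are biased at the age extremes;
  no numeric correction is applied because none is established.
* The pooled z-score reference population is an inference from the published
  descriptive pattern, not a documented choice of the source analysis.
* Contrast intervals for sparsely populated cells (e.g. female
  late-puberty/unknown) are prior-dominated and shrink toward zero — by
  design under partial pooling, but worth remembering when reading them.
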