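# hoopgrowth

Does specializing in basketball before puberty give young players a physical-fitness
advantage?  `hoopgrowth` implements the full analysis pathway used to answer that
question in longitudinal youth-basketball testing data: maturation-referenced
classification of specialization onset, composite fitness scoring, and hierarchical
Bayesian models of within-season and developmental fitness change — plus a
synthetic-cohort generator with known ground truth so every step can be validated by
parameter recovery.

It is written for sport scientists and biostatisticians working with repeated
fitness testing of adolescent athletes (one row per player × assessment occasion:
anthropometry, countermovement jump in cm, line-drill time in s, yo-yo IR1 distance
in m).

## The model

**Maturation.** The maturity offset (years to peak height velocity, PHV) is
predicted from the sex-specific age-and-stature equation
`offset = a_sex + b_sex · (age · stature)`; estimated age at PHV is
`aPHV = age − offset`.  Players are *early / average / late* maturers when their
aPHV is more than six months below / within six months of / more than six months
above the sex reference aPHV (11.9 y female, 13.9 y male).  The offset equation is
only trusted near PHV, so the status applies to U13 females and U13/U15 males;
everyone else is *not classified*.

**Specialization.** The self-reported onset age of exclusive, year-round basketball
is classified against the reference pubertal milestones (growth-spurt onset 9.4 y
female / 11.1 y male; aPHV 11.9 / 13.9): *pre-puberty* (early specialization),
*mid-puberty*, *late-puberty*, or *unknown* when unreported.

**Fitness score.** Each test is standardized against the pooled mean/SD of all
observations; the composite is `z_CMJ − z_linedrill + z_yoyo` (line-drill reversed
because lower times are better).

**Season model.** For each outcome y (2-SD standardized),

```
y ~ 1 + mid + end + male + male:mid + male:end (+ mass_std)
    + (1 + mid + end | player) + (1 | season)
    + (1 + mid + end | specialization:sex)
    + (1 + mid + end | age_group:sex)
    + (1 + mid + end | maturity:sex)
```

with Normal(0, 5) population priors, Exponential(1) group-SD priors, and a
half-Student-t(3, 0, 2.5) residual scale.  The body-mass covariate enters only for
yo-yo IR1 and the composite (body size barely influences the short maximal tests).

**Growth model.** A three-level quadratic growth curve:
`y ~ 1 + age_c + age_c² + sex interactions + (1 + age_c + age_c² | player)
+ (1 + age_c + age_c² | specialization)`, age centered at 14 y.

Models are fitted by a blocked Gibbs sampler written for this package (exact joint
Gaussian coefficient draws with a Schur complement on the player block; collapsed
slice-sampling updates for every SD), 4 chains × 2,000 iterations with 1,000
warm-up by default, with split-chain R̂ / bulk-ESS diagnostics via ArviZ and
posterior predictive checks.

## Worked example

```python
from hoopgrowth import (SimulationConfig, simulate_cohort, build_analysis_frame,
                        build_season_model, fit, SamplerSettings,
                        contrast_specialization, age_at_phv)

# the headline maturation computation: U13 female group means
print(round(float(age_at_phv("female", 12.5, 163.3)), 1))   # -> 11.6

table, truth = simulate_cohort(SimulationConfig(seed=1))    # ~180 players, null effects
frame, _ = build_analysis_frame(table)                      # classify + score
draws = fit(build_season_model("fitness_score"), frame,
            SamplerSettings(seed=1, iterations=1000, warmup=500, scale_sweeps=1))
c = contrast_specialization(draws, "male", "pre_puberty", "mid_puberty")
print(c.summary()[["at", "mean", "lo90", "hi90"]].round(3))
```

prints the estimated age at PHV (`11.6`) and, for the null cohort, a
pre- vs mid-puberty contrast whose 90% intervals cover zero at every phase:

```
    at   mean   lo90   hi90
0  pre  0.049 -0.012  0.128
1  mid  0.059 -0.007  0.140
2  end  0.055 -0.010  0.132
```

(standardized scale; exactly reproducible with these seeds).  That is the
computational form of the study's conclusion: early specialization confers no
detectable fitness advantage.

The numbered scripts under `analysis/` run the same pipeline as a narrative:
simulate (01), classify (02), score (03), fit season models (04), fit growth
models (05), and run the recovery study (06), each writing tables under
`results/`.  A `hoopgrowth` CLI wraps the same calls
(`hoopgrowth simulate/classify/score/fit-season/fit-growth/run-all/report`).

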