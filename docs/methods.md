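# Methods

## Model

The unit of analysis is the domain-year cell: 112 detailed domains (8
states/territories x 7 adult age groups x 2 sexes, totally ordered by
state, then age, then sex) by 21 calendar years, 2352 cells. Only
survey-year cells with respondents enter the likelihood; non-survey years
and structurally empty domains are missing, and their prevalence is a
posterior predictive quantity.

Direct estimates are survey-weighted means with delete-a-group jackknife
standard errors, `SE^2 = (R-1)/R * sum_c (yhat^(c) - yhat)^2`. The model
consumes each observed cell as a continuous binomial observation with
effective size `n_eff = yhat(1-yhat)/SE^2` and effective count
`y_eff = n_eff * yhat` — the design-effect identity, the canonical
effective-sample-size pseudo-likelihood construction. `n_eff`/`y_eff` are
kept real-valued; the binomial likelihood is evaluated with log-gamma
coefficients, avoiding rounding bias in small cells.

Linear predictor on the logit scale:

    eta_dt = beta' x_dt + v_d + z_t v_d^yr + u_t^(s(d))

* 22 fixed effects: intercept; standardized year `z_t = (t - 2011)/sd`
  (sample SD of 2001..2021, denominator n-1, so z ranges about +-1.61);
  male; 6 age contrasts; 7 state contrasts; 6 male-by-age contrasts.
  References: female, 18-24, ACT. Prior N(0, 100) per coefficient.
* `v_d ~ N(0, sigma_I^2)` domain random intercepts, `v_d^yr ~ N(0,
  sigma_S^2)` domain random slopes on `z_t`, independent.
* `u^(s)` one RW1 series per sex-by-age cell (14 series, shared scalar
  innovation variance sigma_RW1^2), sum-to-zero over the 21 years per
  series. The constraint removes the level direction (carried by the fixed
  effects); the series' remaining shape captures common non-linear
  departures from the linear trend within a sex-age cell. A second-order
  walk is available as a config variant (`rw_order=2`, constrained the same
  way) but is not the default.
* Half-normal(scale 1) priors on the three standard deviations. The scale
  is configurable; 1 on the logit scale is weak for effects of this size.
* The binomial dispersion is fixed at 1 (no extra dispersion parameter).

## Sampler

Blocked Gibbs with Pólya-Gamma augmentation. Conditional on the auxiliary
variables, beta, v, v^yr and each RW1 series have exact Gaussian
conditionals (the RW1 draw is a 21-dimensional Gaussian conditioned on the
sum-to-zero constraint by kriging). PG(b, z) variables with real-valued
shape b are drawn from the truncated gamma-series representation (200
terms) plus the analytic mean of the discarded tail; the truncation error
is orders of magnitude below Monte-Carlo noise (validated against closed
forms for the mean and the variance at z = 0).

Plain Gibbs mixes arbitrarily slowly along likelihood-invariant directions
of this model: the time-invariant span of the fixed effects is confounded
with the mean structure of v; the year coefficient with the mean of v^yr
and with the common linear trend of the RW1 series; and each series'
linear-trend component with the mean domain slope of its 8 domains. Four
exact extra moves fix this: an interweaving translation sweep of the
projection of v onto the time-invariant design into beta; scalar sweeps
between the year coefficient and (a) the mean of v^yr, (b) the common RW1
trend; a per-series sweep between each RW1 series' trend and its domains'
mean slope; and ASIS rescaling moves that re-draw each scale parameter in
the non-centered parameterization. All are Gibbs updates along exact
conditional distributions, so the invariant posterior is unchanged. On the
recovery run they reduce the worst R-hat from ~1.7 to ~1.01 and raise the
minimum ESS to several hundred per 2000 retained draws.

Scales are updated by univariate slice sampling on log sigma. mu is
clamped to [1e-12, 1-1e-12] in likelihood evaluations (stored float32
draws are clamped to [1e-7, 1-1e-7]). Chains are seeded from one master
seed via `default_rng([seed, chain])`; initialization sets the intercept
to the pooled logit rate with a small per-chain jitter.

The reference protocol is 3 chains x 10000 iterations after 1000 burn-in,
thinned by 5 (6000 retained draws); convergence is declared when all
monitored split-chain R-hats are below 1.1. The test suite and acceptance
script use reduced runs (2 chains x 2000 or x 1000 iterations) — chosen as
the package's own default trade-off for its synthetic problem sizes, at
which the same R-hat threshold is met.

## Aggregation and assessment

Aggregates (national, state, age, sex, sex-by-age, sex-by-state) are
population-weighted means of the detailed prevalence draws with
year-specific population weights, aggregated per draw *before* taking
posterior summaries; intervals are equal-tailed percentiles, never normal
approximations. Consistency with aggregated direct estimates is checked by
standardized differences (|diff| / direct SE > 2 flags a cell); no
benchmarking constraint is imposed.

WAIC, DIC and PSIS-LOO (Pareto-smoothed importance sampling, shape
diagnostic flagged above 0.7) use the standard draw-based definitions on
the per-cell log-likelihood matrix; the observation unit is the domain-year
cell, the model's likelihood unit. Posterior predictive checks simulate
binomial replicates at the cells' rounded effective sizes and report tail
probabilities of declared statistics (per-year mean, maximum cell
prevalence, zero-cell count).

## Joinpoint analysis

Trends are fitted on `log(prevalence)` with the continuous hinge basis
`log p_t = a + b t + sum_k delta_k max(0, t - tau_k)`. For fixed K the
joinpoints are found by exhaustive grid search over observation-grid
placements with at least 2 years between joinpoints and none in the
first/last 2 years; homoscedastic least squares by default (the
inverse-variance weighted variant uses the trend SEs). K is selected by
sequential permutation tests on the residual-permutation null with
statistic RSS(k_min)/RSS(k_max) and Bonferroni level alpha/(k_max - k_min)
per stage (defaults: K_max 4, alpha 0.05, 499 permutations). APC_k =
100(exp(slope_k)-1); AAPC over a period uses calendar-year segment weights
with a delta-method CI on the weighted slope (t quantiles, residual df);
the empirical-quantile CI variant used by some joinpoint software is a
known alternative and not implemented.

## Synthetic-data generator

The generator defines the study conditions. Truth surfaces are drawn from
the model above with fixed effects defaulting to values that produce a
realistic national decline from roughly 24% to 12% over the window, higher
male prevalence, much lower prevalence at 70+, and variance parameters
sigma_I^2 = sigma_S^2 = 0.04, sigma_RW1^2 = 0.07. The population table
emulates estimated-resident-population statistics: ~19M adults, state
shares from ~32% (NSW) down to ~0.9% (NT), mild annual growth, small
lognormal cell jitter.

Surveys are stratified by state; clusters (area units counted in
dwellings, mean 120) are selected by systematic PPS on a randomly ordered
frame, ~30 dwellings per selected cluster by SRS, one adult per dwelling
with probability inversely proportional to the number of adults (1-3), 85%
response. Base weights are inverse inclusion probabilities calibrated to
in-scope state totals. Cluster allocations give roughly 15000 respondents
per wave, scaled per wave to mirror the uneven achieved sizes of the seven
rounds (largest in 2005; the final wave ~35% smaller); female
participation is 10% above male; adults 70+ in NT are a deterministic
zero-sample domain. Replicate weights: clusters partitioned into R = 60
random groups within strata (R = 30 in 2001), group c zeroed and the rest
rescaled by R/(R-1); strata with fewer clusters than R fall back to
person-level groups with a logged warning.

What the generator does **not** emulate: dwelling/household structure
beyond its effect on adult weights, seasonality of enumeration, item
nonresponse, COVID-era design changes, calibration to age-sex benchmarks
(state totals only), and year-to-year redesigns of any single state's
sample. Passing tests therefore demonstrate the method's behaviour under a
faithful but idealized design, not under every artefact of real survey
operations.

## Numerical choices and edge cases

* Boundary direct estimates (yhat in {0,1} or numerically zero SE) are kept
  in the likelihood via the shrunken rate (y+0.5)/(n+1) at SRS variance
  (n_eff = n), flagged. Implied design effects below 1/4 in tiny cells are
  treated as jackknife artifacts and n_eff capped at 4n, flagged.
* Domain-years with no respondents are emitted as missing, never zeros.
* CV is undefined at yhat = 0 (missing marker, no division error); the
  caution threshold is 25%.
* Joinpoint selection on a flat series degenerates to K = 0; series with
  nonpositive values are skipped with a log entry.
* All stages are deterministic given their seed; the pipeline derives
  per-stage seeds from one master seed.

## Known limitations

* Posterior CVs of extreme cells (prevalence below ~10%, a few dozen
  respondents, endpoint years where |z_t| is maximal) can exceed the 25%
  threshold even though the average precision gain over the direct
  estimator is better than two-fold; the endpoint uncertainty of the
  domain random slope dominates there.
* No spatial CAR term (the final model has none; the machinery would be an
  extension), no covariates beyond the design factors, no benchmarking
  adjustment forcing aggregated model totals to match direct totals.
* The permutation test's Bonferroni sequence is conservative for K_max > 1.
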