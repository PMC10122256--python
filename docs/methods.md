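# Methods

This document specifies the statistical model, the synthetic-cohort
generator, the preprocessing rules, the sampler, and the numerical choices
behind them. Everything here is implemented in `src/headerlag/` and
exercised by the test suite.

## 1. Data structure

An observation is one response-time (RT) trial inside a **block**: a set of
consecutive trials of one task (pro-point or anti-point) by one athlete in
one phase (pre- or post-session) on one day. Exposure data are daily
header counts per athlete, split into **short** headers (close range) and
**long** headers (goal kicks and similar, higher impact velocity). Control
athletes have no header exposure but complete the same test blocks.

## 2. Model

For a correct trial in block *j* by athlete *i*:

```
rt ~ Normal(mu_j, sigma_resid)

mu_j = beta1[task] + u_i
     + beta_short[task] * x_short_j(hl_short[task])
     + beta_long[task]  * x_long_j(hl_long[task])
     + beta_practice[task] * n_prev_sessions_j
     + beta_dev * days_since_first_j
     + beta_carry[task] * carry_j(hl_carry[task])
     + beta_age * (age_i - mean age)

u_i ~ Normal(0, sigma_subject)
```

The exposure covariates are distributed lags with free half-lives:

```
x_short_j(hl) = sum over past header days d of  n_short_d * 2^(-lag_jd / hl)
```

and likewise for `x_long_j`. `lag_jd` is the time from header day *d* to
block *j*'s test; pre-session blocks exclude the same day's headers
(lag > 0 strictly), post-session blocks include them at lag 0. Because
`hl` sits inside the weights, the regression is non-linear and magnitude
(ms per header) and longevity (days) are estimated jointly.

The remaining terms are confounder controls: `n_prev_sessions` counts
completed test sessions (practice/learning effect), `days_since_first`
captures developmental drift over the season, `carry` is a decay-weighted
count of previous *same-day post-session tests* (fatigue/carryover from
testing itself), and `age` is the athlete's age centred at the sample
mean. One subject intercept `u_i` is shared across tasks and phases.

### Half-life support

Half-lives live on `(0.5, 500]` days. Below half a day the weight decays
within a single session and is unidentifiable from block-level data; the
500-day cap is roughly an order of magnitude beyond the observation window,
where the weight function is already indistinguishable from constant
(`2^(-29/500) = 0.9606` after a full season). A posterior piling up near
the cap therefore reads as "no measurable decay within the study window".

### Priors

| parameter | prior | rationale |
|---|---|---|
| `beta1_pro`, `beta1_anti` | Normal(500, 150) | weakly informative around plausible adolescent RTs |
| header / practice / carryover coefficients | Normal(0, 20) | effects beyond ±40 ms/header are implausible |
| `beta_dev`, `beta_age` slopes | Normal(0, 5) / Normal(0, 20) | per-day and per-year drifts are small |
| all half-lives | Uniform(0.5, 500] | the support is the prior; no decay-rate preference |
| `sigma_subject`, `sigma_resid` | Half-Normal(100) | scale of RT variation |

### Collapsed likelihood

The subject intercepts are Gaussian given everything else, so they are
integrated out analytically: the sampler explores only the 20
population-level parameters, and for each saved draw the `u_i` are then
drawn exactly from their Gaussian conditional. For athlete *i* with `n_i`
correct trials, residual mean `r_i` and residual sum of squares around
that mean `SSE0_i`:

```
log p(data_i) = -n_i/2 * log(2*pi*sigma_resid^2)
              - 1/2 * log1p(n_i * sigma_subject^2 / sigma_resid^2)
              - SSE0_i / (2*sigma_resid^2)
              - n_i * r_i^2 / (2*(sigma_resid^2 + n_i*sigma_subject^2))
```

This reduces to the plain likelihood at `sigma_subject = 0` (verified by a
test) and matches numerical quadrature over `u_i` to a relative 1e-7
(also tested). Within a block all trials share `mu_j`, so the likelihood
needs only per-block sufficient statistics (count, sum, sum of squares),
not individual trials.

## 3. Synthetic cohort generator

`GeneratorConfig` defaults encode the emulated study design; they are the
study conditions, not tuning knobs:

| quantity | default | unit |
|---|---|---|
| exposed / control athletes | 16 / 14 | — |
| season length | 29 | days |
| sessions per week | uniform on 1–4 | — |
| age, exposed | Normal(15.7, 0.7), clipped to [13, 18] | years |
| age, control | Normal(14.9, 1.1), clipped to [13, 18] | years |
| headers per session | negative binomial, mean 6.5 | — |
| header dispersion | tuned so the median is 5 | — |
| long-header fraction | 1/7 | — |
| trials per block | 48 | — |
| P(incorrect response) | 0.036 | — |
| P(outlier contamination) | 0.042 of correct trials | — |
| outlier shift | +600 | ms |

Generating parameter values default to the fitted population-level
estimates for this cohort (`reported_study_parameters()`): intercepts
450.64 / 540.43 ms, short-header coefficients −1.10 / −1.17 ms with
half-lives 5.19 / 6.51 days, long-header coefficients 3.69 / 3.20 ms with
half-lives 309.07 / 358.08 days, practice effects −5.21 / −7.34 ms per
session, development −30.94 ms over 91 days. Quantities without a
reported value use defaults chosen for realism: carryover −10 ms with
half-lives 4 / 40 days, age slope −10 ms/year, `sigma_subject` 30 ms,
`sigma_resid` 100 ms.

The generator draws the roster/schedule, the header exposures and the RT
noise from three independent substreams of one seed, so changing exposure
settings shifts block means without perturbing trial noise (tested).
Generated RTs are floored at 1 ms as a physical constraint; at the default
means this triggers on roughly one trial in tens of thousands.

**Scope and non-goals.** The generator reproduces the study *design* and
the model's own data-generating process. It does not model trial-level
sequential effects, RT skew (real RT distributions are right-skewed; the
model and generator are both Gaussian), dropout, or measurement error in
header counts. It exists to validate the estimation machinery
(recovery of known parameters), not to impersonate raw experimental data.

## 4. Preprocessing

1. Drop incorrect-response trials (RT on an error trial measures a
   different process).
2. Within each block, iteratively test the most extreme RT with a
   chi-squared single-outlier statistic, `(x - mean)^2 / s^2` with the
   usual ddof-1 variance, against `chi2(1)` at `alpha = 0.005`; remove
   and repeat until nothing exceeds the threshold (at most
   `max_iterations = 10` removals per block).

`alpha = 0.005` was calibrated analytically before any acceptance runs:
with 48 trials per block, a per-trial false-positive rate of 0.005 keeps
expected clean-trial removal near 0.2–0.5% (well under a 1% budget) while
a +600 ms shift at `sigma_resid = 100` gives a per-outlier statistic of
roughly 36, far beyond the `chi2(1)` 0.005 quantile of 7.88, so recall on
planted outliers stays above 90%. A looser 0.05 would remove several
percent of clean trials.

## 5. Inference

`fit()` runs independent chains (default 4) of an adaptive Metropolis
sampler on unconstrained parameters:

- **Transforms.** Identity for coefficients, `log` for the two sigmas, a
  scaled logit mapping onto `(0.5, 500]` for half-lives, with log-Jacobian
  corrections. The logistic is clipped to `[1e-15, 1 - 1e-15]` so extreme
  proposals cannot underflow onto the boundary.
- **Single-site random-walk updates** with Robbins–Monro step-size
  adaptation toward a 0.44 acceptance rate.
- **Joint adaptive-Metropolis moves** (3 per sweep, scale `2.38/sqrt(d)`)
  using an empirical covariance estimated during warmup. The covariance is
  computed twice: mid-warmup (so the second warmup half already mixes along
  correlated directions) and again at the end of warmup from the improved
  samples. This matters for the intercept–age–variance block, whose
  posterior correlation otherwise slows mixing badly.
- **Diagnostics.** Split-R-hat and effective sample size via ArviZ;
  `converged` requires R-hat < 1.01 and ESS > 400 for every free
  parameter. Non-convergence is flagged with messages, never silently
  ignored.

Default production settings are 4 chains × (1500 warmup + 6000 draws),
about four minutes for the default cohort (~34k correct trials collapsing
to 768 blocks) on one CPU.

### Known posterior geometry

- `hl_long` is weakly identified by design: a 29-day window cannot
  separate half-lives of 300 vs 3000 days. Its posterior is wide (95%
  intervals several hundred days) and the package treats that as the
  correct answer.
- `hl_carry_*` and `beta_carry_*` are weakly identified for the same
  reason (few distinct carryover configurations in a month).
- With one short season, individual parameter estimates carry
  realization-level variance: on any single simulated cohort one or two of
  the twenty parameters can land outside its 95% interval even though the
  estimator is unbiased across seeds (checked with a multi-seed
  maximum-likelihood study during development).

## 6. Projection

`Scenario` / `project_forward` evaluate the accumulated short- and
long-header effects for a given header history at point estimates, and
shift the whole history backward by rest days. Because the decay is
exponential, the short effect (half-life under a week) shrinks by more
than half within one half-life of rest while the long effect (half-life
near a year) is essentially flat over any plausible rest period — the
quantitative basis for "recent headers wash out in days, but the long-ball
effect accumulates over a season".

## 7. Numerical choices

- Decay weights use `2**(-lag/hl)`; base 2 makes the half-life the natural
  unit. `base` is configurable for sensitivity analyses.
- Exposure accumulation is vectorized over blocks with `np.inf`-padded lag
  matrices (`2**(-inf) = 0` handles the padding exactly); it matches a
  per-header brute-force sum to relative 1e-10 (tested on 1000+ random
  configurations).
- Likelihood evaluation uses per-block sufficient statistics; with 48
  trials per block this is a ~48× reduction in work per posterior
  evaluation.
- CSV interchange writes floats with `repr()` (shortest round-trip
  representation) and reads with `float_precision="round_trip"`, so
  `read_dataset(write_dataset(d)) == d` exactly.
- All randomness flows from `numpy.random.SeedSequence` spawns; every
  stage and chain has an independent substream and every result is
  bit-reproducible given the seed.

## 8. Limitations

- Gaussian RT likelihood (no skew, no lapses beyond the preprocessing
  stage); robust likelihoods are future work.
- Half-lives above the season length are reported but not resolved; only
  a longer observation window can identify them.
- The random-walk sampler is adequate at this problem size (20 free
  parameters, hundreds of blocks) but would not scale to trial-level
  non-collapsed formulations; a gradient-based sampler would.
- The generator shares the model's functional form, so recovery tests
  validate the machinery under a correctly specified model, not robustness
  to misspecification.
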