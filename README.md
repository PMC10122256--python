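# headerlag

Bayesian distributed-lag modelling of how repetitive head impacts (soccer
headers) affect response time in adolescent athletes.

## The science

Heading a football is a sub-concussive impact. A season of them may leave
transient traces in cognitive performance, but two questions are hard to
answer with ordinary regression: *how big* is the effect of one header, and
*how long* does it last? This package answers both jointly. Every past
header enters the model through an exponentially decaying weight

```
weight(lag, hl) = 2 ** (-lag / hl)
```

so a header `hl` days ago counts half as much as one today. The half-life
`hl` is a free parameter estimated from the data — one per header type
(short headers from close range, long headers from goal kicks and similar)
and per task — which makes the regression non-linear. Response time on a
pro-point (look toward the stimulus) or anti-point (look away; more
executive control) task is modelled as

```
rt ~ Normal(mu, sigma_resid)
mu = intercept[task] + u_athlete
     + beta_short[task] * x_short(hl_short)   # decay-weighted short headers
     + beta_long[task]  * x_long(hl_long)     # decay-weighted long headers
     + practice, development, carryover and age terms
```

with a per-athlete random intercept `u_athlete`. Short-header effects turn
out fast and transient (half-life under a week); long-header effects are
several times larger per header and fade on a timescale the study window
cannot pin down (posterior for `hl_long` spans hundreds of days — a finding,
not a failure: the data genuinely cannot distinguish "months" from
"years").

The package provides:

- `headerlag.cohort` — a synthetic cohort generator reproducing the study
  design (16 exposed + 14 control athletes, 29-day season, 48-trial RT
  blocks before and after each session, planted incorrect responses and
  attention-lapse outliers),
- `headerlag.preprocessing` — incorrect-trial removal and an iterative
  chi-squared outlier test,
- `headerlag.covariates` — vectorized decay-weighted exposure covariates,
- `headerlag.model` / `headerlag.inference` — the log-posterior with the
  athlete intercepts integrated out analytically, and an adaptive
  Metropolis sampler with convergence diagnostics,
- `headerlag.projection` — scenario projections ("what if the athlete
  rests 10 days?"),
- a `headerlag` CLI and a `run_all` pipeline tying the stages together.

See [docs/methods.md](docs/methods.md) for the full model, priors,
generator and sampler details.

## Worked example

Point estimates for the anti-point task: `beta_short = -1.17` ms/header
with half-life 6.51 days, `beta_long = 3.20` ms/header with half-life
358.08 days. An athlete's recent history is 36 short and 6 long headers
spread over four sessions 3, 5, 7 and 8 days ago.

```python
import headerlag as hl

params = hl.reported_study_parameters()
scenario = hl.example_scenario(params, task=hl.Task.anti_point)
print(scenario.events)
# [(3.0, 9, 2), (5.0, 9, 2), (7.0, 9, 1), (8.0, 9, 1)]

short_ms, long_ms = hl.accumulated_effect(scenario)
print(f"{short_ms:.2f} {long_ms:.2f}")
# -23.32 19.01

print(hl.project_forward(scenario, [0, 10]))
#    added_days  short_effect_ms  long_effect_ms
# 0           0       -23.324065       19.009056
# 1          10        -8.042528       18.644630
```

The accumulated short-header effect today is −23.32 ms (faster responses);
the long-header effect is +19.01 ms (slower). Ten header-free days later
the short effect has shrunk 65.5% to −8.04 ms, while the long effect has
barely moved (1.92% change) — per header, long headers are 2.7 times
larger and far more persistent.

## Full pipeline

The `analysis/` scripts run the complete simulate → preprocess → fit →
project workflow, writing tables to `results/`:

```bash
python analysis/01_simulate_cohort.py   # 36,864 trials, 30 athletes
python analysis/02_preprocess.py        # removes 3.59% incorrect, 4.38% outliers
python analysis/03_fit_model.py         # ~4 minutes; posterior summary table
python analysis/04_project_effects.py   # rest-day projections
```

On the default cohort (seed 1) the fit converges (all R-hat ≤ 1.01) with,
for example, a pro-point intercept posterior of 452.7 ± 6.9 ms against a
generating value of 450.64 ms, and a short-header half-life (pro-point)
of 5.9 ± 1.6 days against a generating value of 5.19 days.

Equivalent CLI: `headerlag run-all --config <config.yaml> --out <dir>`, or
the individual `simulate` / `preprocess` / `fit` / `project` subcommands.

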