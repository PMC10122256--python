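"""Synthetic longitudinal cohorts with the structure the analysis assumes.

The generator emulates a single spring off-season of an observational
heading study: ~30 adolescent athletes (exposed soccer players plus
non-contact controls), 1–4 testing days per week over ~29 days, a pre- and a
post-training test on each testing day with two tasks per test and >=48
trials per block, observer-counted short/long headers on the exposed
athletes' training days, and trial-level response times generated by the
same non-linear hierarchical model the inference stage fits.

A small fraction of trials is flagged incorrect (independent of RT, matching
an analysis that models correct trials only), and a small fraction of the
correct trials receives an additive shift to emulate the attention-lapse
outliers the preprocessing stage is supposed to find.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import predict_mu
from .covariates import build_design
from .types import (
    Athlete,
    Dataset,
    Group,
    HeaderExposure,
    ModelParameters,
    Phase,
    Task,
    TestOccasion,
    Trial,
    ValidationError,
    reported_study_parameters,
)

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "generate_athletes",
    "generate_schedule",
    "generate_exposures",
    "generate_rts",
    "simulate_cohort",
]


@dataclass
class GeneratorConfig:
    """Study-design constants of the emulated cohort.

    Defaults reproduce the published design: 16 exposed / 14 control
    athletes, a 29-day season with 1–4 testing days per week, per-athlete
    session counts with mean 7.8 (SD 2.6) for exposed and 4.2 (SD 2.7) for
    controls, per-session header counts with mean 6.5 and median 5, one long
    header per ~7 headers, 48-trial blocks, 3.6% incorrect trials and 4.2%
    outlier-contaminated correct trials (+600 ms shift).
    """

    n_exposed: int = 16
    n_control: int = 14
    season_days: int = 29
    sessions_per_week: tuple[int, int] = (1, 4)
    mean_sessions_exposed: float = 7.8
    sd_sessions_exposed: float = 2.6
    mean_sessions_control: float = 4.2
    sd_sessions_control: float = 2.7
    header_mean: float = 6.5
    header_dispersion: float = 2.0  # negative-binomial r; r=2 puts the median at 5
    long_header_fraction: float = 1.0 / 7.0
    trials_per_block: int = 48
    p_incorrect: float = 0.036
    p_outlier_contamination: float = 0.042
    outlier_shift_ms: float = 600.0
    age_mean_exposed: float = 15.7
    age_sd_exposed: float = 0.7
    age_mean_control: float = 14.9
    age_sd_control: float = 1.1
    age_range: tuple[float, float] = (13.0, 19.0)
    true_params: ModelParameters = field(default_factory=reported_study_parameters)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed < 0 or self.n_control < 0:
            raise ValidationError("athlete counts must be >= 0")
        if self.season_days < 1:
            raise ValidationError("season_days must be >= 1")
        lo, hi = self.sessions_per_week
        if not (1 <= lo <= hi <= 7):
            raise ValidationError(f"sessions_per_week range {self.sessions_per_week} invalid")
        for p in (self.p_incorrect, self.p_outlier_contamination, self.long_header_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.trials_per_block < 1:
            raise ValidationError("trials_per_block must be >= 1")
        if self.header_mean < 0 or self.header_dispersion <= 0:
            raise ValidationError("header_mean must be >= 0 and dispersion > 0")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedCohort:
    """A generated dataset plus the ground truth the generator used."""

    dataset: Dataset
    config: GeneratorConfig
    subject_intercepts: np.ndarray  # aligned with dataset.athletes
    outlier_flags: dict[tuple, np.ndarray]  # occasion key -> bool per trial
    schedule: dict[str, list[int]]


def generate_athletes(config: GeneratorConfig, rng: np.random.Generator) -> list[Athlete]:
    lo, hi = config.age_range
    out: list[Athlete] = []
    for i in range(config.n_exposed):
        age = float(np.clip(rng.normal(config.age_mean_exposed, config.age_sd_exposed), lo, hi))
        out.append(Athlete(f"S{i + 1:02d}", Group.exposed, age))
    for i in range(config.n_control):
        age = float(np.clip(rng.normal(config.age_mean_control, config.age_sd_control), lo, hi))
        out.append(Athlete(f"C{i + 1:02d}", Group.control, age))
    # Canonical id order, so generated datasets round-trip through the CSV
    # writer/reader unchanged.
    out.sort(key=lambda a: a.athlete_id)
    return out


def generate_schedule(
    config: GeneratorConfig, athletes: list[Athlete], rng: np.random.Generator
) -> dict[str, list[int]]:
    """Ordered testing days per athlete within ``[0, season_days)``.

    Per-athlete session counts are drawn Normal(mean, sd) by group, rounded,
    and clamped to [1, weekly-cap capacity]; days are then placed uniformly
    at random subject to the per-week cap.  The weekly minimum is a design
    description, not a constraint every athlete can satisfy (an athlete with
    a single session cannot test in every week), so only the cap binds.
    """
    n_days = config.season_days
    _, max_pw = config.sessions_per_week
    weeks = [(w, min(7, n_days - 7 * w)) for w in range((n_days + 6) // 7)]
    capacity = sum(min(max_pw, wl) for _, wl in weeks)
    if capacity < 1:
        raise ValidationError("season has no usable testing days")

    schedule: dict[str, list[int]] = {}
    for a in athletes:
        if a.group is Group.exposed:
            mean, sd = config.mean_sessions_exposed, config.sd_sessions_exposed
        else:
            mean, sd = config.mean_sessions_control, config.sd_sessions_control
        n = int(np.clip(round(rng.normal(mean, sd)), 1, capacity))
        week_used = {w: 0 for w, _ in weeks}
        days: list[int] = []
        available = list(range(n_days))
        while len(days) < n:
            open_days = [d for d in available if week_used[d // 7] < max_pw]
            d = int(rng.choice(open_days))
            days.append(d)
            available.remove(d)
            week_used[d // 7] += 1
        schedule[a.athlete_id] = sorted(days)
    return schedule


def generate_exposures(
    config: GeneratorConfig,
    schedule: dict[str, list[int]],
    athletes: list[Athlete],
    rng: np.random.Generator,
) -> list[HeaderExposure]:
    """Header counts for exposed athletes on their training (testing) days.

    Daily totals are negative binomial (right-skewed: mean 6.5 > median 5 at
    dispersion r=2), split short/long by a binomial thinning.  Controls head
    no balls and get no rows.
    """
    out: list[HeaderExposure] = []
    p_nb = config.header_dispersion / (config.header_dispersion + config.header_mean)
    for a in athletes:
        if a.group is not Group.exposed:
            continue
        for day in schedule[a.athlete_id]:
            if config.header_mean == 0:
                total = 0
            else:
                total = int(rng.negative_binomial(config.header_dispersion, p_nb))
            n_long = int(rng.binomial(total, config.long_header_fraction))
            out.append(HeaderExposure(a.athlete_id, day, total - n_long, n_long))
    return out


def generate_rts(
    config: GeneratorConfig,
    schedule: dict[str, list[int]],
    exposures: list[HeaderExposure],
    athletes: list[Athlete],
    rng: np.random.Generator,
) -> tuple[Dataset, np.ndarray, dict[tuple, np.ndarray]]:
    """Trial-level RTs from the generative model, run forward.

    Returns (dataset, subject intercepts, per-occasion outlier flags).
    Incorrect trials draw their RT from the same law (correctness is
    independent of RT and exposure); outlier contamination is an additive
    ``outlier_shift_ms`` on a random subset of correct trials.
    """
    p = config.true_params
    occasions: list[TestOccasion] = []
    for a in athletes:
        for day in schedule[a.athlete_id]:
            for phase in (Phase.pre, Phase.post):
                # Task order matches the canonical occasion sort (anti before
                # pro alphabetically) so the dataset round-trips through CSV.
                for task in (Task.anti_point, Task.pro_point):
                    occasions.append(TestOccasion(a.athlete_id, day, phase, task, []))
    skeleton = Dataset(athletes, occasions, exposures)
    design = build_design(skeleton, base=2.0)
    u = (
        rng.normal(0.0, p.sigma_subject, size=len(athletes))
        if p.sigma_subject > 0
        else np.zeros(len(athletes))
    )
    mu = predict_mu(p, design, u)
    occ_by_key = {o.key(): o for o in occasions}
    outlier_flags: dict[tuple, np.ndarray] = {}
    for j, key in enumerate(design.occasion_keys):
        occ = occ_by_key[key]
        nt = config.trials_per_block
        rts = mu[j] + rng.normal(0.0, p.sigma_resid, size=nt)
        correct = rng.random(nt) >= config.p_incorrect
        outlier = correct & (rng.random(nt) < config.p_outlier_contamination)
        rts = np.where(outlier, rts + config.outlier_shift_ms, rts)
        rts = np.maximum(rts, 1.0)  # RTs are physically positive
        occ.trials = [Trial(float(r), bool(c)) for r, c in zip(rts, correct)]
        outlier_flags[key] = outlier
    dataset = Dataset(athletes, occasions, exposures)
    dataset.validate(require_complete=True, min_trials=config.trials_per_block)
    return dataset, u, outlier_flags


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Run the full generator with independent substreams per stage.

    Separate streams for the roster/schedule, the exposures, and the RT
    noise keep the exposure->RT pathway causal: changing header counts or
    days cannot perturb the trial noise.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    ss = np.random.SeedSequence(config.seed)
    rng_roster, rng_expo, rng_rt = (np.random.default_rng(s) for s in ss.spawn(3))
    athletes = generate_athletes(config, rng_roster)
    schedule = generate_schedule(config, athletes, rng_roster)
    exposures = generate_exposures(config, schedule, athletes, rng_expo)
    dataset, u, flags = generate_rts(config, schedule, exposures, athletes, rng_rt)
    return SimulatedCohort(dataset, config, u, flags, schedule)
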