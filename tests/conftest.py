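"""Shared fixtures: handcrafted datasets, small simulated cohorts, and the
session-scoped full parameter-recovery run used by the recovery tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import headerlag as hl
from headerlag.types import Athlete, Group, HeaderExposure, Phase, Task, TestOccasion, Trial

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_block(athlete_id: str, day: int, phase: Phase, task: Task, rts, correct=None):
    if correct is None:
        correct = [True] * len(rts)
    return TestOccasion(
        athlete_id, day, phase, task, [Trial(float(r), bool(c)) for r, c in zip(rts, correct)]
    )


def manual_dataset(n_trials: int = 48) -> hl.Dataset:
    """Two athletes (one exposed, one control), two testing days, all blocks."""
    rng = np.random.default_rng(99)
    athletes = [
        Athlete("C01", Group.control, 14.5),
        Athlete("S01", Group.exposed, 15.5),
    ]
    occasions = []
    for aid in ("C01", "S01"):
        for day in (0, 3):
            for phase in (Phase.pre, Phase.post):
                for task in (Task.anti_point, Task.pro_point):
                    rts = 500.0 + 40.0 * rng.standard_normal(n_trials)
                    occasions.append(make_block(aid, day, phase, task, rts))
    exposures = [HeaderExposure("S01", 0, 6, 1), HeaderExposure("S01", 3, 4, 2)]
    return hl.Dataset(athletes, occasions, exposures)


@pytest.fixture()
def tiny_config() -> hl.GeneratorConfig:
    return hl.GeneratorConfig(n_exposed=4, n_control=3, season_days=15, seed=7)


@pytest.fixture()
def tiny_cohort(tiny_config) -> hl.SimulatedCohort:
    return hl.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort() -> hl.SimulatedCohort:
    """One full-size cohort at the default (study) generating values."""
    return hl.simulate_cohort(seed=202)


RECOVERY_SEED = 1
RECOVERY_SAMPLER = dict(n_chains=4, n_warmup=1500, n_draws=6000, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_run():
    """The full parameter-recovery run shared by the recovery tests.

    Simulates the default cohort at the study generating values, preprocesses
    it, and fits the joint model by MCMC.  Returns (result, truth, cohort).
    """
    cohort = hl.simulate_cohort(seed=RECOVERY_SEED)
    clean, _ = hl.preprocess(cohort.dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = hl.fit(clean, None, hl.SamplerConfig(**RECOVERY_SAMPLER))
    return result, cohort.config.true_params, cohort
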