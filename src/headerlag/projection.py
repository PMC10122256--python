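"""Scenario calculator: accumulated header effects now and after a rest.

Given point estimates of the header coefficients and half-lives for one
task, and a history of (lag, short count, long count) header events, the
accumulated effect on RT is::

    short_effect = beta_short * sum(n_short * 2**(-lag/hl_short))
    long_effect  = beta_long  * sum(n_long  * 2**(-lag/hl_long))

Projecting forward adds header-free days to every lag, so both magnitudes
shrink — quickly for short headers (half-life under a week), barely at all
for long headers within a month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import accumulate_exposure
from .types import ModelParameters, Task

__all__ = [
    "Scenario",
    "accumulated_effect",
    "project_forward",
    "split_counts",
    "example_scenario",
    "magnitude_ratio",
]


@dataclass
class Scenario:
    """A header history plus one task's header parameters."""

    events: list[tuple[float, float, float]]  # (lag_days, n_short, n_long)
    beta_short: float
    beta_long: float
    hl_short: float
    hl_long: float
    extra_gap_days: float = 0.0
    decay_base: float = 2.0

    def __post_init__(self) -> None:
        for lag, ns, nl in self.events:
            if lag < 0:
                raise ValueError(f"event lag must be >= 0, got {lag}")
            if ns < 0 or nl < 0:
                raise ValueError("header counts must be >= 0")
        if self.extra_gap_days < 0:
            raise ValueError("extra_gap_days must be >= 0")


def accumulated_effect(scenario: Scenario) -> tuple[float, float]:
    """(short_effect_ms, long_effect_ms) for the scenario's header history."""
    gap = scenario.extra_gap_days
    short_events = [(lag + gap, ns) for lag, ns, _ in scenario.events]
    long_events = [(lag + gap, nl) for lag, _, nl in scenario.events]
    short = scenario.beta_short * accumulate_exposure(
        short_events, scenario.hl_short, base=scenario.decay_base
    )
    long = scenario.beta_long * accumulate_exposure(
        long_events, scenario.hl_long, base=scenario.decay_base
    )
    return short, long


def project_forward(scenario: Scenario, added_days) -> pd.DataFrame:
    """Effect trajectory over additional header-free days (sorted offsets)."""
    added = list(added_days)
    if any(a < 0 for a in added):
        raise ValueError("added_days must be >= 0")
    if added != sorted(added):
        raise ValueError("added_days must be sorted ascending")
    rows = []
    for a in added:
        shifted = Scenario(
            scenario.events,
            scenario.beta_short,
            scenario.beta_long,
            scenario.hl_short,
            scenario.hl_long,
            extra_gap_days=scenario.extra_gap_days + a,
            decay_base=scenario.decay_base,
        )
        s, l = accumulated_effect(shifted)
        rows.append({"added_days": a, "short_effect_ms": s, "long_effect_ms": l})
    return pd.DataFrame(rows)


def split_counts(total: int, n_bins: int) -> list[int]:
    """Near-even integer split, remainder assigned to the earliest bins.

    ``split_counts(36, 4) == [9, 9, 9, 9]``; ``split_counts(6, 4) == [2, 2, 1, 1]``.
    """
    base, rem = divmod(int(total), n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


DEFAULT_GAPS = (3.0, 5.0, 7.0, 8.0)


def example_scenario(
    params: ModelParameters,
    task: Task = Task.anti_point,
    n_short: int = 36,
    n_long: int = 6,
    gaps: tuple[float, ...] = DEFAULT_GAPS,
) -> Scenario:
    """The worked example: roughly group-average headers (36 short, 6 long)
    spread over the previous four sessions at gaps of about 3, 5, 7 and 8
    days, evaluated at one task's point estimates."""
    shorts = split_counts(n_short, len(gaps))
    longs = split_counts(n_long, len(gaps))
    events = [(g, s, l) for g, s, l in zip(gaps, shorts, longs)]
    return Scenario(
        events=events,
        beta_short=params.per_task("beta_short", task),
        beta_long=params.per_task("beta_long", task),
        hl_short=params.per_task("hl_short", task),
        hl_long=params.per_task("hl_long", task),
    )


def magnitude_ratio(params: ModelParameters, task: Task) -> float:
    """|beta_long| / |beta_short| — how much larger a long header's per-header
    effect is than a short header's."""
    bs = abs(params.per_task("beta_short", task))
    if bs == 0:
        return np.inf
    return abs(params.per_task("beta_long", task)) / bs
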