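"""Decay-weighted exposure covariates and time-related testing covariates.

The longevity of a head impact's effect is modelled with a half-life ``hl``
inside an exponential decay: a header that happened ``lag`` days before a
test block contributes ``2**(-lag / hl)`` of its initial effect.  The
decay-weighted exposure covariate for a block is the sum of those weights
over every preceding header of a given type (short or long), so the
regression is non-linear in the half-life parameters: the covariates must be
rebuilt whenever a half-life changes.

Time-related covariates control for practice (number of previous same-task
blocks), development (days since the athlete's first session), carryover
(a decayed indicator of the previous testing day, with its own half-life)
and age (centred at the sample mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Dataset, Group, Phase, Task, TestOccasion

__all__ = [
    "decay_weight",
    "accumulate_exposure",
    "OccasionCovariates",
    "build_covariates",
    "DesignMatrices",
    "build_design",
]


def decay_weight(lag_days, half_life_days, *, base: float = 2.0):
    """Fraction of an impact's initial effect remaining after ``lag_days``.

    With the default base 2 the parameter is literally a half-life:
    ``decay_weight(h, h) == 0.5`` and ``decay_weight(0, h) == 1``.  A base-e
    variant (``base=np.e``, rate ``1/half_life_days``) is accepted for
    sensitivity analyses.  Scalar or array ``lag_days``.
    """
    lag = np.asarray(lag_days, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag_days must be >= 0")
    hl = float(half_life_days)
    if not hl > 0:
        raise ValueError(f"half_life_days must be > 0, got {half_life_days}")
    if not base > 1.0:
        raise ValueError("decay base must exceed 1")
    out = np.power(base, -lag / hl)
    return float(out) if np.isscalar(lag_days) else out


def accumulate_exposure(
    header_events, half_life_days: float, *, base: float = 2.0
) -> float:
    """Decay-weighted sum ``sum(count * base**(-lag/hl))`` over (lag, count) events."""
    total = 0.0
    for lag, count in header_events:
        if count < 0:
            raise ValueError("header counts must be >= 0")
        total += count * decay_weight(float(lag), half_life_days, base=base)
    return total


@dataclass(frozen=True)
class OccasionCovariates:
    """Covariates of one test block, for a fixed set of half-lives."""

    x_short: float
    x_long: float
    n_prev_sessions: int
    days_since_first: float
    carry_weight: float
    age_centred: float


def _occasion_sort_key(occ: TestOccasion) -> tuple:
    phase_rank = 0 if occ.phase is Phase.pre else 1
    return (occ.athlete_id, occ.day_index, phase_rank, occ.task.value)


def _header_events(
    exposures_by_athlete: dict[str, list], occ: TestOccasion
) -> list[tuple[float, int, int]]:
    """(lag, n_short, n_long) for every exposure the occasion should see.

    Pre-session blocks happen before that day's training, so same-day
    headers are excluded; post-session blocks include them at lag 0.
    """
    out = []
    for e in exposures_by_athlete.get(occ.athlete_id, ()):
        if e.day_index < occ.day_index or (
            e.day_index == occ.day_index and occ.phase is Phase.post
        ):
            out.append((float(occ.day_index - e.day_index), e.n_short, e.n_long))
    return out


def build_covariates(
    dataset: Dataset,
    hl_short: dict[Task, float],
    hl_long: dict[Task, float],
    hl_carry: dict[Task, float],
    age_center: float | None = None,
    *,
    base: float = 2.0,
) -> dict[tuple, OccasionCovariates]:
    """Per-occasion covariates keyed by ``TestOccasion.key()``.

    Reference (per-occasion, per-header) construction; the vectorized path
    used during fitting lives in :class:`DesignMatrices` and is tested for
    equivalence against this one.
    """
    by_id = dataset.athlete_by_id()
    if age_center is None:
        age_center = float(np.mean([a.age_years for a in dataset.athletes]))
    exposures_by_athlete: dict[str, list] = {}
    for e in dataset.exposures:
        exposures_by_athlete.setdefault(e.athlete_id, []).append(e)

    occs = sorted(dataset.occasions, key=_occasion_sort_key)
    test_days: dict[str, list[int]] = {}
    for occ in occs:
        days = test_days.setdefault(occ.athlete_id, [])
        if not days or days[-1] != occ.day_index:
            if occ.day_index not in days:
                days.append(occ.day_index)
    for days in test_days.values():
        days.sort()

    out: dict[tuple, OccasionCovariates] = {}
    n_prev_seen: dict[tuple[str, str], int] = {}
    for occ in occs:
        athlete = by_id[occ.athlete_id]
        events = _header_events(exposures_by_athlete, occ)
        if athlete.group is Group.control:
            x_s = x_l = 0.0
        else:
            x_s = accumulate_exposure(
                [(lag, ns) for lag, ns, _ in events], hl_short[occ.task], base=base
            )
            x_l = accumulate_exposure(
                [(lag, nl) for lag, _, nl in events], hl_long[occ.task], base=base
            )
        days = test_days[occ.athlete_id]
        first_day = days[0]
        prev_days = [d for d in days if d < occ.day_index]
        if prev_days:
            carry = decay_weight(
                float(occ.day_index - prev_days[-1]), hl_carry[occ.task], base=base
            )
        else:
            carry = 0.0
        pk = (occ.athlete_id, occ.task.value)
        n_prev = n_prev_seen.get(pk, 0)
        out[occ.key()] = OccasionCovariates(
            x_short=x_s,
            x_long=x_l,
            n_prev_sessions=n_prev,
            days_since_first=float(occ.day_index - first_day),
            carry_weight=float(carry),
            age_centred=athlete.age_years - age_center,
        )
        n_prev_seen[pk] = n_prev + 1
    return out


class DesignMatrices:
    """Half-life-independent design of a dataset, vectorized over occasions.

    Event lags and counts are stored padded so that the decay-weighted
    exposure covariates can be recomputed for new half-lives with one
    ``exp2`` call — the inner loop of the non-linear fit.  Trial data enter
    only through per-occasion sufficient statistics (count, sum, sum of
    squares of RT over correct trials), which makes the Gaussian likelihood
    cost independent of the number of trials.
    """

    def __init__(self, dataset: Dataset, age_center: float | None = None, *, base: float = 2.0):
        by_id = dataset.athlete_by_id()
        if age_center is None:
            age_center = float(np.mean([a.age_years for a in dataset.athletes]))
        self.age_center = age_center
        self.base = float(base)
        self.athlete_ids = [a.athlete_id for a in dataset.athletes]
        self.n_athletes = len(self.athlete_ids)
        a_index = {aid: i for i, aid in enumerate(self.athlete_ids)}

        exposures_by_athlete: dict[str, list] = {}
        for e in dataset.exposures:
            exposures_by_athlete.setdefault(e.athlete_id, []).append(e)

        occs = sorted(dataset.occasions, key=_occasion_sort_key)
        self.occasion_keys = [o.key() for o in occs]
        n = len(occs)
        self.n_occasions = n
        self.task_idx = np.array(
            [0 if o.task is Task.pro_point else 1 for o in occs], dtype=np.int64
        )
        self.athlete_idx = np.array([a_index[o.athlete_id] for o in occs], dtype=np.int64)

        test_days: dict[str, list[int]] = {}
        for o in occs:
            test_days.setdefault(o.athlete_id, [])
        for o in occs:
            days = test_days[o.athlete_id]
            if o.day_index not in days:
                days.append(o.day_index)
        for days in test_days.values():
            days.sort()

        n_prev_seen: dict[tuple[str, str], int] = {}
        n_prev = np.zeros(n)
        dsf = np.zeros(n)
        carry_lag = np.full(n, np.inf)
        age_c = np.zeros(n)
        events: list[list[tuple[float, int, int]]] = []
        for j, o in enumerate(occs):
            athlete = by_id[o.athlete_id]
            days = test_days[o.athlete_id]
            dsf[j] = o.day_index - days[0]
            prev = [d for d in days if d < o.day_index]
            if prev:
                carry_lag[j] = o.day_index - prev[-1]
            pk = (o.athlete_id, o.task.value)
            n_prev[j] = n_prev_seen.get(pk, 0)
            n_prev_seen[pk] = n_prev_seen.get(pk, 0) + 1
            age_c[j] = athlete.age_years - age_center
            if athlete.group is Group.control:
                events.append([])
            else:
                events.append(_header_events(exposures_by_athlete, o))
        self.n_prev = n_prev
        self.days_since_first = dsf
        self.carry_lag = carry_lag
        self.age_centred = age_c

        m = max((len(ev) for ev in events), default=0)
        m = max(m, 1)
        self.event_lags = np.full((n, m), np.inf)
        self.short_counts = np.zeros((n, m))
        self.long_counts = np.zeros((n, m))
        for j, ev in enumerate(events):
            for k, (lag, ns, nl) in enumerate(ev):
                self.event_lags[j, k] = lag
                self.short_counts[j, k] = ns
                self.long_counts[j, k] = nl

        # per-occasion sufficient statistics over correct trials
        self.n_trials = np.zeros(n)
        self.sum_rt = np.zeros(n)
        self.sumsq_rt = np.zeros(n)
        for j, o in enumerate(occs):
            rts = np.array([t.rt_ms for t in o.trials if t.correct], dtype=float)
            self.n_trials[j] = rts.size
            self.sum_rt[j] = rts.sum()
            self.sumsq_rt[j] = (rts**2).sum()
        self.total_trials = int(self.n_trials.sum())

    def _decay_sum(self, counts: np.ndarray, hl_pro: float, hl_anti: float) -> np.ndarray:
        hl = np.where(self.task_idx == 0, hl_pro, hl_anti)[:, None]
        if self.base == 2.0:
            w = np.exp2(-self.event_lags / hl)
        else:
            w = np.power(self.base, -self.event_lags / hl)
        return (counts * w).sum(axis=1)

    def x_short(self, hl_pro: float, hl_anti: float) -> np.ndarray:
        return self._decay_sum(self.short_counts, hl_pro, hl_anti)

    def x_long(self, hl_pro: float, hl_anti: float) -> np.ndarray:
        return self._decay_sum(self.long_counts, hl_pro, hl_anti)

    def carry_weight(self, hl_pro: float, hl_anti: float) -> np.ndarray:
        hl = np.where(self.task_idx == 0, hl_pro, hl_anti)
        with np.errstate(over="ignore"):
            if self.base == 2.0:
                w = np.exp2(-self.carry_lag / hl)
            else:
                w = np.power(self.base, -self.carry_lag / hl)
        return w


def build_design(dataset: Dataset, age_center: float | None = None, *, base: float = 2.0) -> DesignMatrices:
    return DesignMatrices(dataset, age_center, base=base)
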