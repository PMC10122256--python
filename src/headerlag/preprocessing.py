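"""Trial filtering: drop incorrect trials, then flag outliers per block.

Outlier detection is the variance-based single-outlier chi-squared test: the
most extreme value's statistic ``(x - mean)^2 / s^2`` (sample variance,
``n-1`` denominator) is referred to the upper-``alpha`` quantile of
chi-squared with one degree of freedom.  Applied two-sided on the most
extreme deviation, per test block, and iteratively: a flagged trial is
removed and the test repeated on the remainder.

The default ``alpha`` is 0.005.  The test compares the block maximum against
an unadjusted chi-squared(1) quantile, so ``alpha`` acts per *comparison*,
not per block: at the conventional 0.05 the expected maximum of ~48 clean
Gaussian trials (|z| near 2.2) is declared significant in most blocks and
iterative trimming then cascades, discarding several percent of clean
trials.  At 0.005 (critical |z| near 2.81) a clean 48-trial block is flagged
~0.2 times on average, while a +600 ms lapse still inflates its block's
variance enough to be caught; see docs/methods.md for the calibration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import Dataset, TestOccasion, Trial, ValidationError

__all__ = [
    "Grouping",
    "PreprocessConfig",
    "PreprocessReport",
    "filter_incorrect",
    "chisq_outlier_mask",
    "preprocess",
]


class Grouping(str, enum.Enum):
    per_occasion = "per_occasion"
    per_athlete_task = "per_athlete_task"


@dataclass
class PreprocessConfig:
    alpha: float = 0.005
    grouping: Grouping = Grouping.per_occasion
    iterative: bool = True
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not isinstance(self.grouping, Grouping):
            self.grouping = Grouping(self.grouping)


@dataclass
class PreprocessReport:
    n_trials_in: int = 0
    n_incorrect_removed: int = 0
    n_outliers_removed: int = 0
    n_trials_out: int = 0
    per_group_outliers: dict = field(default_factory=dict)

    @property
    def frac_incorrect(self) -> float:
        return self.n_incorrect_removed / self.n_trials_in if self.n_trials_in else 0.0

    @property
    def frac_outliers(self) -> float:
        """Outliers as a fraction of correct trials (the denominator reported upstream)."""
        n_correct = self.n_trials_in - self.n_incorrect_removed
        return self.n_outliers_removed / n_correct if n_correct else 0.0

    def to_dict(self) -> dict:
        return {
            "n_trials_in": self.n_trials_in,
            "n_incorrect_removed": self.n_incorrect_removed,
            "frac_incorrect": self.frac_incorrect,
            "n_outliers_removed": self.n_outliers_removed,
            "frac_outliers_of_correct": self.frac_outliers,
            "n_trials_out": self.n_trials_out,
        }


def filter_incorrect(trials: list[Trial]) -> list[Trial]:
    """Keep exactly the correct trials, order preserved."""
    return [t for t in trials if t.correct]


def chisq_outlier_mask(rts, config: PreprocessConfig | None = None) -> np.ndarray:
    """Boolean mask of trials flagged by the iterative chi-squared test.

    Degenerate inputs (fewer than 3 values, or zero variance) flag nothing.
    """
    config = config or PreprocessConfig()
    x = np.asarray(rts, dtype=float)
    mask = np.zeros(x.shape[0], dtype=bool)
    critical = stats.chi2.ppf(1.0 - config.alpha, df=1)
    active = np.arange(x.shape[0])
    n_rounds = config.max_iterations if config.iterative else 1
    for _ in range(n_rounds):
        vals = x[active]
        if vals.size < 3:
            break
        var = vals.var(ddof=1)
        if var == 0.0:
            break
        dev = np.abs(vals - vals.mean())
        j = int(np.argmax(dev))
        statistic = dev[j] ** 2 / var
        if statistic <= critical:
            break
        mask[active[j]] = True
        active = np.delete(active, j)
    return mask


def _group_key(occ: TestOccasion, grouping: Grouping) -> tuple:
    if grouping is Grouping.per_occasion:
        return occ.key()
    return (occ.athlete_id, occ.task.value)


def preprocess(
    dataset: Dataset, config: PreprocessConfig | None = None
) -> tuple[Dataset, PreprocessReport]:
    """Filter incorrect trials, then mask outliers within each group.

    Returns a new dataset (occasions keep their identity, trials are the
    survivors in original order) and a report of per-stage removals.
    """
    config = config or PreprocessConfig()
    report = PreprocessReport(n_trials_in=dataset.n_trials())

    corrected: dict[tuple, list[Trial]] = {}
    for occ in dataset.occasions:
        kept = filter_incorrect(occ.trials)
        report.n_incorrect_removed += len(occ.trials) - len(kept)
        corrected[occ.key()] = kept

    groups: dict[tuple, list[tuple[tuple, int]]] = {}
    for occ in dataset.occasions:
        gk = _group_key(occ, config.grouping)
        members = groups.setdefault(gk, [])
        for i in range(len(corrected[occ.key()])):
            members.append((occ.key(), i))

    keep: dict[tuple, np.ndarray] = {
        k: np.ones(len(v), dtype=bool) for k, v in corrected.items()
    }
    for gk, members in groups.items():
        rts = [corrected[ok][i].rt_ms for ok, i in members]
        mask = chisq_outlier_mask(rts, config)
        n_flagged = int(mask.sum())
        report.n_outliers_removed += n_flagged
        report.per_group_outliers[gk] = n_flagged
        for flagged, (ok, i) in zip(mask, members):
            if flagged:
                keep[ok][i] = False

    new_occasions = []
    for occ in dataset.occasions:
        kept_trials = [t for t, k in zip(corrected[occ.key()], keep[occ.key()]) if k]
        new_occasions.append(
            TestOccasion(occ.athlete_id, occ.day_index, occ.phase, occ.task, kept_trials)
        )
    out = Dataset(list(dataset.athletes), new_occasions, list(dataset.exposures))
    report.n_trials_out = out.n_trials()
    return out, report
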