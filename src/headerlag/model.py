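"""The non-linear hierarchical response-time model.

For trial ``t`` in occasion ``o`` of athlete ``i`` performing task ``k``::

    rt_t ~ Normal(mu_o, sigma_resid)
    mu_o = beta1[k] + u_i
           + beta_short[k] * x_short(o; hl_short[k])
           + beta_long[k]  * x_long(o; hl_long[k])
           + beta_practice[k] * n_prev_sessions(o)
           + beta_dev * days_since_first(o)
           + beta_carry[k] * carry_weight(o; hl_carry[k])
           + beta_age * age_centred(i)
    u_i ~ Normal(0, sigma_subject)

where ``x_short`` / ``x_long`` are the decay-weighted cumulative header
counts (see :mod:`headerlag.covariates`) — the half-lives inside them are
free parameters, which is what makes the regression non-linear.  The only
hierarchical term is the subject intercept ``u_i``, shared across tasks and
phases.

Half-lives carry a uniform prior on (0.5, 500] days; the 500-day cap keeps
the sampler from wandering off to ever larger values when the season is too
short to show any attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .covariates import DesignMatrices, OccasionCovariates, build_design
from .types import HL_LOWER, HL_UPPER, Dataset, ModelParameters, Task

__all__ = [
    "PARAM_NAMES",
    "HALF_LIFE_PARAMS",
    "SIGMA_PARAMS",
    "PriorSpec",
    "default_priors",
    "ModelConfig",
    "linear_predictor",
    "predict_mu",
    "log_likelihood",
    "log_marginal_likelihood",
    "log_prior",
    "log_posterior",
]

PARAM_NAMES: tuple[str, ...] = (
    "beta1_pro",
    "beta1_anti",
    "beta_short_pro",
    "beta_short_anti",
    "beta_long_pro",
    "beta_long_anti",
    "hl_short_pro",
    "hl_short_anti",
    "hl_long_pro",
    "hl_long_anti",
    "beta_practice_pro",
    "beta_practice_anti",
    "beta_carry_pro",
    "beta_carry_anti",
    "hl_carry_pro",
    "hl_carry_anti",
    "beta_dev",
    "beta_age",
    "sigma_subject",
    "sigma_resid",
)

HALF_LIFE_PARAMS = tuple(n for n in PARAM_NAMES if n.startswith("hl_"))
SIGMA_PARAMS = ("sigma_subject", "sigma_resid")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior: family plus (location, scale) or (lower, upper)."""

    family: str  # "normal", "uniform", "halfnormal", "flat"
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform", "halfnormal", "flat"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "uniform" and not self.b > self.a:
            raise ValueError(f"uniform prior needs b > a, got ({self.a}, {self.b})")
        if self.family in ("normal", "halfnormal") and not self.b > 0:
            raise ValueError("scale must be positive")

    def logpdf(self, x: float) -> float:
        if self.family == "flat":
            return 0.0
        if self.family == "normal":
            z = (x - self.a) / self.b
            return -0.5 * z * z - math.log(self.b) - _LOG_SQRT_2PI
        if self.family == "halfnormal":
            if x < 0:
                return -np.inf
            z = x / self.b
            return math.log(2.0) - 0.5 * z * z - math.log(self.b) - _LOG_SQRT_2PI
        # uniform
        if self.a < x <= self.b:
            return -math.log(self.b - self.a)
        return -np.inf

    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            return (self.a, self.b)
        if self.family == "halfnormal":
            return (0.0, np.inf)
        return (-np.inf, np.inf)

    def mean(self) -> float:
        if self.family == "normal":
            return self.a
        if self.family == "uniform":
            return 0.5 * (self.a + self.b)
        if self.family == "halfnormal":
            return self.b * math.sqrt(2.0 / math.pi)
        raise ValueError("flat prior has no mean")


def default_priors() -> dict[str, PriorSpec]:
    """Weakly informative priors on the printed scales of the model.

    Intercepts Normal(500, 150) ms; header and time coefficients
    Normal(0, 20); developmental drift Normal(0, 5) ms/day; half-lives
    Uniform(0.5, 500] days; scale parameters Half-Normal(100) ms.
    """
    priors: dict[str, PriorSpec] = {}
    for name in PARAM_NAMES:
        if name.startswith("beta1"):
            priors[name] = PriorSpec("normal", 500.0, 150.0)
        elif name.startswith("hl_"):
            priors[name] = PriorSpec("uniform", HL_LOWER, HL_UPPER)
        elif name == "beta_dev":
            priors[name] = PriorSpec("normal", 0.0, 5.0)
        elif name in SIGMA_PARAMS:
            priors[name] = PriorSpec("halfnormal", 0.0, 100.0)
        else:
            priors[name] = PriorSpec("normal", 0.0, 20.0)
    return priors


@dataclass
class ModelConfig:
    """Priors, decay convention, and parameters held fixed during inference."""

    priors: dict[str, PriorSpec] = field(default_factory=default_priors)
    decay_base: float = 2.0
    fixed: dict[str, float] = field(default_factory=dict)
    include_likelihood: bool = True  # off => prior-only sampling

    def __post_init__(self) -> None:
        unknown = set(self.priors) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"priors for unknown parameters: {sorted(unknown)}")
        for name in PARAM_NAMES:
            if name not in self.priors:
                self.priors[name] = default_priors()[name]
        unknown = set(self.fixed) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"fixed values for unknown parameters: {sorted(unknown)}")

    def free_names(self) -> list[str]:
        return [n for n in PARAM_NAMES if n not in self.fixed]


def linear_predictor(
    params: ModelParameters,
    cov: OccasionCovariates,
    task: Task,
    subject_intercept: float = 0.0,
) -> float:
    """Occasion-level mean RT (ms) for one test block."""
    return (
        params.per_task("beta1", task)
        + subject_intercept
        + params.per_task("beta_short", task) * cov.x_short
        + params.per_task("beta_long", task) * cov.x_long
        + params.per_task("beta_practice", task) * cov.n_prev_sessions
        + params.beta_dev * cov.days_since_first
        + params.per_task("beta_carry", task) * cov.carry_weight
        + params.beta_age * cov.age_centred
    )


def predict_mu(
    params: ModelParameters, design: DesignMatrices, u: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized occasion-level means; equals `linear_predictor` per occasion."""
    t = design.task_idx
    pick = lambda pro, anti: np.where(t == 0, pro, anti)  # noqa: E731
    mu = pick(params.beta1_pro, params.beta1_anti).astype(float)
    mu = mu + pick(params.beta_short_pro, params.beta_short_anti) * design.x_short(
        params.hl_short_pro, params.hl_short_anti
    )
    mu = mu + pick(params.beta_long_pro, params.beta_long_anti) * design.x_long(
        params.hl_long_pro, params.hl_long_anti
    )
    mu = mu + pick(params.beta_practice_pro, params.beta_practice_anti) * design.n_prev
    mu = mu + params.beta_dev * design.days_since_first
    mu = mu + pick(params.beta_carry_pro, params.beta_carry_anti) * design.carry_weight(
        params.hl_carry_pro, params.hl_carry_anti
    )
    mu = mu + params.beta_age * design.age_centred
    if u is not None:
        mu = mu + np.asarray(u, dtype=float)[design.athlete_idx]
    return mu


def _as_design(data: Dataset | DesignMatrices, base: float) -> DesignMatrices:
    if isinstance(data, DesignMatrices):
        return data
    return build_design(data, base=base)


def log_likelihood(
    params: ModelParameters,
    data: Dataset | DesignMatrices,
    subject_intercepts: np.ndarray | None = None,
    *,
    decay_base: float = 2.0,
) -> float:
    """Gaussian log-likelihood over correct trials, via sufficient statistics.

    ``sum_t logN(rt_t | mu_o, sigma)`` collapses to per-occasion
    ``(n, sum, sumsq)`` because ``mu_o`` is shared within an occasion.
    """
    if params.sigma_resid <= 0:
        return -np.inf
    design = _as_design(data, decay_base)
    mu = predict_mu(params, design, subject_intercepts)
    sse = float(
        np.sum(design.sumsq_rt - 2.0 * mu * design.sum_rt + design.n_trials * mu * mu)
    )
    n = design.total_trials
    s = params.sigma_resid
    return -n * (_LOG_SQRT_2PI + math.log(s)) - 0.5 * sse / (s * s)


def log_marginal_likelihood(
    params: ModelParameters,
    data: Dataset | DesignMatrices,
    *,
    decay_base: float = 2.0,
) -> float:
    """Likelihood with the subject intercepts integrated out analytically.

    Gaussian trial noise and a Gaussian subject intercept make the per-athlete
    integral closed-form: with ``r_i = sum(y - mu0)`` and ``SSE0_i`` the raw
    per-athlete residual sums against the predictor without ``u``,

        loglik_i = -n_i log(sqrt(2 pi) s_e) - SSE0_i/(2 s_e^2)
                   + r_i^2 / (2 s_e^2 (n_i + s_e^2/s_u^2))
                   - 0.5 log(1 + n_i s_u^2/s_e^2)

    At ``sigma_subject == 0`` this reduces exactly to :func:`log_likelihood`
    with all intercepts zero.  Sampling the population parameters against
    this marginal (and drawing ``u`` from its exact Gaussian conditional
    afterwards) produces draws from the same joint posterior as sampling
    ``u`` explicitly, with none of the intercept/random-effect coupling.
    """
    if params.sigma_resid <= 0:
        return -np.inf
    design = _as_design(data, decay_base)
    mu0 = predict_mu(params, design)
    se2 = params.sigma_resid**2
    su2 = params.sigma_subject**2
    n = design.total_trials
    sse0 = np.bincount(
        design.athlete_idx,
        weights=design.sumsq_rt - 2.0 * mu0 * design.sum_rt + design.n_trials * mu0 * mu0,
        minlength=design.n_athletes,
    )
    base = -n * (_LOG_SQRT_2PI + math.log(params.sigma_resid)) - 0.5 * float(sse0.sum()) / se2
    if su2 == 0.0:
        return base
    r = np.bincount(
        design.athlete_idx,
        weights=design.sum_rt - design.n_trials * mu0,
        minlength=design.n_athletes,
    )
    n_i = np.bincount(design.athlete_idx, weights=design.n_trials, minlength=design.n_athletes)
    gain = 0.5 * float(np.sum(r * r / (se2 * (n_i + se2 / su2))))
    shrink = -0.5 * float(np.sum(np.log1p(n_i * su2 / se2)))
    return base + gain + shrink


def log_prior(params: ModelParameters, priors: dict[str, PriorSpec]) -> float:
    total = 0.0
    for name in PARAM_NAMES:
        lp = priors[name].logpdf(getattr(params, name))
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def log_posterior(
    params: ModelParameters,
    subject_intercepts: np.ndarray | None,
    data: Dataset | DesignMatrices,
    config: ModelConfig | None = None,
) -> float:
    """Log-likelihood + log-priors + subject-intercept hierarchy term.

    Returns ``-inf`` outside the support (e.g. a half-life above the 500-day
    cap).  With no subjects (``subject_intercepts`` None or empty) and flat
    priors this reduces to the log-likelihood.
    """
    config = config or ModelConfig()
    lp = log_prior(params, config.priors)
    if not np.isfinite(lp):
        return -np.inf
    u = None
    if subject_intercepts is not None and len(subject_intercepts) > 0:
        u = np.asarray(subject_intercepts, dtype=float)
        if params.sigma_subject == 0.0:
            if np.any(u != 0.0):
                return -np.inf
        else:
            z = u / params.sigma_subject
            lp += float(
                np.sum(-0.5 * z * z - math.log(params.sigma_subject) - _LOG_SQRT_2PI)
            )
    if config.include_likelihood:
        ll = log_likelihood(params, data, u, decay_base=config.decay_base)
        if not np.isfinite(ll):
            return -np.inf
        lp += ll
    return lp
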