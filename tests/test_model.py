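"""Likelihood, priors, posterior support, and the collapsed marginal."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import headerlag as hl
from headerlag.covariates import build_covariates, build_design
from headerlag.model import (
    ModelConfig,
    PriorSpec,
    default_priors,
    linear_predictor,
    log_likelihood,
    log_marginal_likelihood,
    log_posterior,
    log_prior,
    predict_mu,
)
from headerlag.types import ModelParameters, Task, reported_study_parameters
from tests.conftest import manual_dataset


def _covariates_for(dataset, p):
    return build_covariates(
        dataset,
        {Task.pro_point: p.hl_short_pro, Task.anti_point: p.hl_short_anti},
        {Task.pro_point: p.hl_long_pro, Task.anti_point: p.hl_long_anti},
        {Task.pro_point: p.hl_carry_pro, Task.anti_point: p.hl_carry_anti},
    )


class TestLinearPredictor:
    def test_baseline_occasion_equals_intercept(self):
        p = reported_study_parameters()
        cov = hl.OccasionCovariates(0.0, 0.0, 0, 0.0, 0.0, 0.0)
        assert linear_predictor(p, cov, Task.pro_point) == pytest.approx(450.64)
        assert linear_predictor(p, cov, Task.anti_point) == pytest.approx(540.43)

    def test_all_terms_contribute(self):
        p = reported_study_parameters()
        cov = hl.OccasionCovariates(10.0, 2.0, 3, 7.0, 0.5, 1.0)
        want = (
            540.43
            + (-1.17) * 10.0
            + 3.20 * 2.0
            + (-7.34) * 3
            + (-30.94 / 91.0) * 7.0
            + (-10.0) * 0.5
            + (-10.0) * 1.0
        )
        assert linear_predictor(p, cov, Task.anti_point) == pytest.approx(want)

    def test_subject_intercept_is_additive(self):
        p = reported_study_parameters()
        cov = hl.OccasionCovariates(1.0, 1.0, 1, 1.0, 1.0, 1.0)
        base = linear_predictor(p, cov, Task.pro_point)
        assert linear_predictor(p, cov, Task.pro_point, 25.0) == pytest.approx(base + 25.0)

    def test_predict_mu_matches_scalar_path(self, tiny_cohort):
        p = reported_study_parameters()
        d = tiny_cohort.dataset
        design = build_design(d)
        cov = _covariates_for(d, p)
        occ = {o.key(): o for o in d.occasions}
        mu = predict_mu(p, design)
        for j, key in enumerate(design.occasion_keys):
            want = linear_predictor(p, cov[key], occ[key].task)
            assert mu[j] == pytest.approx(want, rel=1e-12)


class TestLogLikelihood:
    def test_matches_per_trial_normal_logpdf(self):
        d = manual_dataset(n_trials=10)
        p = reported_study_parameters()
        cov = _covariates_for(d, p)
        want = 0.0
        for o in d.occasions:
            mu = linear_predictor(p, cov[o.key()], o.task)
            for t in o.trials:
                if t.correct:
                    want += stats.norm.logpdf(t.rt_ms, mu, p.sigma_resid)
        got = log_likelihood(p, d)
        assert got == pytest.approx(want, rel=1e-10)

    def test_subject_intercepts_shift_means(self):
        d = manual_dataset(n_trials=10)
        p = reported_study_parameters()
        u = np.array([5.0, -5.0])  # aligned with athletes C01, S01
        cov = _covariates_for(d, p)
        by_id = {a.athlete_id: i for i, a in enumerate(d.athletes)}
        want = 0.0
        for o in d.occasions:
            mu = linear_predictor(p, cov[o.key()], o.task, u[by_id[o.athlete_id]])
            for t in o.trials:
                if t.correct:
                    want += stats.norm.logpdf(t.rt_ms, mu, p.sigma_resid)
        assert log_likelihood(p, d, u) == pytest.approx(want, rel=1e-10)

    def test_half_life_changes_likelihood(self, tiny_cohort):
        p = reported_study_parameters()
        base = log_likelihood(p, tiny_cohort.dataset)
        perturbed = log_likelihood(
            p.replace(hl_short_pro=20.0), tiny_cohort.dataset
        )
        assert base != perturbed

    def test_zero_sigma_is_minus_inf(self):
        d = manual_dataset(n_trials=5)
        assert log_likelihood(reported_study_parameters().replace(sigma_resid=0.0), d) == -np.inf


class TestMarginalLikelihood:
    def test_reduces_to_loglik_at_zero_sigma_subject(self):
        d = manual_dataset(n_trials=10)
        p = reported_study_parameters().replace(sigma_subject=0.0)
        assert log_marginal_likelihood(p, d) == pytest.approx(
            log_likelihood(p, d), rel=1e-12
        )

    def test_matches_numerical_integration(self):
        """Per-athlete quadrature over u agrees with the closed form."""
        d = manual_dataset(n_trials=6)
        p = reported_study_parameters()
        design = build_design(d)
        mu0 = predict_mu(p, design)
        want = 0.0
        for i in range(design.n_athletes):
            sel = design.athlete_idx == i

            def integrand(u, sel=sel):
                ll = 0.0
                for j in np.flatnonzero(sel):
                    ll += (
                        -design.n_trials[j]
                        * (math.log(p.sigma_resid) + 0.5 * math.log(2 * math.pi))
                        - 0.5
                        * (
                            design.sumsq_rt[j]
                            - 2 * (mu0[j] + u) * design.sum_rt[j]
                            + design.n_trials[j] * (mu0[j] + u) ** 2
                        )
                        / p.sigma_resid**2
                    )
                # scale inside exp to keep quadrature finite
                return math.exp(ll - shift) * stats.norm.pdf(u, 0.0, p.sigma_subject)

            # shift by the likelihood at u=0 for numerical stability
            shift = 0.0
            shift = math.log(integrand(0.0)) - math.log(
                stats.norm.pdf(0.0, 0.0, p.sigma_subject)
            )
            val, _ = integrate.quad(integrand, -150.0, 150.0, limit=200)
            want += math.log(val) + shift
        assert log_marginal_likelihood(p, d) == pytest.approx(want, rel=1e-7)

    def test_profile_peaks_near_generating_half_life(self):
        """A noiseless cohort's marginal likelihood peaks at the generating
        short half-life when profiled over a grid."""
        p = reported_study_parameters().replace(
            hl_short_pro=6.51, sigma_subject=0.0, sigma_resid=1.0
        )
        cohort = hl.simulate_cohort(
            hl.GeneratorConfig(
                p_incorrect=0.0,
                p_outlier_contamination=0.0,
                true_params=p,
                seed=17,
            )
        )
        design = build_design(cohort.dataset)
        grid = np.arange(2.0, 14.01, 0.5)
        vals = [
            log_likelihood(p.replace(hl_short_pro=g, hl_short_anti=g), design)
            for g in grid
        ]
        assert abs(grid[int(np.argmax(vals))] - 6.51) <= 1.0


class TestPriorsAndPosterior:
    def test_prior_spec_families(self):
        assert PriorSpec("normal", 0.0, 1.0).logpdf(0.0) == pytest.approx(
            stats.norm.logpdf(0.0)
        )
        assert PriorSpec("halfnormal", 0.0, 2.0).logpdf(1.0) == pytest.approx(
            stats.halfnorm.logpdf(1.0, scale=2.0)
        )
        assert PriorSpec("halfnormal", 0.0, 2.0).logpdf(-1.0) == -np.inf
        u = PriorSpec("uniform", 0.5, 500.0)
        assert u.logpdf(100.0) == pytest.approx(-math.log(499.5))
        assert u.logpdf(0.4) == -np.inf
        assert PriorSpec("flat").logpdf(1e9) == 0.0
        with pytest.raises(ValueError):
            PriorSpec("cauchy")

    def test_default_priors_cover_all_parameters(self):
        priors = default_priors()
        assert set(priors) == set(hl.model.PARAM_NAMES)
        assert priors["hl_short_pro"].support() == (0.5, 500.0)

    def test_half_life_above_cap_is_minus_inf(self):
        d = manual_dataset(n_trials=5)
        p = reported_study_parameters().replace(hl_long_pro=600.0)
        assert log_posterior(p, None, d) == -np.inf

    def test_half_life_below_floor_is_minus_inf(self):
        d = manual_dataset(n_trials=5)
        p = reported_study_parameters().replace(hl_short_pro=0.3)
        assert log_posterior(p, None, d) == -np.inf

    def test_flat_priors_no_subjects_reduces_to_loglik(self):
        d = manual_dataset(n_trials=5)
        p = reported_study_parameters().replace(sigma_subject=0.0)
        config = ModelConfig(priors={n: PriorSpec("flat") for n in hl.model.PARAM_NAMES})
        assert log_posterior(p, None, d, config) == pytest.approx(
            log_likelihood(p, d), rel=1e-12
        )

    def test_components_add_up(self):
        d = manual_dataset(n_trials=5)
        p = reported_study_parameters()
        u = np.array([10.0, -4.0])
        config = ModelConfig()
        want = (
            log_prior(p, config.priors)
            + float(np.sum(stats.norm.logpdf(u, 0.0, p.sigma_subject)))
            + log_likelihood(p, d, u)
        )
        assert log_posterior(p, u, d, config) == pytest.approx(want, rel=1e-12)

    def test_athlete_relabelling_invariance(self, tiny_cohort):
        d = tiny_cohort.dataset
        p = reported_study_parameters().replace(sigma_subject=0.0)
        lp = log_posterior(p, None, d)
        renamed = hl.Dataset(
            [
                hl.Athlete("Z" + a.athlete_id, a.group, a.age_years)
                for a in d.athletes
            ],
            [
                hl.TestOccasion("Z" + o.athlete_id, o.day_index, o.phase, o.task, o.trials)
                for o in d.occasions
            ],
            [
                hl.HeaderExposure("Z" + e.athlete_id, e.day_index, e.n_short, e.n_long)
                for e in d.exposures
            ],
        )
        assert log_posterior(p, None, renamed) == pytest.approx(lp, rel=1e-12)

    def test_prior_only_mode_ignores_data(self):
        d = manual_dataset(n_trials=5)
        p = reported_study_parameters()
        config = ModelConfig(include_likelihood=False)
        assert log_posterior(p, None, d, config) == pytest.approx(
            log_prior(p, config.priors)
        )
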