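"""Generator behaviour: schedules, exposures, RT law, reproducibility."""

import numpy as np
import pytest

import headerlag as hl
from headerlag.cohort import (
    GeneratorConfig,
    generate_athletes,
    generate_exposures,
    generate_rts,
    generate_schedule,
)
from headerlag.types import Group, HeaderExposure, ModelParameters, Phase, Task, ValidationError


class TestConfig:
    def test_defaults_match_study_design(self):
        c = GeneratorConfig()
        assert (c.n_exposed, c.n_control) == (16, 14)
        assert c.season_days == 29
        assert c.sessions_per_week == (1, 4)
        assert c.header_mean == 6.5
        assert c.long_header_fraction == pytest.approx(1.0 / 7.0)
        assert c.trials_per_block == 48
        assert (c.p_incorrect, c.p_outlier_contamination) == (0.036, 0.042)
        assert c.true_params == hl.reported_study_parameters()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(season_days=0)
        with pytest.raises(ValidationError):
            GeneratorConfig(sessions_per_week=(0, 4))
        with pytest.raises(ValidationError):
            GeneratorConfig(p_incorrect=1.5)


class TestSchedule:
    def test_weekly_cap_respected(self, default_cohort):
        _, max_pw = default_cohort.config.sessions_per_week
        for days in default_cohort.schedule.values():
            assert days == sorted(days)
            assert len(days) == len(set(days))
            weeks = {}
            for d in days:
                weeks[d // 7] = weeks.get(d // 7, 0) + 1
            assert max(weeks.values()) <= max_pw

    def test_every_athlete_tests_at_least_once(self, default_cohort):
        assert all(len(v) >= 1 for v in default_cohort.schedule.values())

    def test_session_count_means_by_group(self):
        # enough athletes to pin the group means within ~2 SEM
        config = GeneratorConfig(n_exposed=600, n_control=600, seed=11)
        rng = np.random.default_rng(0)
        athletes = generate_athletes(config, rng)
        schedule = generate_schedule(config, athletes, rng)
        by_group = {Group.exposed: [], Group.control: []}
        for a in athletes:
            by_group[a.group].append(len(schedule[a.athlete_id]))
        assert np.mean(by_group[Group.exposed]) == pytest.approx(7.8, abs=0.4)
        assert np.mean(by_group[Group.control]) == pytest.approx(4.2, abs=0.4)

    def test_degenerate_week(self):
        config = GeneratorConfig(season_days=7, sessions_per_week=(1, 1))
        rng = np.random.default_rng(0)
        athletes = generate_athletes(config, rng)
        schedule = generate_schedule(config, athletes, rng)
        assert all(len(v) == 1 for v in schedule.values())


class TestExposures:
    def _many_sessions(self, config, n_days=20000):
        rng = np.random.default_rng(3)
        athletes = generate_athletes(config.replace(n_exposed=1, n_control=0), rng)
        schedule = {athletes[0].athlete_id: list(range(n_days))}
        return generate_exposures(config, schedule, athletes, np.random.default_rng(4))

    def test_count_distribution_mean_and_median(self):
        rows = self._many_sessions(GeneratorConfig())
        totals = np.array([e.n_short + e.n_long for e in rows])
        assert totals.mean() == pytest.approx(6.5, abs=0.15)
        # right-skewed: the published median (5) sits below the mean
        assert np.median(totals) == 5
        longs = np.array([e.n_long for e in rows])
        assert longs.sum() / totals.sum() == pytest.approx(1.0 / 7.0, abs=0.01)

    def test_controls_have_no_rows(self, default_cohort):
        exposed_ids = {
            a.athlete_id
            for a in default_cohort.dataset.athletes
            if a.group is Group.exposed
        }
        assert all(e.athlete_id in exposed_ids for e in default_cohort.dataset.exposures)

    def test_zero_long_fraction(self):
        rows = self._many_sessions(GeneratorConfig(long_header_fraction=0.0), n_days=500)
        assert all(e.n_long == 0 for e in rows)

    def test_zero_header_mean(self):
        rows = self._many_sessions(GeneratorConfig(header_mean=0.0), n_days=500)
        assert all(e.n_short == 0 and e.n_long == 0 for e in rows)


def _degenerate_params(**kw) -> ModelParameters:
    """All effects and noise off except what the test switches on."""
    base = dict(
        beta1_pro=450.64,
        beta1_anti=540.43,
        sigma_subject=0.0,
        sigma_resid=0.0,
        hl_short_pro=5.19,
        hl_short_anti=6.51,
        hl_long_pro=309.07,
        hl_long_anti=358.08,
    )
    base.update(kw)
    return ModelParameters(**base)


class TestGenerateRts:
    def _one_athlete(self, params, exposures):
        config = GeneratorConfig(
            n_exposed=1,
            n_control=0,
            p_incorrect=0.0,
            p_outlier_contamination=0.0,
            true_params=params,
        )
        rng = np.random.default_rng(0)
        athletes = generate_athletes(config, rng)
        aid = athletes[0].athlete_id
        schedule = {aid: [3]}
        exposures = [HeaderExposure(aid, 3, ns, nl) for ns, nl in exposures]
        dataset, _, _ = generate_rts(
            config, schedule, exposures, athletes, np.random.default_rng(1)
        )
        return {o.key(): o for o in dataset.occasions}, aid

    def test_no_noise_no_effects_gives_exact_intercepts(self):
        occ, aid = self._one_athlete(_degenerate_params(), [(0, 0)])
        for (a, d, phase, task), o in occ.items():
            want = 450.64 if task == "pro_point" else 540.43
            assert all(t.rt_ms == pytest.approx(want, abs=1e-9) for t in o.trials)

    def test_single_long_header_shifts_post_block_only(self):
        occ, aid = self._one_athlete(
            _degenerate_params(beta_long_pro=3.2), [(0, 1)]
        )
        pre = occ[(aid, 3, "pre", "pro_point")]
        post = occ[(aid, 3, "post", "pro_point")]
        assert all(t.rt_ms == pytest.approx(450.64, abs=1e-9) for t in pre.trials)
        # lag 0 => full weight: the post block moves by exactly beta_long
        assert all(t.rt_ms == pytest.approx(450.64 + 3.2, abs=1e-9) for t in post.trials)

    def test_incorrect_fraction_near_nominal(self, default_cohort):
        trials = [t for o in default_cohort.dataset.occasions for t in o.trials]
        frac = sum(not t.correct for t in trials) / len(trials)
        assert frac == pytest.approx(0.036, abs=0.005)

    def test_outlier_flags_only_on_correct_trials(self, default_cohort):
        for o in default_cohort.dataset.occasions:
            flags = default_cohort.outlier_flags[o.key()]
            for t, f in zip(o.trials, flags):
                if f:
                    assert t.correct

    def test_outlier_contamination_fraction(self, default_cohort):
        total_correct = n_flagged = 0
        for o in default_cohort.dataset.occasions:
            flags = default_cohort.outlier_flags[o.key()]
            total_correct += sum(t.correct for t in o.trials)
            n_flagged += int(flags.sum())
        assert n_flagged / total_correct == pytest.approx(0.042, abs=0.006)


class TestSimulateCohort:
    def test_reproducible(self):
        a = hl.simulate_cohort(seed=5)
        b = hl.simulate_cohort(seed=5)
        assert a.dataset == b.dataset
        assert np.array_equal(a.subject_intercepts, b.subject_intercepts)

    def test_different_seeds_differ(self):
        assert hl.simulate_cohort(seed=5).dataset != hl.simulate_cohort(seed=6).dataset

    def test_dataset_passes_validation(self, default_cohort):
        default_cohort.dataset.validate(require_complete=True)

    def test_ages_in_range(self, default_cohort):
        for a in default_cohort.dataset.athletes:
            assert 13.0 <= a.age_years <= 19.0

    def test_exposure_stream_independent_of_rt_noise(self):
        """Changing header parameters shifts each block's RTs by a constant.

        Exposure counts and trial noise come from separate substreams, so
        turning long headers off changes the occasion means (through the
        decay covariate) but not the per-trial noise around them.
        """
        a = hl.simulate_cohort(seed=9)
        b = hl.simulate_cohort(
            GeneratorConfig(long_header_fraction=0.0, seed=9)
        )
        occ_b = {o.key(): o for o in b.dataset.occasions}
        n_diff = 0
        for o in a.dataset.occasions:
            rts_a = np.array([t.rt_ms for t in o.trials])
            rts_b = np.array([t.rt_ms for t in occ_b[o.key()].trials])
            # the 1 ms physical floor can clip an extreme noise draw in both
            # cohorts; only unclipped trials carry the constant mu shift
            keep = (rts_a > 1.0) & (rts_b > 1.0)
            delta = rts_a[keep] - rts_b[keep]
            assert np.allclose(delta, delta[0], atol=1e-9)
            if abs(delta[0]) > 1e-9:
                n_diff += 1
        assert n_diff > 0  # the covariate change did reach the means

    def test_round_trip_through_csv(self, tiny_cohort, tmp_path):
        hl.write_dataset(tiny_cohort.dataset, tmp_path)
        back = hl.read_dataset(tmp_path, require_complete=True)
        assert back == tiny_cohort.dataset
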