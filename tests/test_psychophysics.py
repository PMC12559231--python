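"""QUEST staircase, 2IFC sessions, psychometric MLE and outlier rejection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visres import psychophysics as psy
from visres import synthetic as syn

LN2 = math.log(2.0)


def oracle_posterior(grid, prior, trials, beta, gamma, delta):
    """Brute-force grid Bayes: explicit per-point likelihood products,
    written independently of the staircase implementation."""
    post = np.array(prior, dtype=float).copy()
    for level, correct in trials:
        for i in range(len(grid)):
            t_log10 = grid[i]
            excess = beta * (t_log10 - math.log10(level))
            p_correct = gamma + (1 - gamma - delta) * (1 - math.exp(-LN2 * 10.0**excess))
            post[i] *= p_correct if correct else (1 - p_correct)
    return post / post.sum()


class TestWeibull:
    def test_floor_ceiling_midpoint(self):
        assert psy.weibull_2ifc(1e6, 60.0, 10.0, lapse=0.02) == pytest.approx(0.5, abs=1e-9)
        assert psy.weibull_2ifc(1e-3, 60.0, 10.0, lapse=0.02) == pytest.approx(0.98, abs=1e-9)
        # the threshold parameter sits at the midway criterion
        assert psy.weibull_2ifc(60.0, 60.0, 10.0, lapse=0.02) == pytest.approx(
            (0.5 + 0.98) / 2, abs=1e-12
        )

    def test_monotone_decreasing_in_level(self):
        levels = np.linspace(10, 200, 100)
        p = psy.weibull_2ifc(levels, 60.0, 10.0, lapse=0.01)
        assert np.all(np.diff(p) <= 0)  # flat only where saturated
        assert p[0] > p[-1]
        assert np.all(p >= 0.5)


class TestQuestInit:
    def test_posterior_is_pmf(self):
        state = psy.quest_init()
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(state.posterior >= 0)

    def test_prior_mean_on_grid(self):
        # prior narrow enough that grid truncation does not shift the mean
        state = psy.quest_init(psy.QuestConfig(prior_sd=0.15))
        mean, _ = psy.quest_estimate(state)
        assert abs(mean - state.config.prior_mean) <= state.config.grid_step

    def test_wide_prior_is_nearly_uniform(self):
        state = psy.quest_init(psy.QuestConfig(prior_sd=1e6))
        ratio = state.posterior.max() / state.posterior.min()
        assert ratio < 1.01

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            psy.QuestConfig(grid_min=2.0, grid_max=1.0)


class TestQuestUpdate:
    def test_posterior_stays_pmf(self):
        state = psy.quest_init()
        rng = np.random.default_rng(0)
        for _ in range(50):
            state = psy.quest_update(state, float(rng.uniform(20, 150)), bool(rng.random() < 0.7))
            assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(state.posterior >= 0)

    def test_correct_easy_trial_never_lowers_mean(self):
        """Monotone likelihood ratio: success at a very coarse (easy) level
        can only pull the threshold estimate up."""
        state = psy.quest_init()
        before, _ = psy.quest_estimate(state)
        after, _ = psy.quest_estimate(psy.quest_update(state, 5.0, True))
        assert after >= before - 1e-12

    def test_updates_commute_over_trial_order(self):
        trials = [(60.0, True), (90.0, False), (40.0, True), (110.0, False)]
        s1 = psy.quest_init()
        for lv, c in trials:
            s1 = psy.quest_update(s1, lv, c)
        s2 = psy.quest_init()
        for lv, c in reversed(trials):
            s2 = psy.quest_update(s2, lv, c)
        np.testing.assert_allclose(s1.posterior, s2.posterior, atol=1e-13)

    def test_fixed_sequence_matches_bruteforce_oracle(self):
        seq = [(60.0, True), (80.0, True), (100.0, False), (90.0, True), (95.0, False),
               (85.0, True), (92.0, True), (97.0, False), (88.0, True), (91.0, True)]
        state = psy.quest_init()
        for lv, c in seq:
            state = psy.quest_update(state, lv, c)
        cfg = state.config
        prior = psy.quest_init().posterior
        expected = oracle_posterior(state.grid, prior, seq, cfg.beta, cfg.gamma, cfg.delta)
        np.testing.assert_allclose(state.posterior, expected, atol=1e-10)

    @given(
        data=st.lists(
            st.tuples(st.floats(min_value=5.0, max_value=190.0), st.booleans()),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_random_sequences_match_oracle(self, data):
        state = psy.quest_init()
        for lv, c in data:
            state = psy.quest_update(state, lv, c)
        cfg = state.config
        expected = oracle_posterior(
            state.grid, psy.quest_init().posterior, data, cfg.beta, cfg.gamma, cfg.delta
        )
        np.testing.assert_allclose(state.posterior, expected, atol=1e-10)


class TestQuestEstimate:
    def test_point_mass_sd_zero(self):
        state = psy.quest_init()
        post = np.zeros_like(state.posterior)
        post[42] = 1.0
        state = psy.QuestState(grid=state.grid, posterior=post, config=state.config)
        mean, sd = psy.quest_estimate(state)
        assert mean == pytest.approx(state.grid[42])
        assert sd == 0.0

    def test_moments_match_bruteforce(self):
        state = psy.quest_init()
        post = np.abs(np.sin(np.linspace(0, 7, state.grid.size))) + 0.01
        post /= post.sum()
        state = psy.QuestState(grid=state.grid, posterior=post, config=state.config)
        mean, sd = psy.quest_estimate(state)
        mean_o = sum(g * p for g, p in zip(state.grid, post))
        var_o = sum((g - mean_o) ** 2 * p for g, p in zip(state.grid, post))
        assert mean == pytest.approx(mean_o, abs=1e-12)
        assert sd == pytest.approx(math.sqrt(var_o), abs=1e-12)


@pytest.fixture(scope="module")
def observer():
    return syn.sample_population(1, seed=11)[0]


@pytest.fixture(scope="module")
def session(observer):
    return psy.run_2ifc_session(observer, ["Ach", "RG", "YV"], 0.0, seed=99)


class TestSession:
    def test_trial_counts_within_study_range(self, session):
        trials, _ = session
        counts = psy.trials_to_frame(trials).groupby("track_id").size()
        assert counts.between(30, 50).all()

    def test_same_seed_reproduces_trials_exactly(self, observer, session):
        trials, _ = session
        again, _ = psy.run_2ifc_session(observer, ["Ach", "RG", "YV"], 0.0, seed=99)
        assert trials == again

    def test_interleaving_preserves_per_track_order(self, session):
        trials, _ = session
        df = psy.trials_to_frame(trials)
        for _, grp in df.groupby("track_id"):
            assert (grp["trial_index"].to_numpy() == np.arange(1, len(grp) + 1)).all()

    def test_triplet_repeat_structure(self, session):
        trials, _ = session
        df = psy.trials_to_frame(trials)
        for _, grp in df.groupby("track_id"):
            # levels change only at triplet boundaries (except a truncated tail)
            rep = grp["repeat_index"].to_numpy()
            lvl = grp["level_ppd"].to_numpy()
            assert rep[0] == 1
            same_triplet = rep[1:] > 1
            assert np.all(lvl[1:][same_triplet] == lvl[:-1][same_triplet])

    def test_unknown_channel_rejected(self, observer):
        with pytest.raises(KeyError):
            psy.run_2ifc_session(observer, ["Ach"], 5.0, seed=1)

    def test_sharp_observer_estimates_converge(self):
        """A nearly deterministic observer (very steep slope, no lapses) is
        recovered within 0.1 log10 units in at least 95% of 200 sessions."""
        hits = 0
        for seed in range(200):
            obs = syn.SimulatedObserver(
                id="sharp", true_thresholds={("Ach", 0.0): 80.0}, slope=1000.0, lapse=0.0
            )
            _, states = psy.run_2ifc_session(obs, ["Ach"], 0.0, seed=seed)
            mean, _ = psy.quest_estimate(states["Ach"])
            hits += abs(mean - math.log10(80.0)) < 0.1
        assert hits >= 190

    def test_aggregate_repeat_mode_runs(self):
        obs = syn.sample_population(1, seed=5)[0]
        cfg = psy.SessionConfig(aggregate_repeats=True)
        trials, states = psy.run_2ifc_session(obs, ["Ach"], 0.0, seed=3, session_config=cfg)
        assert 30 <= len(trials) <= 50
        # QUEST consumed one (aggregated) response per triplet
        assert states["Ach"].n_trials < len(trials)


class TestPsychometricMLE:
    def _simulate(self, threshold, n, seed, slope=10.0, lapse=0.01, levels=None):
        rng = np.random.default_rng(seed)
        if levels is None:
            levels = threshold * 10 ** rng.uniform(-0.25, 0.25, size=n)
        p = psy.weibull_2ifc(levels, threshold, slope, 0.5, lapse)
        correct = rng.random(n) < p
        return pd.DataFrame(
            {
                "track_id": "t",
                "channel": "Ach",
                "eccentricity_deg": 0.0,
                "trial_index": np.arange(1, n + 1),
                "repeat_index": 1,
                "level_ppd": levels,
                "correct": correct.astype(int),
            }
        )

    def test_parameter_recovery(self):
        # median over a few replicates: a single draw of 500 Bernoulli
        # trials has ~2.5% threshold SE, so any one seed can sit near 5%
        fits = [psy.fit_psychometric_mle(self._simulate(40.0, 500, seed=s)) for s in range(1, 6)]
        thresholds = [f.threshold_ppd for f in fits]
        assert np.median(thresholds) == pytest.approx(40.0, rel=0.05)
        assert not any(f.boundary_flag for f in fits)
        assert all(f.loglik <= 0 for f in fits)

    def test_robust_to_far_chance_trials(self):
        df = self._simulate(40.0, 500, seed=2)
        base = psy.fit_psychometric_mle(df).threshold_ppd
        rng = np.random.default_rng(3)
        extra = self._simulate(40.0, 10, seed=4, levels=np.full(10, 180.0))
        extra["correct"] = (rng.random(10) < 0.5).astype(int)
        spiked = psy.fit_psychometric_mle(pd.concat([df, extra], ignore_index=True))
        assert spiked.threshold_ppd == pytest.approx(base, rel=0.02)

    def test_fitted_curve_never_below_chance(self):
        df = self._simulate(60.0, 200, seed=5)
        fit = psy.fit_psychometric_mle(df)
        levels = np.logspace(0.5, 2.3, 200)
        p = psy.weibull_2ifc(levels, fit.threshold_ppd, fit.slope, 0.5, fit.lapse)
        assert np.all(p >= 0.5)

    def test_all_correct_sets_boundary_flag(self):
        df = self._simulate(40.0, 30, seed=6)
        df["correct"] = 1
        fit = psy.fit_psychometric_mle(df)
        assert fit.boundary_flag

    def test_input_validation(self):
        df = self._simulate(40.0, 5, seed=7)
        with pytest.raises(ValueError, match="10 trials"):
            psy.fit_psychometric_mle(df)
        df = self._simulate(40.0, 20, seed=8, levels=np.full(20, 40.0))
        with pytest.raises(ValueError, match="distinct levels"):
            psy.fit_psychometric_mle(df)

    def test_threshold_at_criterion_consistency(self):
        df = self._simulate(40.0, 300, seed=9)
        fit = psy.fit_psychometric_mle(df)
        for crit in (0.6, 0.75, 0.9):
            level = psy.threshold_at_criterion(fit, crit)
            assert psy.weibull_2ifc(level, fit.threshold_ppd, fit.slope, 0.5, fit.lapse) == (
                pytest.approx(crit, abs=1e-9)
            )


class TestOutliers:
    def test_hand_computed_example(self):
        vals = list(range(1, 10)) + [100]
        flags = psy.detect_outliers_modz(vals)
        # median 5.5, MAD 2.5 -> modified Z of 100 is 0.6745*94.5/2.5 = 25.5
        assert flags.tolist() == [False] * 9 + [True]
        z100 = 0.6745 * (100 - 5.5) / 2.5
        assert z100 == pytest.approx(25.5, abs=0.01)

    def test_constant_data_no_outliers(self):
        assert not psy.detect_outliers_modz([7.0] * 10).any()

    def test_zero_mad_fallback(self):
        # MAD is 0 (majority tied) but the 5 is still an outlier by mean-AD
        flags = psy.detect_outliers_modz([1.0, 1.0, 1.0, 1.0, 5.0])
        assert flags.tolist() == [False, False, False, False, True]

    @given(
        scale=st.floats(min_value=0.01, max_value=1e4),
        shift=st.floats(min_value=-1e4, max_value=1e4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        vals = np.array([3.0, 4.0, 5.0, 4.5, 3.5, 30.0, 4.2, 3.8])
        base = psy.detect_outliers_modz(vals)
        moved = psy.detect_outliers_modz(vals * scale + shift)
        assert (base == moved).all()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            psy.detect_outliers_modz([1.0, 2.0])


def test_trials_csv_roundtrip(tmp_path):
    obs = syn.sample_population(1, seed=2)[0]
    trials, _ = psy.run_2ifc_session(obs, ["Ach"], 0.0, seed=8)
    df = psy.trials_to_frame(trials)
    path = tmp_path / "trials.csv"
    df.to_csv(path, index=False)
    back = psy.trials_from_frame(pd.read_csv(path))
    assert len(back) == len(trials)
    for a, b in zip(back, trials):
        assert a.level_ppd == pytest.approx(b.level_ppd, rel=1e-12)
        assert (a.track_id, a.trial_index, a.repeat_index, a.correct) == (
            b.track_id, b.trial_index, b.repeat_index, b.correct
        )
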