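"""Learner module: prediction, soft-max choice, delta-rule and Autostep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexlearn import learners as ln

finite = st.floats(-10, 10, allow_nan=False)


class TestMakeLearner:
    def test_defaults(self):
        s = ln.make_learner("constant", 2)
        assert np.all(s.w == 0.0) and np.all(s.alpha == 0.04)
        assert s.h is None and s.v is None

    def test_flexible_starts_without_history(self):
        s = ln.make_learner("flexible", 3)
        assert np.all(s.h == 0.0) and np.all(s.v == 0.0)

    @pytest.mark.parametrize("kwargs", [dict(alpha0=0.0), dict(alpha0=-1.0), dict(tau=0.0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ln.make_learner("flexible", 2, **kwargs)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ln.make_learner("kalman", 2)


class TestPredict:
    def test_zero_weights(self):
        s = ln.make_learner("constant", 4)
        assert ln.predict(s, np.ones(4)) == 0.0

    def test_one_hot_reads_single_weight(self):
        s = ln.make_learner("constant", 3)
        s.w[:] = (0.3, -0.7, 2.0)
        assert ln.predict(s, np.array([0.0, 1.0, 0.0])) == pytest.approx(-0.7)

    def test_cs3_template_at_true_weights(self):
        # w = true dimension values, x = CS3 at mean size: 2*1.0 + 1*0 + 1*1.0
        W = np.array([1.0, 0.0, 1.0, -1.0, 2.0, 1.0, -1.0, 2.0, 1.0, -1.0])
        s = ln.make_learner("constant", 10)
        s.w[:] = W
        x = np.zeros(10)
        x[0], x[1], x[2] = 2.0, 1.0, 1.0
        assert ln.predict(s, x) == pytest.approx(3.0)

    def test_length_mismatch(self):
        s = ln.make_learner("constant", 3)
        with pytest.raises(ValueError):
            ln.predict(s, np.ones(4))


class TestChoice:
    def test_equal_values_are_a_coin_flip(self):
        assert ln.choice_probability(1.3, 1.3) == 0.5

    def test_unit_gap_closed_form(self):
        assert ln.choice_probability(2.0, 1.0, omega=5.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-5.0)), rel=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(Q1=finite, Q2=finite)
    def test_symmetry(self, Q1, Q2):
        assert ln.choice_probability(Q1, Q2) + ln.choice_probability(Q2, Q1) == pytest.approx(1.0)

    def test_choose_follows_probability(self, rng):
        picks = [ln.choose(2.0, 1.0, 5.0, rng).chosen_index for _ in range(2000)]
        assert np.mean(np.array(picks) == 1) == pytest.approx(1 / (1 + np.exp(-5)), abs=0.01)


class TestRwUpdate:
    def test_one_step_from_cold_start(self):
        # w=0, alpha=0.04, one-hot feature, R=1: w' = 0.04 * (1 - 0) * 1
        s = ln.make_learner("constant", 2)
        ln.rw_update(s, np.array([1.0, 0.0]), 1.0)
        assert s.w[0] == pytest.approx(0.04)
        assert s.w[1] == 0.0

    def test_zero_prediction_error_is_noop(self):
        s = ln.make_learner("constant", 2)
        s.w[:] = (0.5, 0.25)
        before = s.w.copy()
        ln.rw_update(s, np.array([1.0, 1.0]), 0.75)
        np.testing.assert_array_equal(s.w, before)

    def test_absent_features_untouched(self, rng):
        s = ln.make_learner("constant", 5)
        s.w[:] = rng.normal(size=5)
        frozen = s.w[[1, 3]].copy()
        for _ in range(20):
            x = np.array([rng.uniform(0.5, 3), 0.0, 1.0, 0.0, 1.0])
            ln.rw_update(s, x, rng.normal(1.0, 0.5))
        np.testing.assert_array_equal(s.w[[1, 3]], frozen)

    def test_quantitative_feature_scales_update(self):
        s = ln.make_learner("constant", 1)
        ln.rw_update(s, np.array([2.0]), 1.0)
        assert s.w[0] == pytest.approx(0.04 * 1.0 * 2.0)

    def test_deterministic_reversal_convergence(self):
        # noiseless rewarded presentations drive w1 toward the true value 1
        s = ln.make_learner("constant", 2)
        A, B = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        for _ in range(100):
            ln.rw_update(s, A, 1.0)
            ln.rw_update(s, B, 0.0)
        assert abs(s.w[0] - 1.0) < 0.02

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            ln.rw_update(ln.make_learner("flexible", 2), np.ones(2), 1.0)


class TestAutostepUpdate:
    def test_first_update_matches_delta_rule(self):
        # with h = 0 the log-scale step is exp(0) = 1, so only weights move
        s = ln.make_learner("flexible", 3)
        x = np.array([1.0, 1.0, 0.0])
        ln.autostep_update(s, x, 1.0)
        np.testing.assert_allclose(s.w, [0.04, 0.04, 0.0])
        np.testing.assert_allclose(s.alpha, 0.04)

    def test_zero_error_shrinks_trace(self):
        s = ln.make_learner("flexible", 2)
        s.w[:] = (1.0, 0.0)
        s.h[:] = (0.5, -0.5)
        before = s.w.copy()
        ln.autostep_update(s, np.array([1.0, 1.0]), 1.0)
        np.testing.assert_array_equal(s.w, before)
        assert np.all(np.abs(s.h) < 0.5)

    def test_consistent_errors_grow_the_rate(self):
        # constant-sign prediction errors on one feature: the recent-change
        # trace correlates with the current change, so alpha rises from the
        # second update onward
        s = ln.make_learner("flexible", 2)
        x = np.array([1.0, 0.0])
        alphas = []
        for _ in range(20):
            ln.autostep_update(s, x, ln.predict(s, x) + 1.0)
            alphas.append(s.alpha[0])
        diffs = np.diff(alphas)
        assert np.all(diffs[1:] > 0) or np.isclose(sum(s.alpha * x * x), 1.0)
        assert alphas[-1] > 0.04

    def test_inactive_dimensions_bit_identical(self, rng):
        s = ln.make_learner("flexible", 6)
        s.w[:] = rng.normal(size=6)
        idle = [1, 4]
        snap = (s.w[idle].copy(), s.alpha[idle].copy(), s.h[idle].copy(), s.v[idle].copy())
        for _ in range(50):
            x = np.zeros(6)
            x[[0, 2, 3, 5]] = rng.uniform(0.5, 2.0, 4)
            ln.autostep_update(s, x, rng.normal())
        np.testing.assert_array_equal(s.w[idle], snap[0])
        np.testing.assert_array_equal(s.alpha[idle], snap[1])
        np.testing.assert_array_equal(s.h[idle], snap[2])
        np.testing.assert_array_equal(s.v[idle], snap[3])

    def test_mu_zero_reproduces_constant_learner(self, rng):
        flex = ln.make_learner("flexible", 4, mu=0.0)
        const = ln.make_learner("constant", 4)
        for _ in range(500):
            x = np.zeros(4)
            x[rng.integers(4)] = 1.0
            x[0] = rng.uniform(0.5, 2.0)
            R = rng.normal(1.0, 0.3)
            ln.autostep_update(flex, x, R)
            ln.rw_update(const, x, R)
        np.testing.assert_array_equal(flex.w, const.w)
        np.testing.assert_array_equal(flex.alpha, const.alpha)

    def test_rates_positive_and_normalized_under_stress(self, rng):
        s = ln.make_learner("flexible", 5)
        for _ in range(5000):
            x = (rng.random(5) < 0.6) * rng.uniform(0.2, 3.0, 5)
            if not x.any():
                continue
            ln.autostep_update(s, x, rng.normal(0, 5))
            assert np.all(s.alpha > 0)
            assert float(s.alpha @ (x * x)) <= 1.0 + 1e-12
        assert np.all(np.isfinite(s.w)) and np.all(np.isfinite(s.h))
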