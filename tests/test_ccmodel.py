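"""Cooperation/competition model: prediction, simulation, equilibria, fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from popwaves import ccmodel
from popwaves.ccmodel import (
    CCParams,
    equilibria,
    fit_wave,
    predict_R,
    rx_peak,
    simulate,
)


class TestPredict:
    def test_density_independent_limit(self):
        p = CCParams(0.7, 0.0, 0.0)
        assert np.allclose(predict_R(p, np.linspace(-5, 5, 11)), 0.7)

    def test_value_at_interior_maximum(self):
        p = CCParams(1.0, 0.04, 9.0)
        x_star = 0.5 * np.log(p.w / p.c)
        assert predict_R(p, x_star) == pytest.approx(p.rm - 2 * np.sqrt(p.c * p.w))

    def test_hand_arithmetic(self):
        p = CCParams(0.5, 0.01, 2.0)
        assert predict_R(p, np.log(20.0)) == pytest.approx(0.5 - 0.2 - 0.1)

    @given(
        rm=st.floats(0.1, 2.0),
        c=st.floats(1e-4, 0.5),
        w=st.floats(1e-3, 50.0),
        seed=st.integers(0, 100),
    )
    def test_strictly_concave_in_X(self, rm, c, w, seed):
        rng = np.random.default_rng(seed)
        X = np.sort(rng.uniform(-4, 8, 40))
        R = predict_R(CCParams(rm, c, w), X)
        # second difference on an arbitrary grid via divided differences
        d2 = np.diff(np.diff(R) / np.diff(X)) / (X[2:] - X[:-2])
        assert np.all(d2 < 0)


class TestSimulate:
    def test_fixed_point_is_stationary(self):
        p = CCParams(0.6, 0.01, 5.0)
        eq = equilibria(p)
        traj = simulate(p, eq.x_upper, 50, noise_sd=0.0)
        assert np.allclose(traj.sizes, eq.x_upper, rtol=1e-8)

    def test_ricker_limit_converges_to_rm_over_c(self):
        traj = simulate(CCParams(0.5, 0.005, 0.0), x0=10.0, n_gen=200, noise_sd=0.0)
        assert traj.sizes[-1] == pytest.approx(100.0, abs=1e-6)

    def test_below_allee_threshold_declines_matching_step_oracle(self):
        p = CCParams(0.6, 0.01, 5.0)
        eq = equilibria(p)
        x0 = 0.9 * eq.x_lower
        traj = simulate(p, x0, 30, noise_sd=0.0, floor=1e-30)
        assert np.all(np.diff(traj.sizes) < 0)
        x, oracle = x0, [x0]
        for _ in range(len(traj.sizes) - 1):
            x = x * np.exp(p.rm - p.c * x - p.w / x)
            oracle.append(x)
        assert np.allclose(traj.sizes, oracle, rtol=1e-12)

    def test_log_ratio_equals_predict_R_exactly(self):
        p = CCParams(0.8, 0.02, 3.0)
        traj = simulate(p, 7.0, 25, noise_sd=0.0)
        lhs = np.diff(np.log(traj.sizes))
        rhs = predict_R(p, np.log(traj.sizes[:-1]))
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_underflow_truncates_with_flag(self):
        traj = simulate(CCParams(-2.0, 0.01, 0.0), 1.0, 100, floor=1e-3)
        assert traj.extinct and traj.sizes.size < 101

    def test_seeded_noise_reproducible(self):
        p = CCParams(0.5, 0.01, 2.0)
        a = simulate(p, 20.0, 50, noise_sd=0.1, seed=42)
        b = simulate(p, 20.0, 50, noise_sd=0.1, seed=42)
        assert np.array_equal(a.sizes, b.sizes)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate(CCParams(0.5, 0.01, 1.0), x0=0.0, n_gen=5)


class TestEquilibria:
    def test_double_root_at_discriminant_zero(self):
        eq = equilibria(CCParams(2.0, 1.0, 1.0))
        assert eq.exists
        assert eq.x_lower == pytest.approx(1.0) and eq.x_upper == pytest.approx(1.0)

    def test_ricker_limit_single_equilibrium(self):
        eq = equilibria(CCParams(0.5, 0.005, 0.0))
        assert not eq.exists
        assert eq.x_lower is None
        assert eq.x_upper == pytest.approx(100.0)

    def test_roots_match_bisection_oracle(self):
        p = CCParams(0.6, 0.01, 5.0)
        eq = equilibria(p)
        f = lambda x: p.rm - p.c * x - p.w / x
        lo = brentq(f, 1e-6, np.sqrt(p.w / p.c))
        hi = brentq(f, np.sqrt(p.w / p.c), 1e6)
        assert eq.x_lower == pytest.approx(lo, abs=1e-8)
        assert eq.x_upper == pytest.approx(hi, abs=1e-8)

    def test_growth_rate_vanishes_at_roots(self):
        p = CCParams(0.9, 0.02, 7.0)
        eq = equilibria(p)
        for x in (eq.x_lower, eq.x_upper):
            assert abs(predict_R(p, np.log(x))) < 1e-10

    def test_stability_flags(self):
        eq = equilibria(CCParams(0.6, 0.01, 5.0))
        assert eq.stable_lower is False  # Allee threshold repels
        assert eq.stable_upper is True

    def test_no_equilibrium_when_growth_always_negative(self):
        assert not equilibria(CCParams(0.2, 0.1, 5.0)).exists  # rm² < 4cw


class TestRxPeak:
    def test_symmetric_case_peaks_at_zero(self):
        x_peak, _ = rx_peak(CCParams(1.0, 0.3, 0.3))
        assert x_peak == 0.0

    def test_tangent_case_has_zero_peak_rate(self):
        c, w = 0.02, 8.0
        _, r_peak = rx_peak(CCParams(2 * np.sqrt(c * w), c, w))
        assert r_peak == pytest.approx(0.0, abs=1e-14)

    def test_requires_both_terms(self):
        with pytest.raises(ValueError):
            rx_peak(CCParams(0.5, 0.0, 1.0))

    def test_matches_grid_argmax(self):
        rng = np.random.default_rng(17)
        X = np.arange(-10, 10, 1e-4)
        for _ in range(20):
            p = CCParams(rng.uniform(0.1, 2), rng.uniform(1e-3, 0.5), rng.uniform(0.01, 20))
            x_peak, r_peak = rx_peak(p)
            R = predict_R(p, X)
            i = np.argmax(R)
            assert abs(X[i] - x_peak) < 1e-3
            assert R[i] <= r_peak + 1e-12


class TestFitWave:
    def _xy(self, params, n=12, lo=11.0, hi=48.0, sigma=0.0, rng=None):
        X = np.linspace(np.log(lo), np.log(hi), n)
        R = predict_R(params, X)
        if sigma > 0:
            R = R + rng.normal(0, sigma, n)
        return X, R

    def test_noiseless_recovery_is_exact(self):
        p = CCParams(0.6, 0.01, 5.0)
        fit = fit_wave(self._xy(p), method="nls")
        assert fit.params.rm == pytest.approx(p.rm, abs=1e-8)
        assert fit.params.c == pytest.approx(p.c, abs=1e-8)
        assert fit.params.w == pytest.approx(p.w, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)
        assert fit.shape == "humped"

    def test_linear_and_nls_agree_unconstrained(self):
        rng = np.random.default_rng(31)
        p = CCParams(0.6, 0.01, 5.0)
        for _ in range(25):
            X, R = self._xy(p, sigma=0.05, rng=rng)
            a = fit_wave((X, R), method="linear", constrain_nonneg=False)
            b = fit_wave((X, R), method="nls", constrain_nonneg=False)
            assert a.params.rm == pytest.approx(b.params.rm, abs=1e-6)
            assert a.params.c == pytest.approx(b.params.c, abs=1e-6)
            assert a.params.w == pytest.approx(b.params.w, abs=1e-6)

    def test_full_model_never_fits_worse_than_nested_ricker(self):
        rng = np.random.default_rng(77)
        p = CCParams(0.5, 0.008, 3.0)
        for _ in range(20):
            X, R = self._xy(p, sigma=0.1, rng=rng)
            fit = fit_wave((X, R), constrain_nonneg=False)
            assert fit.rss <= fit.ricker.rss + 1e-10

    def test_pure_ricker_data_pins_w_at_zero(self):
        """Nested-model check: no cooperation in, none out."""
        rng = np.random.default_rng(202)
        truth = CCParams(0.5, 0.005, 0.0)
        w_hats, deltas = [], []
        for _ in range(20):
            X = np.linspace(np.log(20.0), np.log(90.0), 12)
            R = predict_R(truth, X) + rng.normal(0, 0.02, 12)
            fit = fit_wave((X, R), method="nls", constrain_nonneg=True)
            w_hats.append(fit.params.w)
            deltas.append(fit.delta_aic)
        assert np.median(w_hats) == pytest.approx(0.0, abs=1e-10)
        assert np.all(np.array(deltas) <= 2.0)

    def test_estimator_bias_below_5pct(self):
        """n = 30, σ_R = 0.02: mean estimate within 5% of truth (1000 reps)."""
        truth = CCParams(0.6, 0.01, 5.0)
        rng = np.random.default_rng(555)
        X = np.linspace(np.log(10.5), np.log(48.5), 30)
        R0 = predict_R(truth, X)
        est = []
        for _ in range(1000):
            f = fit_wave((X, R0 + rng.normal(0, 0.02, 30)), method="linear")
            est.append([f.params.rm, f.params.c, f.params.w])
        mean = np.mean(est, axis=0)
        truth_vec = np.array([truth.rm, truth.c, truth.w])
        assert np.all(np.abs(mean - truth_vec) / truth_vec < 0.05)

    def test_rank_deficient_inputs_rejected(self):
        X = np.full(6, 1.0)
        with pytest.raises(ValueError, match="distinct"):
            fit_wave((X, np.ones(6)))
        with pytest.raises(ValueError, match=">= 4"):
            fit_wave((np.array([1.0, 2, 3]), np.ones(3)))

    def test_wave_object_accepted(self, gen_factory):
        from popwaves.growth import reproductive_rates, segment_waves

        p = CCParams(0.6, 0.01, 5.0)
        traj = simulate(p, 10.5, 30, noise_sd=0.0)
        g = reproductive_rates(gen_factory(traj.sizes, oldest=30 * traj.sizes.size))
        wave = segment_waves(g)[0]
        fit = fit_wave(wave)
        assert fit.n == wave.n_points
        assert fit.params.rm == pytest.approx(p.rm, rel=1e-4)
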