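"""Reproductive rates, wave segmentation, duration stats, phase portraits."""

import numpy as np
import pytest
from scipy import stats

from popwaves import ccmodel
from popwaves.growth import (
    phase_portrait,
    reproductive_rates,
    segment_waves,
    wave_duration_stats,
)


class TestReproductiveRates:
    def test_constant_bins_give_zero_R(self, gen_factory):
        g = reproductive_rates(gen_factory(np.full(10, 4.0)))
        assert np.allclose(g.R, 0.0)

    def test_geometric_bins_give_constant_log_rate(self, gen_factory):
        lam = 1.37
        vals = 2.0 * lam ** np.arange(12)
        g = reproductive_rates(gen_factory(vals))
        assert np.allclose(g.R, np.log(lam), rtol=1e-12)

    def test_hand_oracle(self, gen_factory):
        g = reproductive_rates(gen_factory([10.0, 20.0, 5.0]))
        assert g.R == pytest.approx([np.log(2.0), np.log(0.25)])

    def test_floored_bins_flagged_and_all_floored_rejected(self, gen_factory):
        g = reproductive_rates(gen_factory([1.0, 0.0, 2.0]), floor=1e-12)
        assert list(g.floored) == [False, True, False]
        with pytest.raises(ValueError, match="floor"):
            reproductive_rates(gen_factory([0.0, 0.0]), floor=1e-12)

    def test_scale_invariance(self, gen_factory):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 10, 20)
        g1 = reproductive_rates(gen_factory(vals))
        g2 = reproductive_rates(gen_factory(vals * 137.0))
        assert np.allclose(g1.R, g2.R, atol=1e-12)
        assert np.allclose(g2.X - g1.X, np.log(137.0))


class TestSegmentWaves:
    def test_strictly_increasing_is_one_wave(self, gen_factory):
        g = reproductive_rates(gen_factory(np.arange(1.0, 11.0)))
        waves = segment_waves(g)
        assert len(waves) == 1
        assert (waves[0].start_index, waves[0].end_index) == (0, 8)
        assert waves[0].duration == 9 * 30

    def test_strictly_decreasing_has_no_waves(self, gen_factory):
        g = reproductive_rates(gen_factory(np.arange(10.0, 1.0, -1.0)))
        assert segment_waves(g) == []

    def test_two_runs_match_scan_oracle(self, gen_factory):
        # growth at R-steps 1..5 and 9..14, declines elsewhere
        vals = np.ones(16)
        for i in range(1, 6):
            vals[i + 1] = vals[i] * 1.5
        vals[7] = vals[6] * 0.5
        vals[8] = vals[7] * 0.8
        vals[9] = vals[8] * 0.9
        for i in range(9, 15):
            vals[i + 1] = vals[i] * 1.3
        g = reproductive_rates(gen_factory(vals))
        runs = [(w.start_index, w.end_index) for w in segment_waves(g)]
        # oracle: linear scan over R
        oracle, i = [], 0
        R = g.R
        while i < R.size:
            if R[i] > 0:
                j = i
                while j + 1 < R.size and R[j + 1] > 0:
                    j += 1
                oracle.append((i, j))
                i = j + 1
            else:
                i += 1
        assert runs == oracle == [(1, 5), (9, 14)]

    def test_short_runs_flagged_unfittable(self, gen_factory):
        vals = [1.0, 2.0, 1.5, 3.0, 4.0, 5.0, 6.0, 7.0]
        waves = segment_waves(reproductive_rates(gen_factory(vals)), min_points=4)
        assert [w.fittable for w in waves] == [False, True]

    def test_waves_partition_all_positive_steps(self, gen_factory):
        rng = np.random.default_rng(21)
        g = reproductive_rates(gen_factory(rng.uniform(0.5, 2.0, 60)))
        waves = segment_waves(g)
        covered = set()
        for w in waves:
            steps = set(range(w.start_index, w.end_index + 1))
            assert not (covered & steps)  # disjoint
            covered |= steps
        assert covered == {i for i, r in enumerate(g.R) if r > 0}

    def test_floored_bin_inside_run_marks_it_unfittable(self, gen_factory):
        vals = [1e-15, 1.0, 2.0, 3.0, 4.0, 5.0]
        waves = segment_waves(reproductive_rates(gen_factory(vals)), min_points=4)
        assert waves and waves[0].contains_floored and not waves[0].fittable


class TestDurationStats:
    def test_single_wave_of_ten_steps(self, gen_factory):
        g = reproductive_rates(gen_factory(np.arange(1.0, 12.0)))
        s = wave_duration_stats(segment_waves(g))
        assert s.mean_years == 300.0 and s.count == 1

    def test_two_wave_mean(self, gen_factory):
        # durations 300 and 450 via widths of positive runs
        vals = np.concatenate(
            [1.5 ** np.arange(11), 1.5 ** 10 * 0.5 ** np.arange(1, 3), 2.0 ** np.arange(16)]
        )
        g = reproductive_rates(gen_factory(vals))
        waves = segment_waves(g)
        assert sorted(w.duration for w in waves) == [300.0, 450.0]
        assert wave_duration_stats(waves).mean_years == 375.0

    def test_seeded_durations_match_direct_average(self, gen_factory):
        rng = np.random.default_rng(99)
        vals = [1.0]
        expected = []
        for _ in range(50):
            up = int(rng.integers(1, 12))
            expected.append(up * 30.0)
            for _ in range(up):
                vals.append(vals[-1] * float(rng.uniform(1.05, 1.5)))
            for _ in range(2):
                vals.append(vals[-1] * float(rng.uniform(0.5, 0.9)))
        g = reproductive_rates(gen_factory(np.array(vals), oldest=30 * len(vals)))
        waves = segment_waves(g)
        s = wave_duration_stats(waves)
        assert s.count == 50
        assert s.mean_years == pytest.approx(np.mean(expected))
        assert s.hist_counts.sum() == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wave_duration_stats([])


class TestPhasePortrait:
    def test_length_and_order(self, gen_factory):
        g = reproductive_rates(gen_factory([1.0, 2.0, 3.0]))
        pts = phase_portrait(g)
        assert pts.shape == (2, 2)
        assert np.allclose(pts[:, 0], g.X[:-1])
        assert np.allclose(pts[:, 1], g.R)

    def test_geometric_series_is_horizontal_line(self, gen_factory):
        g = reproductive_rates(gen_factory(3.0 * 1.2 ** np.arange(10)))
        pts = phase_portrait(g)
        assert np.allclose(pts[:, 1], np.log(1.2))

    def test_does_not_mutate_growth(self, gen_factory):
        g = reproductive_rates(gen_factory([1.0, 2.0, 3.0, 4.0]))
        X0, R0 = g.X.copy(), g.R.copy()
        pts = phase_portrait(g)
        pts[:] = -1
        assert np.array_equal(g.X, X0) and np.array_equal(g.R, R0)

    def test_simulated_hump_peak_near_closed_form(self, gen_factory):
        """Trajectory of the cooperation/competition map peaks near ½·ln(w/c)."""
        params = ccmodel.CCParams(rm=0.6, c=0.01, w=5.0)
        traj = ccmodel.simulate(params, x0=10.5, n_gen=40, noise_sd=0.0)
        gens = gen_factory(traj.sizes, oldest=30 * traj.sizes.size)
        g = reproductive_rates(gens)
        pts = phase_portrait(g)
        x_at_max_r = pts[np.argmax(pts[:, 1]), 0]
        x_peak, _ = ccmodel.rx_peak(params)
        # within one trajectory grid step of the analytic optimum
        steps = np.abs(np.diff(pts[:, 0]))
        assert abs(x_at_max_r - x_peak) <= steps.max() + 1e-9

    def test_cooperation_regime_R_increases_with_X_below_threshold(self, gen_factory):
        params = ccmodel.CCParams(rm=0.6, c=0.01, w=5.0)
        traj = ccmodel.simulate(params, x0=10.5, n_gen=25, noise_sd=0.01, seed=4)
        g = reproductive_rates(gen_factory(traj.sizes, oldest=30 * traj.sizes.size))
        pts = phase_portrait(g)
        x_peak, _ = ccmodel.rx_peak(params)
        below = pts[pts[:, 0] < x_peak]
        rho, _ = stats.spearmanr(below[:, 0], below[:, 1])
        assert rho > 0
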