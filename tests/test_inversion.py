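"""Distance recovery: background fit, regularized inversion, band, limits."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import dimerdeer as dd
from dimerdeer.errors import InvalidInputError

from conftest import quadrature_kernel


class TestFitBackground:
    def test_pure_exponential_recovered_exactly(self, time_axis):
        trace = dd.DipolarTrace(time_axis, np.exp(-0.2 * time_axis.values))
        k, depth = dd.fit_background(trace)
        assert k == pytest.approx(0.2, abs=1e-6)
        assert depth == pytest.approx(0.0, abs=1e-6)

    def test_constant_trace(self, time_axis):
        trace = dd.DipolarTrace(time_axis, np.ones(len(time_axis)))
        k, depth = dd.fit_background(trace)
        assert k == pytest.approx(0.0, abs=1e-4)
        assert depth == pytest.approx(0.0, abs=1e-4)

    def test_modulated_trace_depth_estimate(self, time_axis, gaussian_25):
        trace = dd.simulate_trace(dd.TraceModel(0.18, 0.05, gaussian_25), time_axis, 0.0)
        _, depth = dd.fit_background(trace)
        assert 0.16 <= depth <= 0.20

    def test_short_tail_rejected(self, gaussian_25):
        time = dd.TimeAxis(np.linspace(0.0, 0.05, 6))
        trace = dd.DipolarTrace(time, np.ones(6))
        with pytest.raises(InvalidInputError):
            dd.fit_background(trace, fit_start_fraction=0.9)


class TestInvert:
    def test_noiseless_spike_recovered(self, grid, time_axis):
        dist = dd.DistanceDistribution.spike(grid, 3.0)
        trace = dd.simulate_trace(dd.TraceModel(0.3, 0.0, dist), time_axis, 0.0)
        res = dd.invert(trace, grid, alpha=1e-6)
        near = np.abs(grid.values - 3.0) <= grid.dr + 1e-12
        mass = np.trapezoid(np.where(near, res.distribution.density, 0.0), grid.values)
        assert mass >= 0.99

    def test_single_gaussian_modal_distance(self, grid, snr50_trace):
        res = dd.invert(snr50_trace, grid)
        assert abs(res.modal_distance - 2.5) <= grid.dr

    def test_bimodal_recovery(self, grid, time_axis):
        lobes = (np.exp(-0.5 * ((grid.values - 2.2) / 0.12) ** 2)
                 + np.exp(-0.5 * ((grid.values - 3.2) / 0.12) ** 2))
        dist = dd.DistanceDistribution.from_unnormalized(grid, lobes)
        trace = dd.simulate_trace(dd.TraceModel(0.3, 0.05, dist), time_axis,
                                  noise_sd=0.3 / 100, seed=2)
        res = dd.invert(trace, grid)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(res.distribution.density,
                              height=0.1 * res.distribution.density.max())
        modes = grid.values[peaks]
        assert any(abs(m - 2.2) <= grid.dr for m in modes)
        assert any(abs(m - 3.2) <= grid.dr for m in modes)

    def test_output_always_normalized_and_nonnegative(self, grid, snr50_trace):
        res = dd.invert(snr50_trace, grid)
        dens = res.distribution.density
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid.values) == pytest.approx(1.0, abs=1e-6)

    def test_short_trace_rejected(self, grid):
        time = dd.TimeAxis(np.linspace(0.0, 0.2, 20))
        with pytest.raises(InvalidInputError):
            dd.invert(dd.DipolarTrace(time, np.ones(20)), grid)

    def test_parameter_recovery_sweep(self, grid, time_axis):
        """Modal MAE <= 0.05 nm, depth within 0.03, over 20 seeded truths."""
        rng = np.random.default_rng(0)
        modal_errs, depth_errs = [], []
        for seed in range(20):
            mu = rng.uniform(2.0, 3.5)
            dist = dd.DistanceDistribution.gaussian(grid, mu, 0.1)
            trace = dd.simulate_trace(dd.TraceModel(0.18, 0.05, dist), time_axis,
                                      noise_sd=0.18 / 50, seed=seed)
            res = dd.invert(trace, grid)
            modal_errs.append(abs(res.modal_distance - mu))
            depth_errs.append(abs(res.depth_hat - 0.18))
        assert np.mean(modal_errs) <= 0.05
        assert max(depth_errs) <= 0.03

    def test_agrees_with_parametric_oracle(self, grid, time_axis):
        """Modal distances match an independent Gaussian-model trace fit
        (quadrature kernel + curve_fit) within 0.1 nm on 10 scenarios."""
        rng = np.random.default_rng(7)
        Kq = quadrature_kernel(time_axis.values, grid.values, n_nodes=500)

        def model(t, mu, sigma, depth, k):
            dens = np.exp(-0.5 * ((grid.values - mu) / sigma) ** 2)
            dens /= np.trapezoid(dens, grid.values)
            ff = (1 - depth) + depth * (Kq @ dens) * grid.dr
            return ff * np.exp(-k * t)

        for seed in range(10):
            mu_true = rng.uniform(2.2, 3.4)
            dist = dd.DistanceDistribution.gaussian(grid, mu_true, 0.1)
            trace = dd.simulate_trace(dd.TraceModel(0.18, 0.05, dist), time_axis,
                                      noise_sd=0.18 / 50, seed=100 + seed)
            res = dd.invert(trace, grid)
            popt, _ = curve_fit(model, time_axis.values, trace.signal,
                                p0=[2.8, 0.15, 0.2, 0.04],
                                bounds=([1.5, 0.02, 0.01, 0.0], [5.0, 0.5, 0.6, 1.0]))
            assert abs(res.modal_distance - popt[0]) <= 0.1


class TestSelectAlpha:
    def test_single_candidate_returned(self, grid, snr50_trace):
        assert dd.select_alpha(snr50_trace, grid, [0.123]) == 0.123

    def test_too_few_candidates_rejected(self, grid, snr50_trace):
        with pytest.raises(InvalidInputError):
            dd.select_alpha(snr50_trace, grid, [0.1, 0.2])

    def test_noiseless_spike_needs_little_smoothing(self, grid, time_axis):
        dist = dd.DistanceDistribution.spike(grid, 3.0)
        trace = dd.simulate_trace(dd.TraceModel(0.3, 0.0, dist), time_axis, 0.0)
        assert dd.select_alpha(trace, grid) <= 1e-2

    def test_more_noise_means_more_smoothing(self, grid, time_axis, gaussian_25):
        """Majority vote over 20 seeds: alpha(SNR 5) > alpha(SNR 100)."""
        model = dd.TraceModel(0.18, 0.05, gaussian_25)
        wins = 0
        for seed in range(20):
            quiet = dd.simulate_trace(model, time_axis, 0.18 / 100, seed=seed)
            noisy = dd.simulate_trace(model, time_axis, 0.18 / 5, seed=seed)
            wins += dd.select_alpha(noisy, grid) > dd.select_alpha(quiet, grid)
        assert wins > 10


class TestBootstrapBand:
    def test_noiseless_band_is_tight(self, grid, time_axis, gaussian_25):
        trace = dd.simulate_trace(dd.TraceModel(0.18, 0.05, gaussian_25), time_axis, 0.0)
        lo, hi = dd.bootstrap_band(trace, grid, n_boot=20, seed=0)
        assert np.max(hi - lo) <= 1e-3

    def test_band_contains_estimate_and_is_reproducible(self, grid, snr50_trace):
        lo, hi = dd.bootstrap_band(snr50_trace, grid, n_boot=50, seed=3)
        res = dd.invert(snr50_trace, grid)
        dens = res.distribution.density
        assert np.all(lo <= dens + 1e-12) and np.all(dens <= hi + 1e-12)
        lo2, hi2 = dd.bootstrap_band(snr50_trace, grid, n_boot=50, seed=3)
        assert np.array_equal(lo, lo2) and np.array_equal(hi, hi2)

    def test_band_covers_truth_across_seeds(self, grid, time_axis, gaussian_25):
        """Mean pointwise coverage >= 90% where truth mass > 1e-3, 10 seeds."""
        model = dd.TraceModel(0.18, 0.05, gaussian_25)
        coverages = []
        for seed in range(10):
            trace = dd.simulate_trace(model, time_axis, 0.18 / 50, seed=seed)
            lo, hi = dd.bootstrap_band(trace, grid, n_boot=100, seed=0)
            mask = gaussian_25.density > 1e-3
            inside = (gaussian_25.density[mask] >= lo[mask]) & \
                     (gaussian_25.density[mask] <= hi[mask])
            coverages.append(inside.mean())
        assert np.mean(coverages) >= 0.90

    def test_too_few_replicates_rejected(self, grid, snr50_trace):
        with pytest.raises(InvalidInputError):
            dd.bootstrap_band(snr50_trace, grid, n_boot=5)


class TestReliabilityLimit:
    def test_calibration_points(self):
        assert dd.reliability_limit(1.5) == pytest.approx(4.0, abs=0.01)
        assert dd.reliability_limit(0.8) == pytest.approx(3.24, abs=0.01)

    def test_cube_root_scaling(self):
        assert dd.reliability_limit(8 * 0.7) == pytest.approx(2 * dd.reliability_limit(0.7), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            dd.reliability_limit(0.0)

    def test_long_truth_flagged_unreliable(self, grid):
        """A 4.1 nm truth measured with only 0.8 us of evolution time is
        beyond the trustworthy range and the result says so."""
        time = dd.TimeAxis.regular(0.8, 0.008)
        dist = dd.DistanceDistribution.gaussian(grid, 4.1, 0.15)
        trace = dd.simulate_trace(dd.TraceModel(0.3, 0.05, dist), time, 0.3 / 50, seed=6)
        res = dd.invert(trace, grid)
        assert not res.reliable


class TestModalDistance:
    def test_spike_and_tie_rule(self, grid):
        assert dd.modal_distance(dd.DistanceDistribution.spike(grid, 2.5)) == 2.5
        flat = dd.DistanceDistribution.from_unnormalized(grid, np.ones(len(grid)))
        assert dd.modal_distance(flat) == grid.values[0]

    def test_gaussian_mode_on_grid(self, grid):
        dist = dd.DistanceDistribution.gaussian(grid, 4.1, 0.15)
        assert abs(dd.modal_distance(dist) - 4.1) <= grid.dr
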