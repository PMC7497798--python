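"""Decay model and Levenberg–Marquardt fitting: oracles and invariants."""

import numpy as np
import pytest

import flimglia.decay_fit as decay_fit
from flimglia.decay_fit import (
    FitOptions,
    FitParams,
    fit_cube,
    fit_pixel,
    mean_lifetime,
    model_decay,
    shift_curves,
    spatial_bin,
)
from flimglia import phantom
from flimglia.tcspc_io import DecayCube, RunConfig

import helpers

BW = helpers.BW


class TestModelDecay:
    def test_delta_irf_gives_pure_exponential(self):
        irf = helpers.delta_irf()
        p = FitParams(tau1=1.0, tau2=2.0, a1=5.0, a2=0.0)
        m = model_decay(p, irf, 256, BW)
        t = (np.arange(256) + 0.5) * BW
        np.testing.assert_allclose(m, 5.0 * np.exp(-t / 1.0), atol=1e-12)

    def test_delta_irf_is_identity_kernel(self):
        irf = helpers.delta_irf()
        p = FitParams(tau1=0.4, tau2=2.5, a1=3.0, a2=1.0, offset=0.2)
        m = model_decay(p, irf, 256, BW)
        t = (np.arange(256) + 0.5) * BW
        raw = 3.0 * np.exp(-t / 0.4) + 1.0 * np.exp(-t / 2.5) + 0.2
        np.testing.assert_allclose(m, raw, atol=1e-9)

    def test_total_counts_match_geometric_series(self):
        # closed form: sum_k a exp(-(k+1/2) dt / tau) is a geometric series
        irf = helpers.delta_irf()
        p = FitParams(tau1=0.4, tau2=2.5, a1=3.0, a2=1.5, offset=0.1)
        total = model_decay(p, irf, 256, BW).sum()

        def series(a, tau):
            q = np.exp(-BW / tau)
            return a * np.exp(-0.5 * BW / tau) * (1 - q ** 256) / (1 - q)

        closed = series(3.0, 0.4) + series(1.5, 2.5) + 256 * 0.1
        assert total == pytest.approx(closed, rel=1e-12)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            FitParams(tau1=0.0, tau2=2.0, a1=1.0, a2=1.0)
        with pytest.raises(ValueError):
            FitParams(tau1=0.5, tau2=-1.0, a1=1.0, a2=1.0)


class TestRecursionBases:
    def test_match_fft_convolution(self):
        # dual-route: the O(T) recursion vs an independent FFT convolution
        irf = helpers.gaussian_irf()
        t = (np.arange(256) + 0.5) * BW
        tau = np.array([[0.37, 2.81], [1.2, 4.0]])
        E = np.exp(-t[None, None, :] / tau[..., None])
        fft = decay_fit._convolver(irf.values, 256)(E)
        B, Q = decay_fit._exp_bases(tau, irf.values, t)
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(B[j, :, i], fft[i, j], rtol=1e-12,
                                           atol=1e-15)
        # derivative basis against central finite differences
        eps = 1e-6
        Bp, _ = decay_fit._exp_bases(tau * np.exp(eps), irf.values, t, False)
        Bm, _ = decay_fit._exp_bases(tau * np.exp(-eps), irf.values, t, False)
        fd = (Bp - Bm) / (2 * eps)
        np.testing.assert_allclose(Q, fd, rtol=1e-5, atol=1e-9)


class TestSpatialBin:
    def test_radius_zero_identity(self):
        cube = DecayCube(counts=np.random.default_rng(0).poisson(
            5, (4, 4, 8)).astype(np.int64))
        assert spatial_bin(cube, 0) is cube

    def test_uniform_cube_interior_is_9x(self):
        counts = np.ones((5, 5, 8), dtype=np.int64) * 3
        out = spatial_bin(DecayCube(counts=counts), 1)
        np.testing.assert_array_equal(out.counts[2, 2], 27)
        np.testing.assert_array_equal(out.counts[0, 0], 12)   # corner: 4 px

    def test_matches_exhaustive_neighborhood_sums(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4, (3, 3, 6)).astype(np.int64)
        out = spatial_bin(DecayCube(counts=counts), 1)
        for y in range(3):
            for x in range(3):
                acc = np.zeros(6)
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < 3 and 0 <= xx < 3:
                            acc += counts[yy, xx]
                np.testing.assert_allclose(out.counts[y, x], acc)


class TestFitPixel:
    def test_noiseless_mono_exponential(self):
        # two-component model nests the mono truth
        irf = helpers.delta_irf()
        t = (np.arange(256) + 0.5) * BW
        decay = np.exp(-t / 1.0)
        decay *= 1e4 / decay.sum()
        p = fit_pixel(decay, irf, bin_width=BW)
        assert p.tau_m == pytest.approx(1.0, rel=0.01)
        assert p.chi2 < 1e-4
        assert p.converged

    def test_noiseless_biexponential_recovery(self):
        irf = helpers.gaussian_irf()
        curve = helpers.biexp_curve(irf, 0.4, 2.7, 73.0, 3000.0)
        p = fit_pixel(curve, irf, bin_width=BW)
        assert p.tau1 == pytest.approx(0.4, rel=0.02)
        assert p.tau2 == pytest.approx(2.7, rel=0.02)
        assert p.a1_pct == pytest.approx(73.0, abs=0.5)

    def test_poisson_phantom_decay_median_recovery(self):
        # oracle = generating parameters; median over seeded redraws
        irf = helpers.gaussian_irf()
        curve = helpers.biexp_curve(irf, 0.4, 2.5, 75.0, 5000.0)
        tm_true = mean_lifetime(0.75, 0.4, 0.25, 2.5)
        rng = np.random.default_rng(0)
        tms = [fit_pixel(rng.poisson(curve), irf, bin_width=BW).tau_m
               for _ in range(50)]
        assert np.median(tms) == pytest.approx(tm_true, rel=0.05)

    def test_refit_explains_noiseless_variance(self):
        irf = helpers.gaussian_irf()
        curve = helpers.biexp_curve(irf, 0.5, 2.2, 70.0, 4000.0)
        p = fit_pixel(curve, irf, bin_width=BW)
        remodeled = model_decay(p, irf, 256, BW)
        ss_res = ((curve - remodeled) ** 2).sum()
        ss_tot = ((curve - curve.mean()) ** 2).sum()
        assert 1.0 - ss_res / ss_tot >= 0.99

    def test_scale_invariance(self):
        # common scaling of decay and offset leaves lifetimes unchanged
        irf = helpers.gaussian_irf()
        curve = helpers.biexp_curve(irf, 0.4, 2.5, 75.0, 4000.0) + 2.0
        a = fit_pixel(curve, irf, bin_width=BW)
        b = fit_pixel(curve * 10.0, irf, bin_width=BW)
        assert b.tau1 == pytest.approx(a.tau1, rel=0.005)
        assert b.tau2 == pytest.approx(a.tau2, rel=0.005)
        assert b.offset == pytest.approx(10.0 * a.offset, rel=0.05)

    def test_recovery_error_decreases_with_photons(self):
        irf = helpers.gaussian_irf()
        tm_true = mean_lifetime(0.75, 0.4, 0.25, 2.5)
        rng = np.random.default_rng(5)
        med_err = []
        for photons in (500, 2000, 8000):
            curve = helpers.biexp_curve(irf, 0.4, 2.5, 75.0, photons)
            errs = [abs(fit_pixel(rng.poisson(curve), irf, bin_width=BW).tau_m
                        - tm_true)
                    for _ in range(30)]
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]

    def test_all_zero_decay_rejected(self):
        with pytest.raises(ValueError):
            fit_pixel(np.zeros(256), helpers.delta_irf(), bin_width=BW)

    def test_tau_m_within_component_lifetimes(self):
        irf = helpers.gaussian_irf()
        rng = np.random.default_rng(2)
        for _ in range(10):
            curve = rng.poisson(helpers.biexp_curve(
                irf, rng.uniform(0.3, 0.6), rng.uniform(2.0, 3.0),
                rng.uniform(60, 85), 2000.0))
            p = fit_pixel(curve, irf, bin_width=BW)
            assert p.tau1 <= p.tau2
            assert p.tau1 - 1e-9 <= p.tau_m <= p.tau2 + 1e-9


class TestEngineCrossCheck:
    def test_kernel_matches_numpy_engine(self):
        # the compiled per-pixel kernel against the vectorized numpy path
        assert decay_fit._fit_batch_kernel is not None
        irf = helpers.gaussian_irf()
        rng = np.random.default_rng(7)
        Y = np.stack([
            rng.poisson(helpers.biexp_curve(
                irf, rng.uniform(0.3, 0.6), rng.uniform(2.0, 3.2),
                rng.uniform(60, 85), rng.uniform(800, 6000)))
            for _ in range(40)]).astype(float)
        opt = FitOptions()
        with_kernel = decay_fit._fit_batch(Y, irf.values, BW, opt)
        saved = decay_fit._fit_batch_kernel
        decay_fit._fit_batch_kernel = None
        try:
            numpy_only = decay_fit._fit_batch(Y, irf.values, BW, opt)
        finally:
            decay_fit._fit_batch_kernel = saved
        for key in ("tau1", "tau2", "a1", "a2", "offset"):
            np.testing.assert_allclose(with_kernel[key], numpy_only[key],
                                       rtol=1e-6, atol=1e-9)


class TestFitCube:
    def test_threshold_above_all_counts(self):
        cfg = helpers.tiny_culture_config(shape=(32, 32), photons=100.0,
                                          n_microglia=1, n_other=1)
        fov = phantom.generate_phantom(cfg, seed=1)
        maps = fit_cube(fov.cube, fov.irf,
                        RunConfig(photon_threshold=10 ** 9))
        assert not maps.valid.any()
        assert np.isnan(maps.t1).all()

    def test_threshold_zero_keeps_every_pixel(self):
        cfg = helpers.tiny_culture_config(shape=(32, 32), n_microglia=1,
                                          n_other=1)
        fov = phantom.generate_phantom(cfg, seed=1)
        maps = fit_cube(fov.cube, fov.irf, RunConfig(photon_threshold=0))
        assert maps.valid.all()

    def test_classes_separate_in_configured_direction(self, culture_fovs,
                                                      culture_maps):
        # microglia carry more free NAD(P)H (higher a1%) than other glia
        fov, maps = culture_fovs[0], culture_maps[0]
        mg = (fov.class_map == 1) & maps.valid
        other = (fov.class_map == 2) & maps.valid
        assert np.nanmean(maps.a1pct[mg]) > np.nanmean(maps.a1pct[other]) + 5

    def test_estimated_shift_recovers_simulated_shift(self):
        cfg = helpers.tiny_culture_config(shape=(48, 48), n_microglia=2,
                                          n_other=2, shift_bins=1.4)
        fov = phantom.generate_phantom(cfg, seed=6)
        pooled = fov.cube.counts.reshape(-1, 256).sum(axis=0)
        est = decay_fit.estimate_shift(pooled, fov.irf, BW)
        assert est == pytest.approx(1.4, abs=0.2)


class TestShiftCurves:
    def test_sum_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, 64).astype(float)
        for s in (-1.7, -0.5, 0.31, 2.0):
            assert shift_curves(x, s).sum() == pytest.approx(x.sum(), rel=1e-12)


class TestMeanLifetime:
    def test_equal_amplitudes_average(self):
        assert mean_lifetime(2.0, 0.4, 2.0, 2.4) == pytest.approx(1.4)

    def test_single_component_boundary(self):
        assert mean_lifetime(3.0, 0.7, 0.0, 2.4) == pytest.approx(0.7)

    def test_hand_computed_value(self):
        # (3*0.4 + 1*2.4) / 4 = 0.9
        assert mean_lifetime(3.0, 0.4, 1.0, 2.4) == pytest.approx(0.9)

    def test_zero_total_amplitude_rejected(self):
        with pytest.raises(ValueError):
            mean_lifetime(0.0, 0.4, 0.0, 2.4)
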