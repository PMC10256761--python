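"""Wavelet shrinkage, Fourier projection and penalized-spline smoothers."""

import math

import numpy as np
import pytest

from quatsmooth import (
    SmootherConfig,
    TangentSeries,
    estimate_sigma,
    fourier_smooth,
    smooth,
    soft_threshold_vectors,
    spline_smooth,
    universal_threshold,
    wavelet_smooth,
)


def tangent(values, h=1.0):
    return TangentSeries(np.asarray(values, dtype=float), "log", h)


def noisy_sinusoid(seed, n=128, sd=0.1):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    truth = np.column_stack(
        [np.sin(2 * np.pi * t), 0.5 * np.cos(4 * np.pi * t), 0.3 * np.sin(6 * np.pi * t)]
    )
    return truth, truth + rng.normal(0, sd, (n, 3))


class TestSigmaAndThreshold:
    def test_constant_coefficients_give_zero(self):
        assert estimate_sigma(np.full(10, 3.3)) == 0.0

    def test_three_point_reference_value(self):
        # MAD of (-1, 0, 1) is 1, so sigma-hat = 1 / 0.6745
        assert estimate_sigma(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1 / 0.6745)

    def test_consistency_for_gaussian_noise(self):
        draws = np.random.default_rng(7).normal(0.0, 2.0, 100_000)
        assert estimate_sigma(draws) == pytest.approx(2.0, rel=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.array([]))

    def test_universal_threshold_values(self):
        assert universal_threshold(0.0, 128) == 0.0
        assert universal_threshold(1.0, 128) == pytest.approx(math.sqrt(3 * math.log(128)), abs=1e-12)
        assert universal_threshold(2.0, 77) == pytest.approx(2 * universal_threshold(1.0, 77))


class TestSoftThresholdVectors:
    def test_shrinks_along_direction(self):
        out = soft_threshold_vectors(np.array([[3.0, 4.0, 0.0]]), 2.0)
        np.testing.assert_allclose(out, [[1.8, 2.4, 0.0]], atol=1e-12)

    def test_boundary_and_zero_threshold(self):
        w = np.array([[0.6, 0.8, 0.0]])  # norm exactly 1
        assert np.all(soft_threshold_vectors(w, 1.0) == 0)
        np.testing.assert_array_equal(soft_threshold_vectors(w, 0.0), w)

    def test_norm_rule_exact(self, rng):
        w = rng.normal(0, 1, (200, 3))
        t = 0.7
        out = soft_threshold_vectors(w, t)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1),
            np.maximum(0.0, np.linalg.norm(w, axis=1) - t),
            atol=1e-12,
        )

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation

        w = rng.normal(0, 1, (50, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.5]).as_matrix()
        lhs = soft_threshold_vectors(w @ rot.T, 0.8)
        rhs = soft_threshold_vectors(w, 0.8) @ rot.T
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestWaveletSmooth:
    def test_zero_threshold_is_identity(self, rng):
        t = tangent(rng.normal(0, 1, (64, 3)))
        cfg = SmootherConfig(family="wavelet", wavelet_name="d4", decomposition_level=3, threshold=0.0)
        np.testing.assert_allclose(wavelet_smooth(t, cfg).values, t.values, atol=1e-10)

    def test_constant_series_unchanged(self):
        t = tangent(np.tile([0.3, -0.2, 0.5], (32, 1)))
        cfg = SmootherConfig(family="wavelet", wavelet_name="haar", decomposition_level=4)
        np.testing.assert_allclose(wavelet_smooth(t, cfg).values, t.values, atol=1e-12)

    def test_denoises_smooth_signal(self):
        truth, noisy = noisy_sinusoid(11)
        cfg = SmootherConfig(family="wavelet", wavelet_name="d4", decomposition_level=4)
        out = wavelet_smooth(tangent(noisy), cfg).values
        assert np.mean((out - truth) ** 2) < np.mean((noisy - truth) ** 2)

    def test_detail_energy_never_grows(self, rng):
        import pywt

        t = tangent(rng.normal(0, 0.5, (64, 3)))
        cfg = SmootherConfig(family="wavelet", wavelet_name="la8", decomposition_level=3)
        out = wavelet_smooth(t, cfg)
        for c in range(3):
            cin = pywt.wavedec(t.values[:, c], "sym4", mode="periodization", level=3)
            cout = pywt.wavedec(out.values[:, c], "sym4", mode="periodization", level=3)
            for lev in range(1, 4):
                assert np.linalg.norm(cout[lev]) <= np.linalg.norm(cin[lev]) + 1e-10

    def test_non_dyadic_length_rejected(self, rng):
        cfg = SmootherConfig(family="wavelet")
        with pytest.raises(ValueError, match="power-of-two"):
            wavelet_smooth(tangent(rng.normal(0, 1, (100, 3))), cfg)

    def test_excessive_level_rejected(self, rng):
        cfg = SmootherConfig(family="wavelet", decomposition_level=6)
        with pytest.raises(ValueError, match="level"):
            wavelet_smooth(tangent(rng.normal(0, 1, (32, 3))), cfg)

    def test_best_localized_filters_unsupported(self, rng):
        cfg = SmootherConfig(family="wavelet", wavelet_name="bl14")
        with pytest.raises(NotImplementedError):
            wavelet_smooth(tangent(rng.normal(0, 1, (64, 3))), cfg)


class TestFourierSmooth:
    def test_reproduces_signal_in_span(self):
        t_grid = np.linspace(0, 1, 128)
        vals = np.column_stack(
            [np.sin(2 * np.pi * t_grid), np.cos(2 * np.pi * 3 * t_grid), np.ones(128)]
        )
        out = fourier_smooth(tangent(vals), SmootherConfig(family="fourier", n_basis=20))
        np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_constant_unchanged(self):
        t = tangent(np.tile([1.0, -2.0, 0.5], (50, 1)))
        out = fourier_smooth(t, SmootherConfig(family="fourier", n_basis=21))
        np.testing.assert_allclose(out.values, t.values, atol=1e-10)

    def test_residuals_orthogonal_to_basis(self, rng):
        from quatsmooth.smoothing import _fourier_design

        vals = rng.normal(0, 1, (90, 3))
        cfg = SmootherConfig(family="fourier", n_basis=20)
        out = fourier_smooth(tangent(vals), cfg)
        design = _fourier_design(np.arange(90) / 89, 20)
        np.testing.assert_allclose(design.T @ (vals - out.values), 0.0, atol=1e-8)

    def test_basis_counting_convention(self):
        # n_basis = 40 -> constant + 19 sine/cosine pairs: frequency 19
        # is inside the span, frequency 20 is not
        t_grid = np.linspace(0, 1, 256)
        inside = np.tile(np.sin(2 * np.pi * 19 * t_grid)[:, None], (1, 3))
        outside = np.tile(np.sin(2 * np.pi * 20 * t_grid)[:, None], (1, 3))
        cfg = SmootherConfig(family="fourier", n_basis=40)
        np.testing.assert_allclose(
            fourier_smooth(tangent(inside), cfg).values, inside, atol=1e-8
        )
        assert np.abs(fourier_smooth(tangent(outside), cfg).values - outside).max() > 0.1

    def test_oversized_basis_rejected(self, rng):
        with pytest.raises(ValueError, match="n_basis"):
            fourier_smooth(tangent(rng.normal(0, 1, (30, 3))), SmootherConfig(family="fourier", n_basis=31))


class TestSplineSmooth:
    def test_linear_data_reproduced_by_linear_spline(self):
        t_grid = np.linspace(0, 1, 128)
        vals = np.column_stack([2 * t_grid - 1, 0.5 * t_grid, -t_grid + 0.2])
        out = spline_smooth(tangent(vals), SmootherConfig(family="spline", spline_degree=1))
        np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_cubic_polynomial_reproduced_by_cubic_spline(self):
        t_grid = np.linspace(0, 1, 128)
        p = t_grid**3 - 0.5 * t_grid**2 + 0.1
        vals = np.column_stack([p, 2 * p, -p])
        out = spline_smooth(tangent(vals), SmootherConfig(family="spline", spline_degree=3))
        np.testing.assert_allclose(out.values, vals, atol=1e-6)

    def test_gcv_beats_interpolating_fit(self):
        truth, noisy = noisy_sinusoid(23, sd=0.15)
        cfg_cv = SmootherConfig(family="spline", spline_degree=3)
        cfg_interp = SmootherConfig(family="spline", spline_degree=3, smoothing_parameter=1e-10)
        mse_cv = np.mean((spline_smooth(tangent(noisy), cfg_cv).values - truth) ** 2)
        mse_interp = np.mean((spline_smooth(tangent(noisy), cfg_interp).values - truth) ** 2)
        assert mse_cv < mse_interp

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(family="spline", spline_degree=2)


class TestSharedInvariants:
    @pytest.mark.parametrize(
        "cfg",
        [
            SmootherConfig(family="wavelet", wavelet_name="d4", decomposition_level=3),
            SmootherConfig(family="fourier", n_basis=20),
            SmootherConfig(family="spline", spline_degree=3),
        ],
        ids=["wavelet", "fourier", "spline"],
    )
    def test_shift_equivariance(self, cfg, rng):
        vals = rng.normal(0, 0.3, (64, 3))
        shift = np.array([1.5, -0.7, 0.4])
        base = smooth(tangent(vals), cfg).values
        shifted = smooth(tangent(vals + shift), cfg).values
        np.testing.assert_allclose(shifted, base + shift, atol=1e-6, rtol=0)

    def test_none_family_is_identity(self, rng):
        t = tangent(rng.normal(0, 1, (37, 3)))
        assert smooth(t, SmootherConfig(family="none")) is t

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(family="loess")
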