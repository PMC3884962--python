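"""Unit tests for the model building blocks: bias, estimators, residual,
shrinkage, Gauss-Seidel sweep, Bregman update, energy, thresholding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dcac import (
    DegeneratePartitionError,
    DepthBiasModel,
    bias_at,
    bregman_update,
    energy,
    estimate_intensities,
    forward_gradient,
    gauss_seidel_sweep,
    residual_field,
    shrink,
    threshold_partition,
    total_variation,
)

from _reference import scalar_gauss_seidel_sweep, tv_oracle

UNBIASED = DepthBiasModel(1.0)


class TestDepthBias:
    @pytest.mark.parametrize(
        "gamma, z, expected",
        [(1.0, 57, 1.0), (0.37, 0, 1.0), (0.5, 3, 0.125)],
    )
    def test_power_law(self, gamma, z, expected):
        assert bias_at(DepthBiasModel(gamma), z) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("gamma", [0.0, -0.1, 1.5])
    def test_invalid_gamma_rejected(self, gamma):
        with pytest.raises(ValueError):
            DepthBiasModel(gamma)

    def test_profile_non_increasing_in_depth(self):
        p = DepthBiasModel(0.93).profile(40)
        assert np.all(np.diff(p) <= 0) and p[0] == 1.0 and np.all(p > 0)


class TestEstimateIntensities:
    def test_symmetric_half_partition_gives_the_constant(self):
        img = np.full((3, 4, 4), 5.0)
        c1, c2 = estimate_intensities(img, np.full(img.shape, 0.5), UNBIASED)
        assert c1 == pytest.approx(5.0, rel=1e-12)
        assert c2 == pytest.approx(5.0, rel=1e-12)

    def test_exact_decay_model_telescopes(self):
        bias = DepthBiasModel(0.9)
        img = 10.0 * bias.profile(6)[:, None, None] * np.ones((6, 3, 3))
        c1, c2 = estimate_intensities(img, np.full(img.shape, 0.5), bias)
        assert c1 == pytest.approx(10.0, rel=1e-12)

    def test_all_foreground_collapses_background(self):
        bias = DepthBiasModel(0.9)
        img = 10.0 * bias.profile(6)[:, None, None] * np.ones((6, 3, 3))
        with pytest.raises(DegeneratePartitionError, match="background"):
            estimate_intensities(img, np.ones(img.shape), bias)
        with pytest.raises(DegeneratePartitionError, match="foreground"):
            estimate_intensities(img, np.zeros(img.shape), bias)

    def test_two_voxel_column_hand_values(self):
        img = np.array([8.0, 2.0]).reshape(2, 1, 1)
        u = np.array([1.0, 0.0]).reshape(2, 1, 1)
        c1, c2 = estimate_intensities(img, u, UNBIASED)
        assert c1 == pytest.approx(8.0, rel=1e-12)
        assert c2 == pytest.approx(2.0, rel=1e-12)

    def test_reduces_to_region_means_without_bias(self, rng):
        img = rng.uniform(0, 10, (4, 5, 6))
        u = (rng.uniform(size=img.shape) > 0.4).astype(float)
        c1, c2 = estimate_intensities(img, u, UNBIASED)
        assert c1 == pytest.approx(img[u > 0].mean(), rel=1e-12)
        assert c2 == pytest.approx(img[u == 0].mean(), rel=1e-12)

    @pytest.mark.parametrize("scale", [0.25, 3.0, 1000.0])
    def test_intensity_covariance(self, rng, scale):
        # the estimators are linear in the image
        img = rng.uniform(0, 10, (5, 4, 3))
        u = rng.uniform(size=img.shape)
        bias = DepthBiasModel(0.95)
        c1, c2 = estimate_intensities(img, u, bias)
        s1, s2 = estimate_intensities(scale * img, u, bias)
        assert s1 == pytest.approx(scale * c1, rel=1e-12)
        assert s2 == pytest.approx(scale * c2, rel=1e-12)


class TestResidualField:
    def test_perfect_foreground_fit_is_nonpositive(self):
        bias = DepthBiasModel(0.9)
        img = 7.0 * bias.field((4, 2, 2)).copy()
        e_r = residual_field(img, 7.0, 3.0, bias)
        assert np.all(e_r <= 0)

    def test_equidistant_voxel_is_zero(self):
        img = np.full((1, 1, 2), 5.0)
        e_r = residual_field(img, 4.0, 6.0, UNBIASED)
        assert e_r == pytest.approx(np.zeros_like(e_r), abs=1e-12)

    def test_hand_arithmetic(self):
        img = np.full((1, 1, 1), 3.0)
        e_r = residual_field(img, 2.0, 5.0, UNBIASED)
        assert e_r[0, 0, 0] == pytest.approx(-3.0, rel=1e-12)


class TestShrink:
    @pytest.mark.parametrize(
        "v, t, expected",
        [
            ((0.1, 0.0, 0.0), 0.5, (0.0, 0.0, 0.0)),
            ((2.0, 0.0, 0.0), 0.5, (1.5, 0.0, 0.0)),
            ((3.0, 4.0, 0.0), 1.0, (2.4, 3.2, 0.0)),
            ((0.0, 0.0, 0.0), 0.0, (0.0, 0.0, 0.0)),
        ],
    )
    def test_vector_soft_threshold(self, v, t, expected):
        out = shrink(np.asarray(v, dtype=float), t)
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-15)

    @given(
        st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        st.floats(0, 10),
    )
    def test_non_expansive(self, v, t):
        v = np.asarray(v)
        out = shrink(v, t)
        assert np.linalg.norm(out) <= np.linalg.norm(v) + 1e-12

    def test_field_form_matches_per_voxel(self, rng):
        v = rng.normal(size=(3, 2, 3, 4))
        out = shrink(v, 0.7)
        for idx in np.ndindex(2, 3, 4):
            np.testing.assert_allclose(
                out[(slice(None),) + idx],
                shrink(v[(slice(None),) + idx].reshape(3, 1, 1, 1), 0.7).ravel(),
                rtol=1e-12, atol=1e-15,
            )


class TestGaussSeidel:
    def test_constant_u_is_fixed_point(self):
        u = np.full((3, 3, 3), 0.4)
        d = np.zeros((3, 3, 3, 3))
        out = gauss_seidel_sweep(u.copy(), d, d, np.zeros_like(u), 1.0, 1.0)
        np.testing.assert_allclose(out, u, rtol=1e-14)

    def test_clamp_saturates_at_zero(self):
        lam, mu = 2.0, 3.0
        u = np.zeros((3, 3, 3))
        d = np.zeros((3,) + u.shape)
        e_r = np.full(u.shape, 10.0 * mu / lam)
        out = gauss_seidel_sweep(u.copy(), d, d, e_r, lam, mu)
        assert np.all(out == 0.0)

    def test_single_column_sweep_hand_values(self):
        u = np.array([0.0, 1.0, 0.0]).reshape(3, 1, 1)
        zeros = np.zeros((3,) + u.shape)
        out = gauss_seidel_sweep(u.copy(), zeros, zeros, np.zeros_like(u), 1.0, 1.0)
        np.testing.assert_allclose(
            out.ravel(), [1.0 / 6.0, 25.0 / 36.0, 25.0 / 216.0], rtol=1e-14
        )

    def test_matches_scalar_reference(self, rng):
        for shape in [(2, 2, 3), (3, 4, 5), (1, 1, 4)]:
            u = rng.uniform(size=shape)
            d = rng.normal(size=(3,) + shape)
            b = rng.normal(size=(3,) + shape)
            e_r = rng.normal(size=shape)
            expected = scalar_gauss_seidel_sweep(u, d, b, e_r, 1.7, 0.9)
            out = gauss_seidel_sweep(u.copy(), d, b, e_r, 1.7, 0.9)
            np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-14)

    def test_output_always_in_unit_interval(self, rng):
        u = rng.uniform(size=(4, 4, 4))
        d = rng.normal(size=(3, 4, 4, 4)) * 5
        b = rng.normal(size=(3, 4, 4, 4)) * 5
        e_r = rng.normal(size=(4, 4, 4)) * 100
        out = gauss_seidel_sweep(u.copy(), d, b, e_r, 1.0, 1.0, n_sweeps=3)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBregmanUpdate:
    def test_satisfied_constraint_leaves_b_unchanged(self, rng):
        u = rng.uniform(size=(3, 4, 5))
        b = rng.normal(size=(3, 3, 4, 5))
        d = forward_gradient(u)
        np.testing.assert_allclose(bregman_update(b, u, d), b, rtol=1e-12, atol=1e-15)

    def test_accumulates_gradient_from_zero(self, rng):
        u = rng.uniform(size=(3, 4, 5))
        zero = np.zeros((3, 3, 4, 5))
        np.testing.assert_allclose(
            bregman_update(zero, u, zero), forward_gradient(u), rtol=1e-14
        )

    def test_single_link_hand_arithmetic(self):
        u = np.array([0.0, 1.0]).reshape(2, 1, 1)
        d = np.zeros((3, 2, 1, 1))
        b = np.zeros((3, 2, 1, 1))
        d[0, 0, 0, 0] = 0.3
        b[0, 0, 0, 0] = 0.1
        out = bregman_update(b, u, d)
        assert out[0, 0, 0, 0] == pytest.approx(0.8, rel=1e-14)


class TestEnergy:
    def test_perfect_fit_with_full_foreground_is_zero(self):
        bias = DepthBiasModel(0.9)
        img = 4.0 * bias.field((3, 3, 3)).copy()
        e = energy(img, np.ones(img.shape), 4.0, 1.0, lam=7.0, bias=bias)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_unit_step_tv(self):
        u = np.array([0.0, 1.0]).reshape(2, 1, 1)
        assert total_variation(u) == pytest.approx(1.0, rel=1e-14)

    def test_checker_plane_tv_hand_value(self):
        u = np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(1, 2, 2)
        assert total_variation(u) == pytest.approx(2.0 + np.sqrt(2.0), rel=1e-14)

    def test_tv_matches_loop_oracle(self, rng):
        u = rng.uniform(size=(3, 4, 5))
        assert total_variation(u) == pytest.approx(tv_oracle(u), rel=1e-12)

    def test_energy_decomposition(self, rng):
        # energy = TV + lam * fidelity, fidelity computable by hand
        img = rng.uniform(0, 5, (2, 3, 3))
        u = rng.uniform(size=img.shape)
        c1, c2, lam = 4.0, 1.0, 2.5
        fid = ((img - c1) ** 2 * u).sum() + ((img - c2) ** 2 * (1 - u)).sum()
        expected = total_variation(u) + lam * fid
        assert energy(img, u, c1, c2, lam, UNBIASED) == pytest.approx(expected, rel=1e-12)


class TestThresholdPartition:
    def test_strict_inequality_at_threshold(self):
        u = np.full((2, 2, 2), 0.5)
        assert not threshold_partition(u, 0.5).any()

    def test_zero_threshold_keeps_positive_support(self, rng):
        u = rng.uniform(size=(3, 3, 3)) * (rng.uniform(size=(3, 3, 3)) > 0.5)
        np.testing.assert_array_equal(threshold_partition(u, 0.0), u > 0)

    def test_default_half_threshold(self):
        u = np.array([0.2, 0.5, 0.7]).reshape(1, 1, 3)
        np.testing.assert_array_equal(
            threshold_partition(u, 0.5).ravel(), [False, False, True]
        )

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_partition(np.zeros((2, 2, 2)), 1.5)
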