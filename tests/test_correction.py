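import numpy as np
import pytest

from cbctscatter.correction import (CorrectionParams, cap_scatter_fraction,
                                    correct_projection, correct_projection_set,
                                    log_projections, scale_to_experiment,
                                    smooth_scatter, subtract_scatter,
                                    upsample_scatter)
from cbctscatter.geometry import ProjectionImage


class TestSmoothing:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).random((8, 8))
        np.testing.assert_array_equal(smooth_scatter(img, 0.0), img)

    def test_constant_image_preserved(self):
        img = np.full((16, 16), 3.7)
        np.testing.assert_allclose(smooth_scatter(img, 4.0), 3.7)

    def test_impulse_response_sums_to_one(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = smooth_scatter(img, 3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out[16, 16] == out.max()


class TestBlankScaling:
    def test_uniform_ratio(self):
        s = np.full((2, 2), 10.0)
        out = scale_to_experiment(s, np.full((2, 2), 2000.0), np.full((2, 2), 1000.0))
        np.testing.assert_allclose(out, 20.0)

    def test_identity_when_blanks_equal(self):
        s = np.arange(4.0).reshape(2, 2)
        b = np.full((2, 2), 123.0)
        np.testing.assert_allclose(scale_to_experiment(s, b, b), s)

    def test_patterned_blanks_pixelwise(self):
        s = np.array([[10.0, 20.0], [30.0, 40.0]])
        be = np.array([[100.0, 200.0], [300.0, 400.0]])
        bs = np.array([[50.0, 50.0], [150.0, 100.0]])
        expected = np.array([[20.0, 80.0], [60.0, 160.0]])
        np.testing.assert_allclose(scale_to_experiment(s, be, bs), expected)

    def test_zero_blank_pixel_names_location(self):
        s = np.ones((2, 2))
        bs = np.array([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ZeroDivisionError, match=r"i=0, j=1"):
            scale_to_experiment(s, np.ones((2, 2)), bs)


class TestScatterFractionCap:
    def test_cap_active(self):
        out = cap_scatter_fraction(np.array([[100.0]]), np.array([[90.0]]), 0.8)
        assert out[0, 0] == 80.0

    def test_cap_inactive(self):
        out = cap_scatter_fraction(np.array([[100.0]]), np.array([[50.0]]), 0.8)
        assert out[0, 0] == 50.0

    def test_mixed_row_elementwise(self):
        i = np.array([[100.0, 100.0, 100.0]])
        s = np.array([[50.0, 80.0, 120.0]])
        np.testing.assert_allclose(cap_scatter_fraction(i, s, 0.8),
                                   [[50.0, 80.0, 80.0]])

    def test_zero_measured_forces_zero_scatter(self):
        out = cap_scatter_fraction(np.array([[0.0]]), np.array([[40.0]]), 0.8)
        assert out[0, 0] == 0.0


class TestWeightedSubtraction:
    def test_basic_arithmetic(self):
        out = subtract_scatter(np.array([[100.0]]), np.array([[50.0]]), 0.8)
        assert out[0, 0] == pytest.approx(60.0)

    def test_zero_weight_is_identity(self):
        i = np.arange(6.0).reshape(2, 3) + 1.0
        np.testing.assert_array_equal(subtract_scatter(i, np.ones_like(i), 0.0), i)

    def test_unit_weight_is_plain_subtraction(self):
        i = np.array([[100.0, 80.0]])
        s = np.array([[30.0, 20.0]])
        np.testing.assert_allclose(subtract_scatter(i, s, 1.0), [[70.0, 60.0]])

    def test_monotone_in_weight(self):
        rng = np.random.default_rng(1)
        i = 100.0 + 50.0 * rng.random((6, 6))
        s = 60.0 * rng.random((6, 6))
        prev = subtract_scatter(i, s, 0.0)
        for w in (0.2, 0.5, 0.8, 1.0):
            cur = subtract_scatter(i, s, w)
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_positivity_bound_with_cap_before_weight(self):
        rng = np.random.default_rng(2)
        i = 10.0 + 90.0 * rng.random((8, 8))
        s = 200.0 * rng.random((8, 8))  # routinely above the cap
        capped = cap_scatter_fraction(i, s, 0.8)
        out = subtract_scatter(i, capped, 0.8)
        assert np.all(out >= (1.0 - 0.8 * 0.8) * i - 1e-12)

    def test_cap_weight_order_is_pinned(self):
        # weighting before capping would cap at 0.8*I and admit a different
        # result; this case distinguishes the two orders
        i = np.array([[100.0]])
        s = np.array([[150.0]])
        cap_then_weight = subtract_scatter(i, cap_scatter_fraction(i, s, 0.8), 0.8)
        weight_then_cap = i - np.minimum(0.8 * s, 0.8 * i)
        assert cap_then_weight[0, 0] == pytest.approx(36.0)
        assert weight_then_cap[0, 0] == pytest.approx(20.0)
        assert cap_then_weight[0, 0] != weight_then_cap[0, 0]


class TestUpsampling:
    def test_constant_preserved(self):
        out = upsample_scatter(np.full((4, 6), 2.5), (8, 12))
        assert out.shape == (8, 12)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_factor_one_identity(self):
        img = np.random.default_rng(3).random((5, 7))
        np.testing.assert_array_equal(upsample_scatter(img, (5, 7)), img)

    def test_linear_ramp_preserved(self):
        v = np.linspace(1.0, 2.0, 16)
        img = np.tile(v, (12, 1))
        out = upsample_scatter(img, (24, 32))
        # interior of a bicubic upsample reproduces a linear ramp
        interior = out[4:-4, 4:-4]
        u = (np.arange(32) + 0.5) / 2.0 - 0.5
        expected = np.interp(u, np.arange(16), v)[4:-4]
        np.testing.assert_allclose(
            interior, np.broadcast_to(expected, interior.shape), rtol=1e-3)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            upsample_scatter(np.ones((4, 4)), (6, 6))


class TestFullChain:
    def _stack(self, n, shape, value, role="measured"):
        return [ProjectionImage(np.full(shape, value), 10.0 * k, role=role)
                for k in range(n)]

    def test_zero_scatter_is_identity(self):
        measured = self._stack(3, (8, 8), 500.0)
        scatter = self._stack(3, (8, 8), 0.0, role="scatter")
        blank = np.full((8, 8), 1000.0)
        corrected, _ = correct_projection_set(measured, scatter, blank, blank,
                                              CorrectionParams())
        for m, c in zip(measured, corrected):
            np.testing.assert_allclose(c.pixels, m.pixels)

    def test_single_pixel_trace_through_all_steps(self):
        # hand trace: S'=40 (constant, smoothing is a no-op), blank ratio
        # 2000/1000 doubles it to 80, SF cap 0.8*90=72 binds, subtraction
        # gives 90 - 0.8*72 = 32.4
        params = CorrectionParams(w=0.8, sf_max=0.8, smoothing_sigma=2.0,
                                  epsilon_floor=1.0)
        i_exp = np.full((4, 4), 90.0)
        s_sim = np.full((4, 4), 40.0)
        out = correct_projection(i_exp, s_sim, np.full((4, 4), 2000.0),
                                 np.full((4, 4), 1000.0), params)
        np.testing.assert_allclose(out, 32.4, rtol=1e-12)

    def test_log_projection_of_blank_is_zero(self):
        blank = np.full((4, 4), 800.0)
        stack = [ProjectionImage(blank.copy(), 0.0)]
        logs = log_projections(stack, blank)
        np.testing.assert_allclose(logs[0].pixels, 0.0, atol=1e-12)

    def test_angle_mismatch_warns(self):
        measured = [ProjectionImage(np.full((4, 4), 100.0), 5.0)]
        scatter = [ProjectionImage(np.full((4, 4), 1.0), 0.0, role="scatter")]
        blank = np.full((4, 4), 1000.0)
        with pytest.warns(UserWarning, match="deg from measured"):
            correct_projection_set(measured, scatter, blank, blank)

    def test_shape_mismatch_rejected(self):
        measured = [ProjectionImage(np.full((4, 4), 100.0), 0.0)]
        scatter = [ProjectionImage(np.full((4, 4), 1.0), 0.0, role="scatter")]
        with pytest.raises(ValueError):
            correct_projection_set(measured, scatter, np.full((8, 8), 1000.0),
                                   np.full((8, 8), 1000.0))

    def test_low_resolution_scatter_upsampled(self):
        measured = [ProjectionImage(np.full((8, 8), 500.0), 0.0)]
        scatter = [ProjectionImage(np.full((4, 4), 10.0), 0.0, role="scatter")]
        blank = np.full((8, 8), 1000.0)
        corrected, _ = correct_projection_set(measured, scatter, blank, blank,
                                              CorrectionParams(smoothing_sigma=0.0))
        np.testing.assert_allclose(corrected[0].pixels, 500.0 - 0.8 * 10.0)


def test_params_validation():
    with pytest.warns(UserWarning, match="outside"):
        CorrectionParams(w=1.5)
    with pytest.raises(ValueError):
        CorrectionParams(sf_max=1.5)
    with pytest.raises(ValueError):
        CorrectionParams(smoothing_sigma=-1.0)
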