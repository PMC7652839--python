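"""Intensity-transform pipeline: gradient, negative rescale, gamma."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from crackseg import (
    GrayImage,
    enhance,
    gaussian_gradient,
    negative_rescale,
    power_transform,
)
from crackseg.image_transform import ImageInputError, TransformParameterError


class TestGaussianGradient:
    def test_constant_image_gives_zero_gradient(self):
        g = gaussian_gradient(np.full((16, 16), 0.5), sigma=1.0)
        assert np.allclose(g.pixels, 0.0)

    def test_step_edge_gradient_peaks_at_edge(self):
        """Per-row max of the squared gradient sits on the step column,
        matching a central-finite-difference oracle on the smoothed image."""
        img = np.zeros((20, 40))
        img[:, 20:] = 1.0
        g = gaussian_gradient(img, sigma=1.0).pixels
        peak_cols = g.argmax(axis=1)
        assert np.all(np.abs(peak_cols - 19.5) <= 1.0)

        smoothed = ndimage.gaussian_filter(img, 1.0, mode="reflect", truncate=4.0)
        gx = 0.5 * (np.roll(smoothed, -1, axis=1) - np.roll(smoothed, 1, axis=1))
        oracle_peaks = (gx**2)[:, 2:-2].argmax(axis=1) + 2
        assert np.all(np.abs(peak_cols - oracle_peaks) <= 1)

    def test_smooth_then_derive_equals_derivative_kernel(self):
        """Differentiating the smoothed image equals convolving with the
        differentiated kernel (convolution associativity) — the identity
        that justifies computing the gradient with one derivative-of-
        Gaussian pass instead of smoothing first."""
        rng = np.random.default_rng(42)
        img = rng.random((64, 64))
        sigma = 1.5
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        d = np.array([0.5, 0.0, -0.5])  # central difference

        # order 1: smooth, then differentiate
        smoothed = ndimage.convolve1d(img, g, axis=1, mode="reflect")
        route_a = ndimage.convolve1d(smoothed, d, axis=1, mode="reflect")
        # order 2: differentiate the kernel, then one convolution
        dg = np.convolve(d, g)
        route_b = ndimage.convolve1d(img, dg, axis=1, mode="reflect")

        interior = (slice(None), slice(radius + 2, -(radius + 2)))
        assert np.allclose(route_a[interior], route_b[interior], atol=1e-8)

    def test_parameter_and_input_errors(self):
        with pytest.raises(TransformParameterError):
            gaussian_gradient(np.zeros((8, 8)), sigma=0.0)
        with pytest.raises(ImageInputError):
            gaussian_gradient(np.zeros((2, 2)), sigma=1.0)


class TestNegativeRescale:
    def test_direct_arithmetic(self):
        out, degenerate = negative_rescale(np.array([[0.0, 5.0], [10.0, 5.0]]))
        assert not degenerate
        assert np.allclose(out, [[1.0, 0.5], [0.0, 0.5]])

    def test_unit_input_is_complemented(self):
        x = np.array([[0.0, 0.3], [1.0, 0.7]])
        out, _ = negative_rescale(x)
        assert np.allclose(out, 1.0 - x)

    def test_constant_input_flags_degenerate(self):
        out, degenerate = negative_rescale(np.full((5, 5), 3.3))
        assert degenerate
        assert np.all(out == 1.0)

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=64).filter(
            lambda v: max(v) > min(v)
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_spans_unit_interval(self, values):
        out, _ = negative_rescale(np.array(values).reshape(1, -1))
        assert out.min() == 0.0 and out.max() == 1.0


class TestPowerTransform:
    def test_pointwise_values(self):
        out = power_transform(np.array([[0.5]]), gamma=2.0)
        assert out.pixels[0, 0] == pytest.approx(0.25)

    def test_identity_at_gamma_one(self):
        x = np.linspace(0, 1, 25).reshape(5, 5)
        assert np.array_equal(power_transform(x, 1.0).pixels, x)

    def test_contrast_stretch_ratio(self):
        out = power_transform(np.array([[0.2, 0.8]]), gamma=3.0).pixels
        assert out[0, 1] / out[0, 0] == pytest.approx(64.0)
        assert out[0, 1] / out[0, 0] > 4.0  # exceeds the input ratio

    def test_gamma_must_be_positive(self):
        with pytest.raises(TransformParameterError):
            power_transform(np.zeros((3, 3)), gamma=0.0)

    @given(
        st.floats(0.1, 8.0),
        st.lists(st.floats(1e-3, 1.0), min_size=2, max_size=32, unique=True),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_order_preserved(self, gamma, values):
        # increasing inputs never invert, and values separated beyond float
        # rounding map to strictly increasing outputs
        x = np.sort(np.array(values))
        y = power_transform(x.reshape(1, -1), gamma).pixels.ravel()
        assert np.all(np.diff(y) >= 0)
        separated = np.diff(x) > 1e-9 * x[1:]
        assert np.all(np.diff(y)[separated] > 0)


class TestPipeline:
    def test_enhanced_range_and_boundary_low(self):
        """Full pipeline stays in [0, 1] and its minimum marks the edge of a
        two-region phantom to within one pixel."""
        img = np.zeros((32, 32))
        img[:, 16:] = 0.8
        out = enhance(GrayImage(img), sigma=1.0, gamma=2.0)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        min_cols = out.pixels.argmin(axis=1)
        assert np.all(np.abs(min_cols - 15.5) <= 1.0)
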