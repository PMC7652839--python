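"""Intensity transforms that turn a grayscale image into a groove map.

The segmentation-by-fracture idea needs a scalar field whose *low* values
mark the target boundary: that field becomes the thickness of a thin plate,
so boundaries turn into grooves.  The pipeline is

1. squared Gaussian-gradient magnitude  ``|∇(G_sigma * I)|^2``  (boundaries high),
2. negative min-max rescale to [0, 1]   (boundaries low),
3. power-law (gamma) transform          (grooves deepened).

Steps 2-3 are usually applied per local window so that faint local edges are
amplified without interference from high-contrast pixels elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class TransformParameterError(ValueError):
    """A transform parameter is outside its admissible range."""


class ImageInputError(ValueError):
    """The input image violates a precondition (shape, range)."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with values rescaled to [0, 1].

    Parameters
    ----------
    pixels
        2-D float array in [0, 1].
    pixel_spacing
        Physical size of one pixel (used only to report distances in
        physical units); dimensionless 1.0 by default.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or min(p.shape) < 3:
            raise ImageInputError("image must be 2-D and at least 3x3")
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ImageInputError("image values must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GradientImage:
    """Squared Gaussian-gradient magnitude of a grayscale image."""

    pixels: np.ndarray
    sigma: float


@dataclass(frozen=True)
class EnhancedImage:
    """Contrast-enhanced negative gradient field in [0, 1].

    Low values mark boundaries.  ``degenerate`` is set when the source
    window carried no gradient information at all (constant input); the
    window driver treats such regions as boundary gaps, not as errors.
    """

    pixels: np.ndarray
    gamma: float
    degenerate: bool = field(default=False)


def load_gray_image(path: str, pixel_spacing: float = 1.0) -> GrayImage:
    """Read an 8/16-bit grayscale PNG/TIFF and normalize to [0, 1]."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    dtype = raw.dtype
    if raw.ndim == 3:  # collapse an RGB(A) save of a gray image
        raw = raw[..., :3].mean(axis=-1)
    raw = raw.astype(float)
    if np.issubdtype(dtype, np.integer):
        raw = raw / np.iinfo(dtype).max
    elif raw.max() > 1.0:
        raw = raw / raw.max()
    return GrayImage(raw, pixel_spacing=pixel_spacing)


def gaussian_gradient(
    image: GrayImage | np.ndarray,
    sigma: float,
    *,
    squared: bool = True,
) -> GradientImage:
    """Squared magnitude of the Gaussian-smoothed gradient.

    Computed with derivative-of-Gaussian kernels (differentiating the kernel
    rather than the smoothed image), truncated at 4*sigma, with reflect
    padding.  By associativity of convolution this equals smoothing first
    and differentiating after, so either order may be used interchangeably.

    Parameters
    ----------
    image
        GrayImage or bare 2-D array in [0, 1].
    sigma
        Gaussian standard deviation in pixels; must be > 0.
    squared
        If False return |grad| instead of |grad|^2.  The later min-max
        rescale is invariant to monotone maps of the gradient only up to
        shape, so the squared form is the default.
    """
    if sigma <= 0:
        raise TransformParameterError(f"sigma must be > 0, got {sigma}")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise ImageInputError("image must be 2-D and at least 3x3")
    gr = ndimage.gaussian_filter(pixels, sigma, order=(1, 0), mode="reflect", truncate=4.0)
    gc = ndimage.gaussian_filter(pixels, sigma, order=(0, 1), mode="reflect", truncate=4.0)
    mag2 = gr * gr + gc * gc
    return GradientImage(mag2 if squared else np.sqrt(mag2), sigma=float(sigma))


def negative_rescale(gradient: np.ndarray | GradientImage) -> tuple[np.ndarray, bool]:
    """Negative min-max rescale: 1 - (x - min)/(max - min).

    The global minimum of the input maps to 1 and the maximum to 0, so
    boundary pixels (high gradient) become low values.

    Returns
    -------
    (rescaled, degenerate)
        ``degenerate`` is True when the input is constant (no contrast);
        the output is then all ones and callers must treat the region as a
        boundary gap rather than a groove.
    """
    x = gradient.pixels if isinstance(gradient, GradientImage) else np.asarray(gradient, float)
    if x.size == 0:
        raise ImageInputError("empty input")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones_like(x), True
    return 1.0 - (x - lo) / (hi - lo), False


def power_transform(image: np.ndarray, gamma: float, *, degenerate: bool = False) -> EnhancedImage:
    """Elementwise power-law (gamma) transform x -> x**gamma.

    Order-preserving for any gamma > 0 with fixed points 0 and 1; gamma > 1
    stretches high values apart, deepening the grooves that the low values
    will become.
    """
    if gamma <= 0:
        raise TransformParameterError(f"gamma must be > 0, got {gamma}")
    x = np.asarray(image, float)
    if x.min() < -1e-12 or x.max() > 1 + 1e-12:
        raise ImageInputError("power_transform input must lie in [0, 1]")
    return EnhancedImage(np.clip(x, 0.0, 1.0) ** gamma, gamma=float(gamma), degenerate=degenerate)


def enhance(image: GrayImage | np.ndarray, sigma: float = 1.5, gamma: float = 2.0) -> EnhancedImage:
    """Full pipeline: gradient -> negative rescale -> gamma transform."""
    grad = gaussian_gradient(image, sigma)
    rescaled, degenerate = negative_rescale(grad)
    return power_transform(rescaled, gamma, degenerate=degenerate)


def enhance_window(window: np.ndarray, gamma: float = 2.0) -> EnhancedImage:
    """Per-window contrast enhancement of an already-computed gradient patch.

    Applies the negative rescale and gamma transform using the window's own
    min/max, so a faint local edge spans the full [0, 1] range regardless of
    stronger edges elsewhere in the image.
    """
    rescaled, degenerate = negative_rescale(window)
    return power_transform(rescaled, gamma, degenerate=degenerate)
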