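"""Synthetic phantoms with exact ground truth.

Star-convex objects (disk, ellipse, Fourier-perturbed blob) on
configurable backgrounds, with optional texture, additive Gaussian noise
and boundary gaps, plus groove-plate fixtures for the fracture solver.
Every phantom is fully determined by its spec and seed, and always comes
with the analytic boundary and the exact rasterized truth mask — gaps and
noise change only the visibility of the boundary, never the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image_transform import GrayImage


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic test image.

    shape
        'disk' | 'ellipse' | 'blob' (Fourier-perturbed disk).
    size
        Image side length in pixels (square image).
    radius
        Object radius r0 in px; for an ellipse, the semi-major axis.
    axis_ratio
        Semi-minor/semi-major for 'ellipse' (ignored otherwise).
    angle_deg
        Rotation of the ellipse major axis / blob phase offset.
    intensity
        'uniform' | 'ramp' (linear background gradient) |
        'radial' (radially inhomogeneous object interior).
    fg, bg
        Base object / background gray levels in [0, 1].
    texture
        'none' | 'sinusoid' | 'checker', applied to the background.
    texture_amp, texture_period
        Amplitude (gray levels) and period (px) of the texture.
    noise_sigma
        Additive Gaussian noise level; applied with the generator seed.
    gaps
        List of (center_deg, width_deg) arcs where the boundary contrast
        is locally erased (the edge becomes invisible; the object itself
        is unchanged).
    seed
        Seed for the blob shape and the noise.
    """

    shape: str = "disk"
    size: int = 128
    radius: float = 30.0
    axis_ratio: float = 0.7
    angle_deg: float = 0.0
    intensity: str = "uniform"
    fg: float = 0.75
    bg: float = 0.25
    texture: str = "none"
    texture_amp: float = 0.08
    texture_period: float = 9.0
    noise_sigma: float = 0.0
    gaps: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "blob"):
            raise PhantomSpecError(f"unknown shape {self.shape!r}")
        if self.intensity not in ("uniform", "ramp", "radial"):
            raise PhantomSpecError(f"unknown intensity model {self.intensity!r}")
        if self.texture not in ("none", "sinusoid", "checker"):
            raise PhantomSpecError(f"unknown texture {self.texture!r}")
        if sum(w for _, w in self.gaps) >= 360.0:
            raise PhantomSpecError("gap arcs cover the entire boundary")


@dataclass(frozen=True)
class Phantom:
    """Generated image plus exact ground truth."""

    image: GrayImage
    mask: np.ndarray            # bool, True inside the object
    boundary: np.ndarray        # (n, 2) float (row, col) analytic boundary
    spec: PhantomSpec

    @property
    def center(self) -> tuple[float, float]:
        return ((self.image.shape[0] - 1) / 2.0, (self.image.shape[1] - 1) / 2.0)


def _radius_function(spec: PhantomSpec) -> callable:
    """r(theta) of the star-convex object boundary."""
    if spec.shape == "disk":
        return lambda th: np.full_like(np.asarray(th, float), spec.radius)
    if spec.shape == "ellipse":
        a = spec.radius
        b = spec.radius * spec.axis_ratio
        phi = math.radians(spec.angle_deg)

        def r_ell(th):
            th = np.asarray(th, float) - phi
            return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

        return r_ell
    # Fourier-perturbed blob: r(th) = r0 (1 + sum a_k cos(k th + phi_k)),
    # k <= 5, |a_k| <= 0.15 -> organ-like irregular outlines
    rng = np.random.default_rng(spec.seed)
    ks = np.arange(2, 6)
    amps = rng.uniform(-0.10, 0.10, len(ks))
    phases = rng.uniform(0, 2 * np.pi, len(ks))

    def r_blob(th):
        th = np.asarray(th, float)
        pert = sum(a * np.cos(k * th + p) for k, a, p in zip(ks, amps, phases))
        return spec.radius * (1.0 + pert)

    return r_blob


def gen_phantom(spec: PhantomSpec) -> Phantom:
    """Generate image, truth mask and analytic boundary for a spec.

    The mask is the exact rasterization of the analytic shape at pixel
    centers.  Gap arcs blend the image toward the local background inside
    a thin band around the boundary, with smooth angular and radial
    tapers, so the edge disappears without creating new spurious edges
    and without touching the mask.
    """
    n = spec.size
    cy = cx = (n - 1) / 2.0
    r_of = _radius_function(spec)

    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dy = rows - cy
    dx = cols - cx
    rad = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_theta = r_of(theta)
    mask = rad <= r_theta

    # base intensities
    img = np.full((n, n), spec.bg)
    if spec.intensity == "ramp":
        img += (spec.fg - spec.bg) * 0.5 * (cols / (n - 1.0))
    if spec.texture == "sinusoid":
        img += spec.texture_amp * np.sin(2 * np.pi * cols / spec.texture_period) * np.sin(
            2 * np.pi * rows / spec.texture_period
        )
    elif spec.texture == "checker":
        img += spec.texture_amp * (
            ((rows // int(spec.texture_period)) + (cols // int(spec.texture_period))) % 2 - 0.5
        )
    bg_field = img.copy()

    if spec.intensity == "radial":
        obj = spec.fg - 0.35 * (spec.fg - spec.bg) * (rad / np.maximum(r_theta, 1e-9))
    else:
        obj = np.full((n, n), spec.fg)
    img = np.where(mask, obj, img)

    # boundary gaps: fade the object intensity into the background over a
    # thin band straddling the boundary, tapered in angle and radius
    for center_deg, width_deg in spec.gaps:
        c_rad = math.radians(center_deg)
        half = math.radians(width_deg) / 2.0
        inner = 0.4 * half  # fully erased core; cosine taper to the edges
        dtheta = np.abs(np.angle(np.exp(1j * (theta - c_rad))))
        ang_w = np.where(
            dtheta <= inner,
            1.0,
            np.clip(np.cos(np.pi * (dtheta - inner) / (2 * (half - inner))), 0.0, 1.0) ** 2,
        )
        rad_w = np.exp(-((rad - r_theta) ** 2) / (2 * 4.0**2))
        w = np.where(dtheta < half, ang_w * rad_w, 0.0)
        img = img * (1 - w) + bg_field * w

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(img, 0.0, 1.0)

    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    rb = r_of(th)
    boundary = np.column_stack([cy + rb * np.sin(th), cx + rb * np.cos(th)])

    return Phantom(image=GrayImage(img), mask=mask, boundary=boundary, spec=spec)


def gen_noise(image: np.ndarray, sigma_n: float, seed: int) -> np.ndarray:
    """Additive Gaussian noise, clipped to [0, 1], fully seeded."""
    if sigma_n < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma_n == 0:
        return np.asarray(image, float).copy()
    rng = np.random.default_rng(seed)
    return np.clip(np.asarray(image, float) + rng.normal(0, sigma_n, np.shape(image)), 0, 1)


def gen_groove_plate(
    H: float,
    groove_depth: float,
    path: str = "straight",
    size: int = 31,
    profile: str = "smooth",
    profile_width: float = 0.8,
    seed: int = 0,
    arc_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thickness field with a groove along a prescribed path.

    Parameters
    ----------
    H
        Plate height away from the groove.
    groove_depth
        Depth at the groove centerline; centerline height is H - depth.
    path
        'straight' (horizontal mid-row), 'quarter-arc' (circle of radius
        ``arc_radius`` about the top-left corner) or 'spline' (random
        cubic spline across the plate, seeded).
    profile
        'smooth': Gaussian cross-section of width ``profile_width`` px —
        the shape a blurred image edge produces through the intensity
        transforms; 'flat': binary groove one pixel wide.

    Returns
    -------
    (h, centerline)
        h is the (size, size) thickness field; centerline is (m, 2)
        float (row, col) points of the groove centerline.
    """
    if not 0 <= groove_depth < H or (groove_depth and H - groove_depth < 1):
        raise ValueError("groove depth must satisfy 1 <= H - depth < H")
    yy, xx = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5, indexing="ij")

    if path == "straight":
        mid = size // 2 + 0.5
        t = np.linspace(0, size, 4 * size)
        center = np.column_stack([np.full_like(t, mid), t])
        dist = np.abs(yy - mid)
    elif path == "quarter-arc":
        R = arc_radius if arc_radius is not None else 0.65 * size
        t = np.linspace(0, np.pi / 2, 4 * size)
        center = np.column_stack([R * np.cos(t), R * np.sin(t)])
        dist = np.abs(np.hypot(xx, yy) - R)
    elif path == "spline":
        from scipy.interpolate import CubicSpline

        rng = np.random.default_rng(seed)
        knots_x = np.array([0, size / 3, 2 * size / 3, size], float)
        knots_y = size / 2 + rng.uniform(-size / 5, size / 5, 4)
        cs = CubicSpline(knots_x, knots_y)
        t = np.linspace(0, size, 8 * size)
        ty = np.clip(cs(t), 2.5, size - 3.5)
        center = np.column_stack([ty, t])
        dist = np.min(
            np.sqrt((xx[..., None] - t) ** 2 + (yy[..., None] - ty) ** 2), axis=-1
        )
    else:
        raise ValueError(f"unknown groove path {path!r}")

    if profile == "smooth":
        h = H - groove_depth * np.exp(-(dist**2) / (2 * profile_width**2))
    elif profile == "flat":
        h = np.full((size, size), float(H))
        h[dist < 0.5 + 1e-9] = H - groove_depth
    else:
        raise ValueError(f"unknown groove profile {profile!r}")
    return h, center


def gen_edge_with_blank_band(
    size: int = 96,
    edge_col: int = 48,
    band: tuple[int, int] = (40, 52),
    taper: int = 4,
    fg: float = 0.75,
    bg: float = 0.25,
) -> tuple[np.ndarray, float]:
    """Vertical two-region edge whose contrast is erased over a row band.

    Inside ``band`` the image is replaced by a featureless wide horizontal
    ramp (the boundary is invisible there, with no spurious edges), with a
    linear taper of ``taper`` rows at both ends.  Returns (image,
    true edge column) — the true boundary runs at edge_col - 0.5 through
    the band as well, which is what a tracer bridging the blank region
    should recover.
    """
    img = np.full((size, size), bg)
    img[:, edge_col:] = fg
    ramp = bg + (fg - bg) * np.arange(size) / (size - 1)
    b0, b1 = band
    for r in range(max(b0 - taper, 0), min(b1 + taper, size)):
        if r < b0:
            w = (r - (b0 - taper) + 1) / (taper + 1)
        elif r >= b1:
            w = 1 - (r - b1 + 1) / (taper + 1)
        else:
            w = 1.0
        img[r] = (1 - w) * img[r] + w * ramp
    return img, edge_col - 0.5


# ---------------------------------------------------------------------------
# named presets reproducing the synthetic test regimes

PRESETS: dict[str, PhantomSpec] = {
    # regime: inhomogeneous background intensity
    "fig4a": PhantomSpec(shape="blob", intensity="ramp"),
    # regime: inhomogeneous object interior
    "fig4b": PhantomSpec(shape="ellipse", intensity="radial", axis_ratio=0.75, angle_deg=25.0),
    # regime: textured background
    "fig4c": PhantomSpec(shape="disk", texture="sinusoid"),
    # regime: texture plus noise
    "fig4d": PhantomSpec(shape="ellipse", texture="checker", noise_sigma=0.02, axis_ratio=0.8),
    # regime: intensity inhomogeneity plus Gaussian noise
    "fig4e": PhantomSpec(shape="ellipse", intensity="ramp", noise_sigma=0.03, axis_ratio=0.75, angle_deg=-20.0),
    # discontinuous boundary (single 10-degree gap)
    "fig3": PhantomSpec(shape="disk", gaps=((0.0, 10.0),)),
}


def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Look up a named preset, re-seeded and optionally overridden."""
    if name not in PRESETS:
        raise PhantomSpecError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
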