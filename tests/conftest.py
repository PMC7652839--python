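"""Shared fixtures: groove plates, phantoms, and path-accuracy helpers."""

from __future__ import annotations

import numpy as np
import pytest

from crackseg import MaterialParams, PhantomSpec, gen_phantom


@pytest.fixture(scope="session")
def material() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def disk_phantom():
    return gen_phantom(PhantomSpec(shape="disk", radius=30.0, size=128))


def boundary_seed(phantom, ang_idx: int = 180, spacing_px: float = 3.0):
    """Three analytic boundary points ~spacing_px apart, plus the middle one.

    Mimics a user clicking a short polyline on the visible edge.
    """
    b = phantom.boundary
    step = max(1, int(round(spacing_px / (2 * np.pi * phantom.spec.radius / len(b)))))
    n = len(b)
    pts = b[[(ang_idx - step) % n, ang_idx, (ang_idx + step) % n]]
    return pts, b[ang_idx]


def smooth_polyline(v: np.ndarray, w: int = 5) -> np.ndarray:
    """Moving-average smoothing, endpoints clamped (same operator the
    contour integration applies to open traces)."""
    if len(v) < w:
        return v
    k = np.ones(w) / w
    out = np.empty_like(np.asarray(v, float))
    for c in range(v.shape[1]):
        out[:, c] = np.convolve(np.pad(v[:, c], (w // 2, w // 2), mode="edge"), k, "valid")
    return out


def polyline_distances(vertices: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Distance from each vertex to a densely sampled reference curve."""
    v = np.asarray(vertices, float)
    c = np.asarray(curve, float)
    return np.min(
        np.sqrt(
            (v[:, 0][:, None] - c[:, 0]) ** 2 + (v[:, 1][:, None] - c[:, 1]) ** 2
        ),
        axis=1,
    )
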