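"""Initial crack placement: manual polyline or automatic ray sweep.

The first local window needs a short seed crack lying on the target
boundary.  Manually, the user supplies a few pixel coordinates along the
boundary.  Automatically, an apex point O is placed outside the window at
N window-widths from the near side; rays swept from O across the window
through a fan of half-angle arctan(1/(2N)) are intersected with a Canny
edge map, and the first edge hit per ray marks a boundary point.  A short
line segment fitted through those hits becomes the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import feature


class SeedError(ValueError):
    """No usable seed could be constructed."""


@dataclass(frozen=True)
class CrackSeed:
    """Short ordered polyline along the target boundary.

    points are (row, col) floats in window-local pixel coordinates;
    source is 'manual' or 'auto'.
    """

    points: np.ndarray
    source: str

    @property
    def direction(self) -> np.ndarray:
        """Unit (row, col) direction from first to last point."""
        v = self.points[-1] - self.points[0]
        n = np.linalg.norm(v)
        if n == 0:
            raise SeedError("degenerate seed: zero length")
        return v / n


@dataclass(frozen=True)
class SweepConfig:
    """Ray-sweep parameters.

    N
        Apex distance in window widths (> 1); larger N gives a narrower
        fan: the full sweep angle is 2*arctan(1/(2N)).
    m
        Number of angular subdivisions (>= 2); m+1 rays are cast.
    canny_sigma
        Gaussian width for the edge detector.
    low_pct, high_pct
        Hysteresis thresholds as gradient-magnitude percentiles.
    """

    N: float = 2.0
    m: int = 8
    canny_sigma: float = 1.5
    low_pct: float = 70.0
    high_pct: float = 90.0


def sweep_angles(N: float, m: int) -> tuple[float, np.ndarray]:
    """Fan half-geometry of the ray sweep.

    Returns (phi, angles): the full sweep angle phi = 2*arctan(1/(2N))
    subtended at the apex by the window's near side, and the m+1 ray
    angles i*phi/m for i = 0..m measured from the first fan edge.
    """
    if N <= 1:
        raise ValueError(f"apex distance multiple N must be > 1, got {N}")
    if not isinstance(m, (int, np.integer)) or m < 2:
        raise ValueError(f"angular subdivisions m must be an integer >= 2, got {m}")
    phi = 2.0 * math.atan(1.0 / (2.0 * N))
    return phi, np.arange(m + 1) * (phi / m)


def manual_initial_crack(points, window_shape: tuple[int, int] | None = None) -> CrackSeed:
    """Validate a user-supplied seed polyline.

    Consecutive duplicate points are dropped; at least two distinct points
    must remain, all inside the window if a shape is given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise SeedError("manual seed needs at least two (row, col) points")
    keep = [0] + [k for k in range(1, len(pts)) if not np.allclose(pts[k], pts[k - 1])]
    pts = pts[keep]
    if len(pts) < 2:
        raise SeedError("manual seed collapsed to a single point")
    if window_shape is not None:
        nr, nc = window_shape
        if (pts[:, 0] < 0).any() or (pts[:, 1] < 0).any() or (
            pts[:, 0] > nr - 1
        ).any() or (pts[:, 1] > nc - 1).any():
            raise SeedError("manual seed points outside the window")
    return CrackSeed(points=pts, source="manual")


def _ray_hits(edges: np.ndarray, apex: np.ndarray, directions: np.ndarray) -> list[np.ndarray]:
    """First edge pixel along each ray from the apex (may skip rays)."""
    nr, nc = edges.shape
    hits = []
    for d in directions:
        tmax = (np.linalg.norm(apex - np.array([nr / 2, nc / 2])) + 1.5 * max(nr, nc))
        entered = False
        for t in np.arange(0.0, tmax, 0.5):
            p = apex + t * d
            r, c = int(round(p[0])), int(round(p[1]))
            if r < 0 or c < 0 or r >= nr or c >= nc:
                if entered:
                    break  # ray crossed the window without an edge hit
                continue
            entered = True
            if edges[r, c]:
                hits.append(np.array([p[0], p[1]]))
                break
    return hits


def auto_initial_crack(window: np.ndarray, config: SweepConfig | None = None) -> CrackSeed:
    """Automatic seed via ray sweep against a Canny edge map.

    The sweep is attempted from all four window sides (apex beyond each
    midpoint at N side-lengths); the orientation collecting the most ray
    hits wins.  A total-least-squares line through the hits, clipped to a
    few pixels around their centroid, is returned as the seed.
    """
    config = config or SweepConfig()
    win = np.asarray(window, dtype=float)
    nr, nc = win.shape
    edges = feature.canny(
        win,
        sigma=config.canny_sigma,
        low_threshold=config.low_pct / 100.0,
        high_threshold=config.high_pct / 100.0,
        use_quantiles=True,
    )
    if not edges.any():
        raise SeedError("no edges detected in window")

    phi, angles = sweep_angles(config.N, config.m)
    side = float(max(nr, nc))
    center = np.array([(nr - 1) / 2.0, (nc - 1) / 2.0])
    best_hits: list[np.ndarray] = []
    # apex beyond each side midpoint; fan axis points back across the window
    for axis in (
        np.array([1.0, 0.0]),
        np.array([-1.0, 0.0]),
        np.array([0.0, 1.0]),
        np.array([0.0, -1.0]),
    ):
        apex = center - axis * (config.N * side)
        base = math.atan2(axis[1], axis[0])
        dirs = []
        for a in angles:
            ang = base - phi / 2.0 + a
            dirs.append(np.array([math.cos(ang), math.sin(ang)]))
        hits = _ray_hits(edges, apex, np.array(dirs))
        if len(hits) > len(best_hits):
            best_hits = hits
    if len(best_hits) < 2:
        raise SeedError("fewer than two ray hits: boundary not found")

    pts = np.array(best_hits)
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]  # total-least-squares line direction
    proj = (pts - centroid) @ direction
    half = min(2.5, max(1.0, (proj.max() - proj.min()) / 2.0))
    seed_pts = np.array(
        [centroid - half * direction, centroid, centroid + half * direction]
    )
    seed_pts = np.clip(seed_pts, 0, [nr - 1, nc - 1])
    return CrackSeed(points=seed_pts, source="auto")
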