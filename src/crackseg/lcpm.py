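"""Local crack-propagation driver: window iteration and contour assembly.

The segmentation loop never builds one huge plate.  Instead it walks the
boundary with small overlapping square windows: each window is enhanced
(negative gradient rescale + gamma), converted to a variable-thickness
plate, and cracked from a seed inherited from the previous window's crack
tail.  The crack's direction sets the next window center, stepped a fixed
distance alpha along the fitted boundary line, so consecutive windows
always overlap and the new window contains the old crack's end as its
initial crack.  Fragments are merged, deduplicated in the overlaps,
optionally closed, smoothed, and rasterized to a mask.

Boundary gaps appear as windows whose groove vanishes: the front stalls,
and the driver either lets the solver bridge a short gap or spawns a
second front in a window past the degenerate region, continuing in the
same travel sense; the blank span is closed with a straight bridge at
integration time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import fracture
from .crack_init import SweepConfig, auto_initial_crack, manual_initial_crack
from .fracture import CrackPath, LoadSpec
from .image_transform import GrayImage, enhance_window, gaussian_gradient
from .plate_model import (
    MaterialParams,
    WindowSpec,
    build_mesh,
    extract_window,
    thickness_map,
)

logger = logging.getLogger(__name__)


class LcpmConfigError(ValueError):
    pass


class LcpmError(RuntimeError):
    pass


@dataclass(frozen=True)
class LcpmConfig:
    """Driver configuration.

    L
        Window half-size; windows are (2L+1) square.
    alpha
        Center step between consecutive windows, 0 < alpha < 2L so that
        windows overlap and each inherits the previous crack's tail.
    H
        Maximum plate thickness; the groove floor is always 1.
    sigma, gamma
        Gaussian-gradient width and power-law exponent of the intensity
        transforms.
    transform_scope
        'window': re-normalize (rescale + gamma) per window so faint local
        edges always span the full thickness range; 'global': transform
        once on the whole image.
    closure_eps
        Arming distance for closure: the front must first travel at least
        2 * closure_eps from its start before closure is considered.
    closure_tol
        Close the contour as soon as any newly traced vertex comes within
        this distance of the contour start (checked per vertex, so the
        returning front cannot step over the start between windows).
    fit_tail
        Number of tail crack points used to fit the local boundary
        direction.
    seed_tail
        Number of tail vertices carried into the next window as its seed.
    gap_scan
        How far (px) past a stalled tip to search for the boundary to
        resume before giving up on a second front.
    max_windows
        Iteration guard.
    """

    L: int = 15
    alpha: float = 10.0
    H: float = 20.0
    sigma: float = 0.8
    gamma: float = 2.0
    transform_scope: str = "window"
    closure_eps: float | None = None
    closure_tol: float = 3.0
    fit_tail: int = 12
    seed_tail: int = 5
    gap_scan: int = 40
    max_windows: int = 500
    material: MaterialParams = field(default_factory=MaterialParams)
    load: LoadSpec = field(default_factory=LoadSpec)
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def __post_init__(self) -> None:
        if self.L < 4:
            raise LcpmConfigError(f"window half-size L must be >= 4, got {self.L}")
        if not (0 < self.alpha < 2 * self.L):
            raise LcpmConfigError(
                f"window step alpha must satisfy 0 < alpha < 2L = {2 * self.L}, got {self.alpha}"
            )
        if self.transform_scope not in ("window", "global"):
            raise LcpmConfigError("transform_scope must be 'window' or 'global'")

    @property
    def eps(self) -> float:
        return self.alpha if self.closure_eps is None else self.closure_eps


@dataclass
class LocalBoundary:
    """Crack of one window mapped to global image coordinates."""

    points: np.ndarray  # (n, 2) float (row, col)
    window_index: int
    theta: float | None = None  # fitted boundary orientation, radians
    bridge_before: bool = False  # straight bridge joins this fragment to the previous


@dataclass
class Contour:
    """Merged global segmentation boundary."""

    points: np.ndarray  # (n, 2) float (row, col)
    closed: bool
    provenance: list[int] = field(default_factory=list)
    windows: int = 0
    stalls: int = 0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the contour interior (pixel centers inside the polygon)."""
        from skimage.draw import polygon

        rr, cc = polygon(self.points[:, 0], self.points[:, 1], shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    def to_json(self, config_echo: dict | None = None) -> str:
        return json.dumps(
            {
                "points": np.round(self.points, 3).tolist(),
                "closed": self.closed,
                "provenance": self.provenance,
                "windows": self.windows,
                "stalls": self.stalls,
                "config": config_echo or {},
            }
        )


# ---------------------------------------------------------------------------
# coordinate plumbing

def _node_to_global(ij: tuple[int, int], origin: tuple[int, int]) -> np.ndarray:
    """Window lattice node (i, j) -> global (row, col).

    Mesh nodes sit at pixel corners: node (i, j) of a window whose
    top-left pixel is (r0, c0) lies at (r0 - 0.5 + i, c0 - 0.5 + j).
    """
    return np.array([origin[0] - 0.5 + ij[0], origin[1] - 0.5 + ij[1]])


def _global_to_node(g: np.ndarray, origin: tuple[int, int]) -> tuple[int, int]:
    return (int(round(g[0] + 0.5 - origin[0])), int(round(g[1] + 0.5 - origin[1])))


def crack_to_boundary(crack: CrackPath, origin: tuple[int, int], window_index: int = 0) -> LocalBoundary:
    """Map a window-local crack polyline to global image coordinates."""
    if len(crack.grid_vertices) == 0:
        raise LcpmError("empty crack")
    pts = np.array([_node_to_global(v, origin) for v in crack.grid_vertices])
    return LocalBoundary(points=pts, window_index=window_index)


def fit_boundary_direction(points: np.ndarray) -> float:
    """Orientation of the best-fit line through boundary points.

    Total-least-squares (first principal direction), so vertical
    boundaries — infinite ordinary slope — are handled; the angle theta
    in (-pi/2, pi/2] satisfies tan(theta) = slope whenever the ordinary
    slope exists.  Measured in the (x=col, y=row) plane.
    """
    pts = np.asarray(points, float)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise LcpmError("need at least two distinct points to fit a direction")
    xy = np.column_stack([pts[:, 1], pts[:, 0]])  # (x, y)
    xy = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    vx, vy = vt[0]
    theta = np.arctan2(vy, vx)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return float(theta)


def next_center(
    center: tuple[float, float],
    theta: float,
    alpha: float,
    prev_step: np.ndarray,
) -> tuple[float, float]:
    """Step the window center a distance alpha along the boundary line.

    The boundary fit gives an orientation, not a direction; the sign is
    chosen so the step continues the previous travel (positive dot
    product with ``prev_step``, a (row, col) vector).
    """
    if alpha <= 0:
        raise LcpmConfigError("alpha must be positive")
    d = np.array([np.sin(theta), np.cos(theta)])  # (row, col)
    if float(d @ np.asarray(prev_step, float)) < 0:
        d = -d
    return (center[0] + alpha * d[0], center[1] + alpha * d[1])


# ---------------------------------------------------------------------------
# seed plumbing

def _snap_to_lattice_path(
    points: np.ndarray, origin: tuple[int, int], shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Snap float global points to a connected window lattice path."""
    rows, cols = shape
    nodes: list[tuple[int, int]] = []
    for g in points:
        ij = _global_to_node(np.asarray(g, float), origin)
        ij = (min(max(ij[0], 0), rows), min(max(ij[1], 0), cols))
        if not nodes or ij != nodes[-1]:
            # L-path from previous node: rows first, then columns
            if nodes:
                i0, j0 = nodes[-1]
                while i0 != ij[0]:
                    i0 += 1 if ij[0] > i0 else -1
                    if (i0, j0) != nodes[-1]:
                        nodes.append((i0, j0))
                while j0 != ij[1]:
                    j0 += 1 if ij[1] > j0 else -1
                    nodes.append((i0, j0))
            else:
                nodes.append(ij)
    # drop accidental repeats while keeping order
    seen = {}
    out = []
    for nd in nodes:
        if nd in seen:
            # truncate a loop back to the first occurrence
            out = out[: seen[nd] + 1]
            seen = {v: k for k, v in enumerate(out)}
            continue
        seen[nd] = len(out)
        out.append(nd)
    return out


def _seed_for_window(
    prev_tail: np.ndarray, origin: tuple[int, int], shape: tuple[int, int], n_tail: int
) -> list[tuple[int, int]]:
    """Build the next window's seed from the previous crack's tail points."""
    rows, cols = shape
    inside = []
    for g in prev_tail:
        i, j = _global_to_node(g, origin)
        if 0 <= i <= rows and 0 <= j <= cols:
            inside.append(g)
        else:
            inside = []
    if len(inside) < 2:
        raise LcpmError("previous crack tail does not reach into the next window")
    return _snap_to_lattice_path(np.array(inside[-n_tail:]), origin, shape)


# ---------------------------------------------------------------------------
# merging

def merge_and_smooth(
    fragments: list[LocalBoundary],
    closed: bool,
    smooth_window: int = 5,
    dedup_tol: float = 1.5,
) -> Contour:
    """Integrate per-window boundary fragments into one contour.

    Overlap runs are deduplicated by proximity against the tail of the
    merged polyline; gaps between fragments (dual-front bridges) are
    closed implicitly by polyline continuity.  A moving-average smoothing
    pass (wrap-around when closed, endpoint-preserving when open) gives
    the final trace; closed contours are oriented counterclockwise.
    """
    if not fragments:
        raise LcpmError("no fragments to merge")
    merged: list[np.ndarray] = []
    provenance: list[int] = []
    for frag in fragments:
        for p in frag.points:
            if merged:
                tail = np.array(merged[-8:])
                if np.min(np.linalg.norm(tail - p, axis=1)) < dedup_tol:
                    continue
            merged.append(np.asarray(p, float))
            provenance.append(frag.window_index)
    pts = np.array(merged)
    if len(pts) < 3:
        raise LcpmError("merged contour degenerate")

    w = max(1, int(smooth_window))
    if w > 1 and len(pts) > w:
        kernel = np.ones(w) / w
        if closed:
            padded = np.vstack([pts[-(w // 2):], pts, pts[: w // 2]])
        else:
            padded = np.vstack(
                [np.repeat(pts[:1], w // 2, axis=0), pts, np.repeat(pts[-1:], w // 2, axis=0)]
            )
        sm = np.column_stack(
            [np.convolve(padded[:, k], kernel, mode="valid") for k in range(2)]
        )
        if not closed:
            sm[0], sm[-1] = pts[0], pts[-1]  # endpoints preserved exactly
        pts = sm

    if closed:
        # counterclockwise in the (x=col, y=row) plane
        x, y = pts[:, 1], pts[:, 0]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area < 0:
            pts = pts[::-1]
            provenance = provenance[::-1]

    return Contour(points=pts, closed=closed, provenance=provenance)


# ---------------------------------------------------------------------------
# the driver

@dataclass
class LcpmResult:
    contour: Contour
    mask: np.ndarray
    fragments: list[LocalBoundary]
    onset_log: list[dict]


def run_lcpm(
    image: GrayImage | np.ndarray,
    first_center: tuple[int, int],
    seed_points: np.ndarray | None = None,
    config: LcpmConfig | None = None,
) -> LcpmResult:
    """Segment one boundary by iterated local crack propagation.

    Parameters
    ----------
    image
        Grayscale image in [0, 1].
    first_center
        Center (row, col) of the first window; it must contain a piece of
        the target boundary.
    seed_points
        Optional manual seed: ordered (row, col) global coordinates of a
        short polyline along the boundary.  When omitted, the automatic
        ray-sweep seeder runs in the first window.
    config
        LcpmConfig; defaults are suitable for objects tens of pixels
        across.

    Returns
    -------
    LcpmResult with the merged contour (closed flag set when the crack
    returned to its start), the rasterized mask, per-window fragments and
    the onset-load log.
    """
    cfg = config or LcpmConfig()
    img = image if isinstance(image, GrayImage) else GrayImage(np.asarray(image, float))
    pixels = img.pixels
    shape = pixels.shape

    grad = gaussian_gradient(img, cfg.sigma).pixels
    if cfg.transform_scope == "global":
        enhanced_global = enhance_window(grad, cfg.gamma).pixels

    def window_field(spec: WindowSpec):
        if cfg.transform_scope == "window":
            patch = extract_window(grad, spec)
            enh = enhance_window(patch.pixels, cfg.gamma)
            return patch, enh.pixels, enh.degenerate
        patch = extract_window(enhanced_global, spec)
        return patch, patch.pixels, bool(np.ptp(patch.pixels) == 0)

    fragments: list[LocalBoundary] = []
    onset_log: list[dict] = []
    contour_start: np.ndarray | None = None
    armed = False
    closed = False
    stalls = 0
    n_stall_fronts = 0

    center = (float(first_center[0]), float(first_center[1]))
    prev_step: np.ndarray | None = None
    seed_nodes: list[tuple[int, int]] | None = None
    pending_bridge = False

    def handle_stall(tip_global: np.ndarray, tail: np.ndarray) -> bool:
        """Spawn a second front past a degenerate region; True to continue."""
        nonlocal center, seed_nodes, prev_step, pending_bridge, n_stall_fronts
        # a stalling front often ends in a few confused vertices (failed
        # bridge probes at the gap edge); anchor the resume scan a few
        # points back and take the direction from a line fit over the
        # clean tail before them
        pts = np.vstack([f.points for f in fragments])
        anchor = pts[-4] if len(pts) >= 4 else pts[-1]
        fit_pts = pts[-14:-3] if len(pts) >= 14 else pts[: max(len(pts) - 3, 2)]
        try:
            theta_fit = fit_boundary_direction(fit_pts)
            travel = np.array([np.sin(theta_fit), np.cos(theta_fit)])
            along = fit_pts[-1] - fit_pts[0]
            if float(travel @ along) < 0:
                travel = -travel
        except LcpmError:
            travel = tail[-1] - tail[max(len(tail) - 4, 0)]
            nrm = np.linalg.norm(travel)
            travel = travel / nrm if nrm > 0 else np.asarray(prev_step, float)
        spawned = _find_resume_point(grad, fragments, anchor, travel, cfg)
        if spawned is None:
            logger.warning(
                "front stalled at %s with no resume point; contour left open", tip_global
            )
            return False
        n_stall_fronts += 1
        if n_stall_fronts > 8:
            logger.warning("too many stalled fronts; contour left open")
            return False
        resume_center, resume_dir = spawned
        center = (float(resume_center[0]), float(resume_center[1]))
        spec_b = WindowSpec(
            center=(int(round(center[0])), int(round(center[1]))), half_size=cfg.L
        )
        gray_patch = extract_window(pixels, spec_b)
        try:
            seed_b = auto_initial_crack(gray_patch.pixels, cfg.sweep)
        except Exception:
            logger.warning("second front seeding failed; contour left open")
            return False
        pts_b = seed_b.points
        if float(seed_b.direction @ resume_dir) < 0:
            pts_b = pts_b[::-1]
        seed_global_b = pts_b + np.asarray(gray_patch.origin, float)
        seed_nodes = _snap_to_lattice_path(
            seed_global_b, gray_patch.origin, gray_patch.pixels.shape
        )
        prev_step = resume_dir
        pending_bridge = True
        return True

    k = 0
    while k < cfg.max_windows:
        spec = WindowSpec(center=(int(round(center[0])), int(round(center[1]))), half_size=cfg.L)
        patch, field_px, degenerate = window_field(spec)
        origin = patch.origin

        if degenerate:
            # information-free window: a boundary gap, not an error —
            # unless it is the very first window, which must see the edge
            if k == 0 or not fragments:
                raise LcpmError("degenerate first window: no boundary information")
            stalls += 1
            prev_tail = fragments[-1].points
            if not handle_stall(prev_tail[-1], prev_tail[-min(4, len(prev_tail)):]):
                break
            k += 1
            continue

        if seed_nodes is None:
            if seed_points is not None:
                seed = manual_initial_crack(
                    np.asarray(seed_points, float) - np.asarray(origin, float),
                    window_shape=field_px.shape,
                )
            else:
                gray_patch = extract_window(pixels, spec)
                seed = auto_initial_crack(gray_patch.pixels, cfg.sweep)
            seed_global = seed.points + np.asarray(origin, float)
            seed_nodes = _snap_to_lattice_path(seed_global, origin, field_px.shape)
            if len(seed_nodes) < 2:
                raise LcpmError("seed too short after snapping to the mesh")

        thick = thickness_map(field_px, cfg.H)
        mesh = build_mesh(thick, cfg.material, origin=origin)
        crack = fracture.propagate_crack(mesh, seed_nodes, cfg.material, cfg.load)

        # the fully clamped window border distorts the stress field in its
        # immediate neighborhood; vertices grown within 2 px of the border
        # are discarded (the next, overlapping window re-traces that zone)
        def _border_dist(v: tuple[int, int]) -> int:
            return min(v[0], mesh.rows - v[0], v[1], mesh.cols - v[1])

        if not crack.stalled and _border_dist(crack.tip) == 0:
            while (
                len(crack.grid_vertices) > len(seed_nodes) + 2
                and _border_dist(crack.grid_vertices[-1]) < 2
            ):
                crack.grid_vertices.pop()
                if crack.onset_loads:
                    crack.onset_loads.pop()

        frag = crack_to_boundary(crack, origin, window_index=k)
        frag.bridge_before = pending_bridge
        pending_bridge = False
        new_pts = frag.points[max(len(seed_nodes) - 1, 0):]
        frag_for_merge = LocalBoundary(
            points=new_pts if k > 0 else frag.points,
            window_index=k,
            bridge_before=frag.bridge_before,
        )
        fragments.append(frag_for_merge)
        onset_log.append(
            {
                "window": k,
                "center": [spec.center[0], spec.center[1]],
                "onsets": [None if not np.isfinite(o) else float(o) for o in crack.onset_loads],
                "stalled": bool(crack.stalled),
                "bridged": len(crack.bridged_steps),
            }
        )

        tip_global = _node_to_global(crack.tip, origin)
        if contour_start is None:
            contour_start = frag.points[0]

        # closure / termination checks
        dist_start = float(np.linalg.norm(tip_global - contour_start))
        if dist_start > 2.0 * cfg.eps:
            armed = True
        if armed and k >= 2 and len(frag_for_merge.points):
            d_start = np.linalg.norm(frag_for_merge.points - contour_start, axis=1)
            hit = np.flatnonzero(d_start <= cfg.closure_tol)
            if hit.size:
                # truncate at the closest approach and close the loop
                frag_for_merge.points = frag_for_merge.points[: hit[0] + 1]
                closed = True
                break
        if (
            tip_global[0] <= 0.5
            or tip_global[1] <= 0.5
            or tip_global[0] >= shape[0] - 1.5
            or tip_global[1] >= shape[1] - 1.5
        ):
            break  # boundary ran off the image

        tail = frag.points[-min(cfg.fit_tail, len(frag.points)):]
        theta = fit_boundary_direction(tail)
        frag.theta = theta
        if prev_step is None:
            prev_step = frag.points[-1] - frag.points[0]

        if crack.stalled:
            stalls += 1
            if not handle_stall(tip_global, tail):
                break
            k += 1
            continue

        center = next_center(center, theta, cfg.alpha, prev_step)
        prev_step = np.array([np.sin(theta), np.cos(theta)])
        if float(prev_step @ (frag.points[-1] - frag.points[0])) < 0:
            prev_step = -prev_step
        center = (
            float(np.clip(center[0], 0, shape[0] - 1)),
            float(np.clip(center[1], 0, shape[1] - 1)),
        )
        next_spec = WindowSpec(
            center=(int(round(center[0])), int(round(center[1]))), half_size=cfg.L
        )
        next_patch = extract_window(grad, next_spec)
        try:
            seed_nodes = _seed_for_window(
                frag.points, next_patch.origin, next_patch.pixels.shape, cfg.seed_tail
            )
        except LcpmError:
            # curvature outran the step: fall back to a window centered on
            # the crack tip so the tail is always inside
            center = (
                float(np.clip(tip_global[0], 0, shape[0] - 1)),
                float(np.clip(tip_global[1], 0, shape[1] - 1)),
            )
            retry_spec = WindowSpec(
                center=(int(round(center[0])), int(round(center[1]))), half_size=cfg.L
            )
            retry_patch = extract_window(grad, retry_spec)
            seed_nodes = _seed_for_window(
                frag.points, retry_patch.origin, retry_patch.pixels.shape, cfg.seed_tail
            )
        k += 1

    contour = merge_and_smooth(fragments, closed=closed)
    contour.windows = len(fragments)
    contour.stalls = stalls
    mask = contour.mask(shape)
    return LcpmResult(contour=contour, mask=mask, fragments=fragments, onset_log=onset_log)


def _find_resume_point(
    grad: np.ndarray,
    fragments: list[LocalBoundary],
    tip: np.ndarray,
    travel: np.ndarray,
    cfg: LcpmConfig,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Scan past a stalled tip for the point where the boundary resumes.

    Reference edge strength is the median gradient along the boundary
    traced so far; the scan walks the straight continuation and triggers
    when the local gradient maximum (across a short transverse segment)
    recovers a quarter of that reference.  Returns (window center,
    travel direction) for the second front, or None.
    """
    ref_pts = np.vstack([f.points for f in fragments])[-60:]
    vals = []
    for p in ref_pts:
        r, c = int(round(p[0])), int(round(p[1]))
        if 0 <= r < grad.shape[0] and 0 <= c < grad.shape[1]:
            vals.append(grad[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2].max())
    if not vals:
        return None
    ref = float(np.median(vals))
    normal = np.array([-travel[1], travel[0]])
    for t in range(3, cfg.gap_scan):
        p = tip + t * travel
        # widening transverse probe: a curved boundary sags away from the
        # straight continuation, the farther the more
        half_width = 2 + t // 4
        strengths = []
        best_off = 0
        for s in range(-half_width, half_width + 1):
            q = p + s * normal
            r, c = int(round(q[0])), int(round(q[1]))
            if 0 <= r < grad.shape[0] and 0 <= c < grad.shape[1]:
                strengths.append(grad[r, c])
                if grad[r, c] == max(strengths):
                    best_off = s
        if not strengths:
            return None  # ran off the image
        if max(strengths) >= 0.25 * ref:
            center = p + best_off * normal + (cfg.L / 2.0) * travel
            center = np.clip(center, [0, 0], [grad.shape[0] - 1, grad.shape[1] - 1])
            return center, travel
    return None


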