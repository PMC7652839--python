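"""Quasi-static brittle crack growth in a variable-thickness plate.

The crack is an explicit polyline along mesh edges.  Displacement jumps
across it are made possible by node splitting: every vertex strictly
interior to the crack is duplicated and the elements on either side of the
path reference opposite copies, so the faces can separate while the tip
node stays shared.

Loading follows the glass-cutter picture: a pair of equal-and-opposite
nodal force patches straddles the crack just behind the tip, pulling the
faces apart normal to the crack (Mode-I opening).  The load ramps linearly
from zero in steps of ``ramp_step``; because the problem is linear, one
unit-load solve per crack configuration determines the first ramp step at
which the maximum principal stress in any candidate element ahead of the
tip reaches the material threshold.  The crack then extends one mesh edge
toward the failing material, the new vertex is split, the ramp resets, and
the loop repeats.  Extension is instantaneous-brittle: no softening law,
the fracture energy parameter is accepted but unused.

A groove (thin elements) ahead of the tip concentrates stress roughly in
proportion to the thickness contrast, which is what steers the crack along
the image boundary.  Where the groove is interrupted (a boundary gap), the
required load exceeds the ramp cap; the crack may then penetrate a short
gap by straight continuation, and stalls otherwise so the window driver
can start a second front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import fem
from .plate_model import MaterialParams, PlateMesh


class CrackError(ValueError):
    """Crack geometry violates a precondition (off-mesh, self-intersecting)."""


# lattice steps (di, dj) in grid-index space; x=j, y=i
_STEPS = ((0, 1), (0, -1), (1, 0), (-1, 0))


@dataclass
class CrackPath:
    """Ordered crack polyline on the structured node lattice.

    ``grid_vertices`` are (i, j) structured-grid indices of consecutive,
    edge-adjacent nodes; the first vertex is the seed entry, the last is
    the tip.  ``onset_loads`` records the ramp load at which each extension
    fired (NaN for forced gap-bridging steps, whose indices are listed in
    ``bridged_steps``).
    """

    grid_vertices: list[tuple[int, int]]
    stalled: bool = False
    onset_loads: list[float] = field(default_factory=list)
    bridged_steps: list[int] = field(default_factory=list)
    ramp_cap_used: float | None = None
    ramp_step_used: float | None = None

    @property
    def tip(self) -> tuple[int, int]:
        return self.grid_vertices[-1]

    @property
    def tip_direction(self) -> np.ndarray:
        """Unit vector (x, y) of the last segment."""
        (i0, j0), (i1, j1) = self.grid_vertices[-2], self.grid_vertices[-1]
        v = np.array([j1 - j0, i1 - i0], float)
        return v / np.linalg.norm(v)

    def travel_direction(self, window: int = 3) -> np.ndarray:
        """Unit mean direction of the last ``window`` segments.

        Smoother than ``tip_direction``: after a one-step kink (e.g. the
        crack hopping from one face of a groove row to the other) the
        overall travel is still along the groove, and the forward-material
        test must use that, not the kink itself.
        """
        k = min(window, len(self.grid_vertices) - 1)
        (i0, j0) = self.grid_vertices[-1 - k]
        (i1, j1) = self.grid_vertices[-1]
        v = np.array([j1 - j0, i1 - i0], float)
        n = np.linalg.norm(v)
        return v / n if n > 0 else self.tip_direction

    def vertices_xy(self, pixel_size: float = 1.0) -> np.ndarray:
        """(n, 2) window-local (x, y) coordinates of the vertices."""
        g = np.asarray(self.grid_vertices, float)
        return np.column_stack([g[:, 1], g[:, 0]]) * pixel_size

    def __len__(self) -> int:
        return len(self.grid_vertices)


@dataclass(frozen=True)
class LoadSpec:
    """Tip-local ramp loading parameters.

    patch_radius
        Radius (px) of the two opposing force patches behind the tip.
    ramp_cap
        Optional hard maximum total force.  The default (None) realizes
        the prescription of a cap "large enough to break every thin
        structure": the ramp always reaches the onset of a failing thin
        element, and growth stops only where no thin material lies ahead.
        An explicit finite cap additionally stalls the front whenever the
        onset would exceed it (useful for uniform plates in tests).
    ramp_step
        Force increment per ramp iteration; defaults to 1/10 of the first
        extension's required load and is then held fixed, so every onset
        is quantized on the same ramp.
    gap_thickness_frac
        An element counts as part of a groove (thin, crackable) when its
        thickness is below min + frac * (max - min) of the window's
        thickness range.  Above that, the material ahead is considered a
        boundary gap.
    gap_max
        Maximum number of forced straight extensions allowed to bridge a
        groove gap before the front is declared stalled.
    look_radius
        Radius (px) of the forward neighborhood searched for the failure
        ridge when steering the next extension.
    max_backtracks, backtrack_window
        A stalled front may rewind up to ``backtrack_window`` recent
        vertices to the nearest genuinely ambiguous side choice and take
        the other branch, at most ``max_backtracks`` times per window.
    """

    patch_radius: float = 3.0
    ramp_cap: float | None = None
    ramp_step: float | None = None
    gap_thickness_frac: float = 0.35
    gap_max: int = 3
    look_radius: float = 3.0
    max_backtracks: int = 12
    backtrack_window: int = 6


def validate_crack(mesh: PlateMesh, grid_vertices: list[tuple[int, int]]) -> None:
    if len(grid_vertices) < 2:
        raise CrackError("crack needs at least two vertices")
    if len(set(grid_vertices)) != len(grid_vertices):
        raise CrackError("crack path is self-intersecting")
    for (i0, j0), (i1, j1) in zip(grid_vertices, grid_vertices[1:]):
        if abs(i0 - i1) + abs(j0 - j1) != 1:
            raise CrackError(f"vertices {(i0, j0)}-{(i1, j1)} are not edge neighbors")
    for i, j in grid_vertices:
        if not (0 <= i <= mesh.rows and 0 <= j <= mesh.cols):
            raise CrackError(f"vertex {(i, j)} outside mesh")


def split_nodes(mesh: PlateMesh, crack: CrackPath | list[tuple[int, int]]) -> PlateMesh:
    """Duplicate the crack's interior nodes so the faces can separate.

    Every vertex strictly interior to the polyline is duplicated; the up to
    four elements incident to it are partitioned by the two crack edges
    meeting there (sweeping counterclockwise from the incoming to the
    outgoing edge direction), and one side is rewired to the duplicate.
    Endpoints (seed entry and tip) keep a single shared node.
    """
    verts = crack.grid_vertices if isinstance(crack, CrackPath) else list(crack)
    validate_crack(mesh, verts)

    node_xy = mesh.node_xy
    grid_node = mesh.grid_node
    elem_nodes = mesh.elem_nodes.copy()
    new_xy: list[np.ndarray] = []
    new_grid: list[np.ndarray] = []
    next_id = mesh.n_nodes

    def elem_id(r: int, c: int) -> int | None:
        if 0 <= r < mesh.rows and 0 <= c < mesh.cols:
            return r * mesh.cols + c
        return None

    for k in range(1, len(verts) - 1):
        i, j = verts[k]
        if i in (0, mesh.rows) or j in (0, mesh.cols):
            # border vertices stay single: both copies would be fully
            # constrained anyway, and the angular element partition is
            # undefined with part of the neighborhood missing
            continue
        ip, jp = verts[k - 1]
        inx, jnx = verts[k + 1]
        node = mesh.structured_node(i, j)
        # angles of the incoming/outgoing crack edges, in (x, y) = (j, i)
        a_in = math.atan2(ip - i, jp - j)
        a_out = math.atan2(inx - i, jnx - j)
        sweep = (a_out - a_in) % (2 * math.pi)
        moved = []
        for dr, dc in ((-1, -1), (-1, 0), (0, -1), (0, 0)):
            e = elem_id(i + dr, j + dc)
            if e is None:
                continue
            # element centroid direction from the vertex
            a_e = math.atan2(dr + 0.5, dc + 0.5)
            if 0.0 < (a_e - a_in) % (2 * math.pi) < sweep:
                moved.append(e)
        if not moved or len(moved) == 4:
            raise CrackError(f"degenerate split at vertex {(i, j)}")
        dup = next_id
        next_id += 1
        new_xy.append(node_xy[node])
        new_grid.append(grid_node[node])
        for e in moved:
            en = elem_nodes[e]
            en[en == node] = dup

    if not new_xy:
        return replace_mesh(mesh, elem_nodes=elem_nodes)
    return replace_mesh(
        mesh,
        node_xy=np.vstack([node_xy, np.array(new_xy)]),
        grid_node=np.vstack([grid_node, np.array(new_grid)]),
        elem_nodes=elem_nodes,
    )


def replace_mesh(mesh: PlateMesh, **kw) -> PlateMesh:
    return replace(mesh, **kw)


def tip_loads(mesh: PlateMesh, crack: CrackPath, magnitude: float, patch_radius: float = 3.0) -> np.ndarray:
    """Opposing nodal force patches straddling the crack behind the tip.

    The patch center sits ``2 px`` behind the tip on the crack line; nodes
    within ``patch_radius`` of it are split by the sign of their offset
    along the crack normal (nodes on the line itself are skipped).  Each
    side receives total force ``magnitude`` along +/- normal, shared
    equally among its nodes — a force couple normal to the crack at the
    tip, i.e. Mode-I opening.  The normal is taken from the smoothed travel
    direction so a single-step kink (the crack hopping across a groove row)
    does not swing the pull parallel to the boundary.
    """
    t = crack.travel_direction()  # (x, y)
    normal = np.array([-t[1], t[0]])
    g = np.asarray(crack.grid_vertices[-1], float)
    tip_xy = np.array([g[1], g[0]]) * mesh.pixel_size
    center = tip_xy - 2.0 * mesh.pixel_size * t

    rel = mesh.node_xy - center
    dist = np.linalg.norm(rel, axis=1)
    side = rel @ normal
    near = dist <= patch_radius * mesh.pixel_size
    pos = near & (side > 0.25 * mesh.pixel_size)
    neg = near & (side < -0.25 * mesh.pixel_size)

    forces = np.zeros((mesh.n_nodes, 2))
    if pos.any():
        forces[pos] += magnitude * normal / pos.sum()
    if neg.any():
        forces[neg] -= magnitude * normal / neg.sum()
    return forces


def _candidate_edges(mesh: PlateMesh, crack: CrackPath) -> list[tuple[int, int]]:
    """Forward lattice steps from the tip: within +/-90 deg of travel,
    staying on the mesh and off the existing path (simple path).

    Steps landing next to an older crack vertex are also excluded: the
    material flanking an open crack face is already traversed boundary,
    and re-cracking alongside it would retrace the same image edge.
    """
    i, j = crack.tip
    t = crack.tip_direction
    visited = set(crack.grid_vertices)
    older = set(crack.grid_vertices[:-2])
    cands = []
    for di, dj in _STEPS:
        nxt = (i + di, j + dj)
        if nxt in visited:
            continue
        if not (0 <= nxt[0] <= mesh.rows and 0 <= nxt[1] <= mesh.cols):
            continue
        if any((nxt[0] + a, nxt[1] + b) in older for a, b in _STEPS):
            continue
        d = np.array([dj, di], float)
        if d @ t >= -1e-9:  # forward half-plane; backward growth forbidden
            cands.append((di, dj))
    return cands


@dataclass
class _RidgeEval:
    """Unit-load evaluation of the stress ridge ahead of the tip.

    ``sigma1_unit`` is the maximum principal stress (per unit load) over
    the forward elements within the look radius; ``target`` is the
    centroid of that ridge element (window coordinates) and
    ``principal_angle`` its principal direction; ``steps`` are the
    admissible lattice steps from the tip.
    """

    sigma1_unit: float
    target: np.ndarray
    principal_angle: float
    steps: list[tuple[int, int]]


def _evaluate_tip(
    mesh: PlateMesh, crack: CrackPath, load: LoadSpec
) -> _RidgeEval | None:
    """Solve at unit load and locate the failure ridge ahead of the tip.

    The crack is steered toward the element of maximum principal stress
    among *thin* elements (thickness below the groove threshold) lying
    forward of the tip (positive projection on the smoothed travel
    direction) within ``look_radius``.  Only forward material counts —
    never the already-traversed groove behind the tip — and looking a
    couple of pixels past the immediately adjacent elements rides over
    single-pixel rasterization corners of a curved groove, where the
    failing element sits diagonal to the tip.  Returns None when no thin
    forward material or no admissible step exists: the boundary groove is
    interrupted there.
    """
    steps = _candidate_edges(mesh, crack)
    if not steps:
        return None
    smesh = split_nodes(mesh, crack)
    forces = tip_loads(smesh, crack, 1.0, load.patch_radius)
    _, stress = fem.solve_elasticity(smesh, forces)
    s1, ang = fem.principal_stress(stress.sxx, stress.syy, stress.txy)

    i, j = crack.tip
    t = crack.travel_direction()
    tip_xy = np.array([j, i], float) * mesh.pixel_size

    h = mesh.thickness
    h_thr = h.min() + load.gap_thickness_frac * (h.max() - h.min())

    rr, cc = np.meshgrid(np.arange(mesh.rows), np.arange(mesh.cols), indexing="ij")
    cent_x = (cc.ravel() + 0.5) * mesh.pixel_size
    cent_y = (rr.ravel() + 0.5) * mesh.pixel_size
    dx = cent_x - tip_xy[0]
    dy = cent_y - tip_xy[1]
    proj = dx * t[0] + dy * t[1]
    dist = np.hypot(dx, dy)
    forward = (
        (proj > 0.1 * mesh.pixel_size)
        & (dist <= load.look_radius * mesh.pixel_size)
        & (h <= h_thr)
    )
    if not forward.any():
        return None
    fidx = np.flatnonzero(forward)
    best = fidx[np.argmax(s1[fidx])]
    s_best = float(s1[best])
    if s_best <= 0:
        return None  # forward thin material entirely in compression
    # steer toward the stress-weighted center of the failing neighborhood
    # rather than the single argmax element: the weighted centroid traces
    # the groove centerline smoothly where rasterization makes the argmax
    # hop between adjacent elements
    heavy = fidx[s1[fidx] >= 0.6 * s_best]
    w = s1[heavy] ** 2
    if w.sum() <= 0:
        target = np.array([cent_x[best], cent_y[best]])
    else:
        target = np.array(
            [float(np.average(cent_x[heavy], weights=w)), float(np.average(cent_y[heavy], weights=w))]
        )
    return _RidgeEval(s_best, target, float(ang[best]), steps)


def _onset_load(sigma1_unit: float, material: MaterialParams, step: float, cap: float) -> float:
    """First ramp level at which the scaled stress reaches the threshold.

    Stress is exactly linear in the load, so the continuous onset is
    sigma_max / sigma1(unit); the ramp quantizes it up to a multiple of
    ramp_step.  Returns inf past the cap.
    """
    if sigma1_unit <= 0:
        return math.inf
    required = material.max_principal_stress / sigma1_unit
    quantized = math.ceil(required / step - 1e-12) * step
    return quantized if quantized <= cap + 1e-9 else math.inf


def _angle_score(step: tuple[int, int], principal_angle: float) -> float:
    """|cos| of the angle between the step and the opening-growth direction
    (perpendicular to the sigma1 eigenvector) of the ridge element."""
    d = np.array([step[1], step[0]], float)
    g = np.array([-math.sin(principal_angle), math.cos(principal_angle)])
    return abs(float(d @ g))


def _rank_steps(ev: _RidgeEval, crack: CrackPath, mesh: PlateMesh) -> list[tuple[int, int]]:
    """Rank the admissible lattice steps toward the failure ridge.

    Primary: smallest landing-node distance to the ridge element's
    centroid.  Ties go to the direction perpendicular to the ridge
    element's principal stress direction (the opening-growth direction of
    the failing material) and then to the previous travel direction,
    which also covers the isotropic-stress case where the principal
    direction is undefined.  When the ridge element lies diagonal to the
    tip both adjacent landings are equidistant and the choice of side is
    genuinely ambiguous at lattice resolution; the full ranking is kept so
    the propagation loop can revisit the decision if the leader later
    stalls.
    """
    i, j = crack.tip
    t = crack.tip_direction

    def landing_distance(s: tuple[int, int]) -> float:
        land = np.array([j + s[1], i + s[0]], float) * mesh.pixel_size
        return float(np.linalg.norm(ev.target - land))

    def prev_score(s: tuple[int, int]) -> float:
        return s[1] * t[0] + s[0] * t[1]

    return sorted(
        ev.steps,
        key=lambda s: (
            -round(landing_distance(s), 6),
            round(_angle_score(s, ev.principal_angle), 6),
            prev_score(s),
        ),
        reverse=True,
    )


def propagate_crack(
    mesh: PlateMesh,
    seed: list[tuple[int, int]] | CrackPath,
    material: MaterialParams | None = None,
    load: LoadSpec | None = None,
    max_length: int | None = None,
) -> CrackPath:
    """Grow a crack from the seed until it leaves the window or stalls.

    Loop: split nodes along the current path, apply the tip-local force
    couple, ramp the load linearly (via one unit solve and linearity) and,
    once the maximum principal stress on the forward ridge reaches the
    material threshold, extend one mesh edge toward that ridge; repeat.
    Stops when the tip reaches the window border, the path exceeds
    ``max_length`` edges (default 4L), or the ramp cap is hit without
    extension — in which case forced bridging steps try to cross a groove
    gap, and if that fails the loop backtracks to the most recent
    genuinely ambiguous side choice (a ridge element diagonal to the tip)
    and takes the other branch before declaring the front stalled.
    """
    material = material or mesh.material
    load = load or LoadSpec()
    verts = list(seed.grid_vertices) if isinstance(seed, CrackPath) else list(seed)
    validate_crack(mesh, verts)
    if max_length is None:
        max_length = 2 * max(mesh.rows, mesh.cols)  # = 4L for a (2L+1) window

    crack = CrackPath(grid_vertices=verts)
    cap = load.ramp_cap if load.ramp_cap is not None else math.inf
    step = load.ramp_step
    # one entry per vertex appended after the seed: the ranked alternatives
    # not taken at that decision (empty for forced/bridged vertices)
    alt_stack: list[list[tuple[int, int]]] = []
    backtracks_left = load.max_backtracks

    def at_border(v: tuple[int, int]) -> bool:
        return v[0] in (0, mesh.rows) or v[1] in (0, mesh.cols)

    def sync_stack() -> None:
        while len(alt_stack) < len(crack.onset_loads):
            alt_stack.append([])

    def pop_vertices(n: int) -> None:
        del crack.grid_vertices[-n:]
        del crack.onset_loads[-n:]
        del alt_stack[-n:]
        kept = len(crack.grid_vertices)
        crack.bridged_steps[:] = [b for b in crack.bridged_steps if b < kept - 1]

    def backtrack() -> bool:
        """Rewind to the nearest decision with an untried alternative and
        take it as a forced step; the stall told us the leading branch
        chose the wrong side of the groove."""
        nonlocal backtracks_left
        if backtracks_left <= 0:
            return False
        for depth in range(1, min(load.backtrack_window, len(alt_stack)) + 1):
            if alt_stack[-depth]:
                alts = alt_stack[-depth]
                tip_before = crack.grid_vertices[-depth - 1]
                pop_vertices(depth)
                di, dj = alts.pop(0)
                assert crack.tip == tip_before
                crack.grid_vertices.append((tip_before[0] + di, tip_before[1] + dj))
                crack.onset_loads.append(math.nan)
                alt_stack.append(alts)
                backtracks_left -= 1
                return True
        return False

    while not at_border(crack.tip) and len(crack) <= max_length:
        ridge = _evaluate_tip(mesh, crack, load)
        if ridge is not None:
            if step is None:
                # quantize the whole ramp on the first extension's level
                step = material.max_principal_stress / ridge.sigma1_unit / 10.0
            onset = _onset_load(ridge.sigma1_unit, material, step, cap)
        else:
            onset = math.inf
        if math.isfinite(onset):
            ranked = _rank_steps(ridge, crack, mesh)
            di, dj = ranked[0]
            i, j = crack.tip
            alts = _near_tie_alternatives(ranked, ridge, (i, j), mesh)
            crack.grid_vertices.append((i + di, j + dj))
            crack.onset_loads.append(onset)
            alt_stack.append(alts)
            continue
        if step is None:
            # no thin material ahead of the seed at all
            crack.stalled = True
            break
        if _bridge_gap(mesh, crack, material, load, step, cap, at_border):
            sync_stack()
            continue
        if backtrack():
            continue
        crack.stalled = True
        break

    crack.ramp_cap_used = cap if math.isfinite(cap) else None
    crack.ramp_step_used = step
    return crack


def _near_tie_alternatives(
    ranked: list[tuple[int, int]],
    ridge: _RidgeEval,
    tip: tuple[int, int],
    mesh: PlateMesh,
) -> list[tuple[int, int]]:
    """Runner-up steps whose landing is nearly as close to the ridge.

    Only genuinely ambiguous side choices are kept (landing distance
    within one pixel of the winner): these arise when the ridge element is
    diagonal to the tip and either side of it is a defensible crack path.
    """

    def landing_distance(s: tuple[int, int]) -> float:
        land = np.array([tip[1] + s[1], tip[0] + s[0]], float) * mesh.pixel_size
        return float(np.linalg.norm(ridge.target - land))

    best = landing_distance(ranked[0])
    return [s for s in ranked[1:] if landing_distance(s) <= best + 1.0 + 1e-9]


def _bridge_gap(mesh, crack, material, load, step, cap, at_border) -> bool:
    """Probe forced extensions across a groove interruption.

    Two recovery modes, tried in order:

    1. Straight continuation, up to ``gap_max`` forced steps: a short
       boundary gap is crossed straight ahead, carried by the concentrated
       stress at the tip.
    2. A single lateral step: at a concave staircase corner of a
       rasterized curved groove the failing element sits diagonal to the
       tip, flanked by no candidate edge; one sideways step re-exposes it.

    After each forced step the onset criterion is re-checked: the probe
    resumes normal growth as soon as thin (groove) material reappears
    ahead of the tip within the ramp cap.  Probes that do not resume are
    rolled back; if nothing resumes the front stalls.
    """

    def push(nxt) -> None:
        crack.grid_vertices.append(nxt)
        crack.onset_loads.append(math.nan)
        crack.bridged_steps.append(len(crack.grid_vertices) - 2)

    def pop(n: int = 1) -> None:
        del crack.grid_vertices[-n:]
        del crack.onset_loads[-n:]
        del crack.bridged_steps[-n:]

    def resumed() -> bool:
        ridge = _evaluate_tip(mesh, crack, load)
        if ridge is None:
            return False
        return math.isfinite(_onset_load(ridge.sigma1_unit, material, step, cap))

    def straight_step() -> tuple[int, int] | None:
        t = crack.travel_direction()
        steps = _candidate_edges(mesh, crack)
        if not steps:
            return None
        best = max(steps, key=lambda s: s[1] * t[0] + s[0] * t[1])
        if best[1] * t[0] + best[0] * t[1] <= 0:
            return None
        return best

    # mode 1: straight across the gap
    pushed = 0
    for _ in range(load.gap_max):
        s = straight_step()
        if s is None:
            break
        i, j = crack.tip
        nxt = (i + s[0], j + s[1])
        push(nxt)
        pushed += 1
        if at_border(nxt) or resumed():
            return True
    if pushed:
        pop(pushed)

    # mode 2: one lateral step around a staircase corner
    t = crack.travel_direction()
    laterals = sorted(
        _candidate_edges(mesh, crack),
        key=lambda s: -(s[1] * t[0] + s[0] * t[1]),
    )
    straight = straight_step()
    for s in laterals:
        if s == straight:
            continue
        i, j = crack.tip
        nxt = (i + s[0], j + s[1])
        push(nxt)
        if at_border(nxt) or resumed():
            return True
        pop()
    return False


def groove_depth_stress_curve(
    depths: list[float],
    H: float = 10.0,
    size: tuple[int, int] = (21, 21),
    total_force: float = 1.0,
    material: MaterialParams | None = None,
) -> list[float]:
    """Maximum principal stress vs groove depth at fixed transverse load.

    Builds plates of uniform height H with a centered straight groove of
    each given depth (element height H - depth along the middle row), pulls
    them uniformly perpendicular to the groove, and reports the maximum
    principal stress.  The deeper the groove, the thinner its elements and
    the greater the stress concentration, so the curve increases.
    """
    from .plate_model import build_mesh

    material = material or MaterialParams()
    out = []
    for depth in depths:
        if not 0 <= depth < H:
            raise ValueError(f"groove depth must be in [0, H), got {depth}")
        h = np.full(size, float(H))
        h[size[0] // 2, :] = H - depth
        mesh = build_mesh(h, material)
        forces, fixed_dofs = fem.uniform_edge_tension(mesh, total_force, axis="y")
        _, stress = fem.solve_elasticity(mesh, forces, fixed_dofs=fixed_dofs)
        out.append(float(stress.sigma1.max()))
    return out
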