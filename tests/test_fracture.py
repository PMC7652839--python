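"""Discrete crack growth: node splitting, groove following, gaps, stalls."""

import numpy as np
import pytest

from crackseg import (
    LoadSpec,
    MaterialParams,
    build_mesh,
    gen_groove_plate,
    groove_depth_stress_curve,
    propagate_crack,
    split_nodes,
)
from crackseg.fem import solve_elasticity
from crackseg.fracture import CrackError, tip_loads

from conftest import polyline_distances, smooth_polyline

H = 20.0


def straight_groove_mesh(material, gap_cols=(), size=31):
    h = np.full((size, size), H)
    h[size // 2, :] = 1.0
    for c in gap_cols:
        h[size // 2, c] = H
    return build_mesh(h, material)


class TestSplitNodes:
    def test_interior_vertices_duplicated(self, material):
        mesh = build_mesh(np.ones((10, 10)), material)
        crack = [(5, 2), (5, 3), (5, 4), (5, 5), (5, 6), (5, 7)]
        split = split_nodes(mesh, crack)
        assert split.n_nodes == mesh.n_nodes + 4  # endpoints stay shared

    def test_seed_only_leaves_mesh_unchanged(self, material):
        mesh = build_mesh(np.ones((10, 10)), material)
        split = split_nodes(mesh, [(5, 4), (5, 5)])
        assert split.n_nodes == mesh.n_nodes

    def test_opening_load_separates_crack_faces(self, material):
        """Opposite tip-local forces must pull duplicated node pairs apart:
        positive relative normal displacement across the crack."""
        mesh = build_mesh(np.full((15, 15), 2.0), material)
        crack_verts = [(7, 3), (7, 4), (7, 5), (7, 6), (7, 7), (7, 8)]
        split = split_nodes(mesh, crack_verts)
        from crackseg.fracture import CrackPath

        crack = CrackPath(grid_vertices=list(crack_verts))
        forces = tip_loads(split, crack, 1e6, patch_radius=3.0)
        u, _ = solve_elasticity(split, forces)
        for orig in range(mesh.n_nodes, split.n_nodes):
            # duplicated node: find its partner at the same coordinates
            same = np.flatnonzero(
                (split.node_xy == split.node_xy[orig]).all(axis=1)
            )
            assert len(same) == 2
            gap = abs(u[same[0], 1] - u[same[1], 1])
            assert gap > 0.0

    def test_nonadjacent_vertices_rejected(self, material):
        mesh = build_mesh(np.ones((10, 10)), material)
        with pytest.raises(CrackError):
            split_nodes(mesh, [(5, 2), (5, 4)])

    def test_self_intersection_rejected(self, material):
        mesh = build_mesh(np.ones((10, 10)), material)
        with pytest.raises(CrackError):
            split_nodes(mesh, [(5, 2), (5, 3), (5, 2)])


class TestPropagateCrack:
    def test_straight_groove_followed_exactly(self, material):
        mesh = straight_groove_mesh(material)
        crack = propagate_crack(mesh, [(15, 13), (15, 14), (15, 15)])
        assert not crack.stalled
        rows = {v[0] for v in crack.grid_vertices}
        assert rows <= {15, 16}  # both faces of the groove row are on it
        assert crack.tip[1] in (0, 31)

    def test_quarter_arc_groove_followed(self, material):
        """Crack traces a quarter-circle groove; mean distance of the
        smoothed trace to the analytic arc stays below one pixel."""
        h, center = gen_groove_plate(H, H - 1, path="quarter-arc", size=31, arc_radius=20.0)
        mesh = build_mesh(h, material)
        crack = propagate_crack(mesh, [(0, 20), (1, 20), (2, 20)])
        assert not crack.stalled
        vs = np.array(crack.grid_vertices, float)
        d = polyline_distances(smooth_polyline(vs), center)
        assert d.mean() <= 1.0
        # the crack crossed the full quadrant
        assert crack.tip[1] <= 2 or crack.tip[0] >= 18

    def test_short_gap_is_penetrated(self, material):
        mesh = straight_groove_mesh(material, gap_cols=(15, 16, 17))
        crack = propagate_crack(mesh, [(15, 5), (15, 6), (15, 7)])
        assert not crack.stalled
        assert crack.tip[1] == 31  # crossed the gap and left the window
        assert len(crack.bridged_steps) >= 1

    def test_wide_blank_stalls_the_front(self, material):
        h = np.full((31, 31), H)
        h[15, :15] = 1.0
        mesh = build_mesh(h, material)
        crack = propagate_crack(mesh, [(15, 5), (15, 6), (15, 7)])
        assert crack.stalled
        tip = np.array(crack.tip, float)
        assert np.linalg.norm(tip - [15, 14]) <= 4.0  # stops near the groove end

    def test_uniform_plate_with_low_cap_stalls_unchanged(self, material):
        mesh = build_mesh(np.full((31, 31), H), material)
        seed = [(15, 5), (15, 6), (15, 7)]
        crack = propagate_crack(
            mesh, seed, load=LoadSpec(ramp_cap=1e-9, gap_max=0, max_backtracks=0)
        )
        assert crack.stalled
        assert crack.grid_vertices == seed

    def test_random_spline_grooves_tracked(self, material):
        """Randomized smooth grooves: the smoothed crack trace keeps at
        least 95% of its vertices within one pixel of the centerline."""
        fracs = []
        for k in range(6):
            h, center = gen_groove_plate(H, H - 1, path="spline", size=31, seed=k)
            mesh = build_mesh(h, material)
            y1 = int(round(center[np.argmin(np.abs(center[:, 1] - 1.0)), 0]))
            y3 = int(round(center[np.argmin(np.abs(center[:, 1] - 3.0)), 0]))
            seed = [(y1, 1), (y1, 2)]
            yy = y1
            while yy != y3:
                yy += 1 if y3 > yy else -1
                seed.append((yy, 2))
            seed.append((y3, 3))
            crack = propagate_crack(mesh, seed)
            vs = np.array(crack.grid_vertices, float)
            d = polyline_distances(smooth_polyline(vs), center)
            fracs.append(float((d <= 1.0).mean()))
        assert np.mean(fracs) >= 0.95

    def test_onset_load_matches_linearity(self, material):
        """The ramp's detected onset equals threshold / sigma1(unit load),
        up to one ramp step (stress is exactly linear in the load)."""
        mesh = straight_groove_mesh(material)
        crack = propagate_crack(mesh, [(15, 13), (15, 14), (15, 15)])
        onsets = [o for o in crack.onset_loads if np.isfinite(o)]
        assert len(onsets) > 5
        step = crack.ramp_step_used
        assert step is not None
        for o in onsets:
            ratio = o / step
            assert abs(ratio - round(ratio)) < 1e-6


class TestGrooveDepthCurve:
    def test_deeper_grooves_concentrate_more_stress(self):
        curve = groove_depth_stress_curve([2.0, 4.0, 6.0, 8.0], H=10.0)
        assert all(a < b for a, b in zip(curve, curve[1:]))

    def test_no_groove_recovers_far_field(self, material):
        (flat,) = groove_depth_stress_curve([0.0], H=10.0, total_force=1.0)
        # uniform plate: sigma = F / (width * thickness)
        expected = 1.0 / (21.0 * 10.0)
        assert flat == pytest.approx(expected, rel=1e-6)

    def test_repeatable(self):
        a = groove_depth_stress_curve([3.0, 6.0], H=10.0)
        b = groove_depth_stress_curve([3.0, 6.0], H=10.0)
        assert a == b

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            groove_depth_stress_curve([10.0], H=10.0)


class TestStressConcentrationLocus:
    def test_max_stress_sits_in_the_groove(self, material):
        """Transverse tension on a grooved plate concentrates the maximum
        principal stress inside the groove row."""
        from crackseg.fem import principal_stress, uniform_edge_tension

        h = np.full((21, 21), 10.0)
        h[10, :] = 2.0
        mesh = build_mesh(h, material)
        forces, fixed = uniform_edge_tension(mesh, 1.0, axis="y")
        _, s = solve_elasticity(mesh, forces, fixed_dofs=fixed)
        s1, _ = principal_stress(s.sxx, s.syy, s.txy)
        r, c = divmod(int(np.argmax(s1)), 21)
        assert r == 10
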