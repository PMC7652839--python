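"""Driver: coordinate plumbing, center updates, merging, end-to-end runs."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crackseg import (
    LcpmConfig,
    PhantomSpec,
    crack_to_boundary,
    dice,
    fit_boundary_direction,
    gen_phantom,
    hausdorff,
    mask_boundary,
    merge_and_smooth,
    next_center,
    run_lcpm,
)
from crackseg.fracture import CrackPath
from crackseg.lcpm import LcpmConfigError, LcpmError, LocalBoundary

from conftest import boundary_seed


class TestCrackToBoundary:
    def test_node_to_global_translation(self):
        # window with top-left pixel (40, 40): node (i, j) -> (39.5+i, 39.5+j)
        crack = CrackPath(grid_vertices=[(10, 15), (10, 16)])
        lb = crack_to_boundary(crack, origin=(40, 40))
        # node (i, j) sits at the pixel corner (origin - 0.5) + (i, j)
        assert np.allclose(lb.points[0], [49.5, 54.5])
        assert np.allclose(lb.points[1], [49.5, 55.5])

    def test_zero_origin_is_identity_up_to_half_pixel(self):
        crack = CrackPath(grid_vertices=[(3, 4), (3, 5)])
        lb = crack_to_boundary(crack, origin=(0, 0))
        assert np.allclose(lb.points, [[2.5, 3.5], [2.5, 4.5]])

    def test_empty_crack_rejected(self):
        with pytest.raises(LcpmError):
            crack_to_boundary(CrackPath(grid_vertices=[]), origin=(0, 0))


class TestFitBoundaryDirection:
    def test_diagonal_line(self):
        pts = np.array([[i, i] for i in range(8)], float)
        assert fit_boundary_direction(pts) == pytest.approx(np.pi / 4)

    def test_vertical_line_handled(self):
        pts = np.array([[i, 3.0] for i in range(8)])
        assert fit_boundary_direction(pts) == pytest.approx(np.pi / 2)

    def test_noisy_horizontal_line(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(0, 0.3, 20), np.arange(20.0)])
        theta = fit_boundary_direction(pts)
        assert abs(np.degrees(theta)) < 5.0

    def test_coincident_points_rejected(self):
        with pytest.raises(LcpmError):
            fit_boundary_direction(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestNextCenter:
    def test_step_along_positive_x(self):
        c = next_center((50.0, 50.0), theta=0.0, alpha=8.0, prev_step=np.array([0.0, 1.0]))
        assert c == pytest.approx((50.0, 58.0))

    def test_sign_resolved_by_previous_step(self):
        c = next_center((50.0, 50.0), theta=0.0, alpha=8.0, prev_step=np.array([0.0, -1.0]))
        assert c == pytest.approx((50.0, 42.0))

    @given(
        st.floats(-np.pi / 2 + 1e-3, np.pi / 2),
        st.floats(0.5, 25.0),
        st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_step_length_is_exactly_alpha(self, theta, alpha, prev_angle):
        prev = np.array([np.sin(prev_angle), np.cos(prev_angle)])
        c = next_center((10.0, 20.0), theta, alpha, prev)
        d = np.hypot(c[0] - 10.0, c[1] - 20.0)
        assert d == pytest.approx(alpha, rel=1e-12)


class TestMergeAndSmooth:
    def test_overlap_points_deduplicated(self):
        a = LocalBoundary(points=np.array([[0.0, i] for i in range(0, 16, 2)]), window_index=0)
        b = LocalBoundary(points=np.array([[0.0, i] for i in range(12, 28, 2)]), window_index=1)
        contour = merge_and_smooth([a, b], closed=False, smooth_window=1)
        cols = contour.points[:, 1]
        # the overlapping run (12, 14) appears once, order is preserved
        assert len(cols) == len(set(cols.tolist()))
        assert np.all(np.diff(cols) > 0)
        assert cols.max() == 26.0

    def test_open_contour_endpoints_preserved(self):
        rng = np.random.default_rng(1)
        pts = np.cumsum(rng.random((30, 2)), axis=0)
        frag = LocalBoundary(points=pts, window_index=0)
        contour = merge_and_smooth([frag], closed=False, smooth_window=5)
        assert np.allclose(contour.points[0], pts[0])
        assert np.allclose(contour.points[-1], pts[-1])

    def test_closed_contour_is_counterclockwise(self):
        th = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([10 + 5 * np.sin(th), 10 + 5 * np.cos(th)])[::-1]
        frag = LocalBoundary(points=pts, window_index=0)
        contour = merge_and_smooth([frag], closed=True)
        x, y = contour.points[:, 1], contour.points[:, 0]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area > 0

    def test_two_fronts_joined_across_a_jump(self):
        a = LocalBoundary(points=np.array([[0.0, i] for i in range(0, 10, 2)]), window_index=0)
        b = LocalBoundary(
            points=np.array([[0.0, 14.0 + i] for i in range(0, 10, 2)]), window_index=1,
            bridge_before=True,
        )
        contour = merge_and_smooth([a, b], closed=False, smooth_window=1)
        # both fronts survive in order; the 6-px jump is a straight bridge
        assert len(contour.points) == 10
        assert contour.points[0][1] == 0.0 and contour.points[-1][1] == 22.0


class TestConfig:
    def test_alpha_range_enforced(self):
        with pytest.raises(LcpmConfigError):
            LcpmConfig(L=15, alpha=30.0)
        with pytest.raises(LcpmConfigError):
            LcpmConfig(L=15, alpha=0.0)


class TestRunLcpm:
    def test_clean_disk_closes_accurately(self, disk_phantom):
        seed, bp = boundary_seed(disk_phantom)
        res = run_lcpm(
            disk_phantom.image, first_center=(int(bp[0]), int(bp[1])), seed_points=seed
        )
        assert res.contour.closed
        assert dice(res.mask, disk_phantom.mask) >= 0.97
        assert hausdorff(mask_boundary(res.mask), mask_boundary(disk_phantom.mask)) <= 3.0

    def test_window_overlap_invariant(self, disk_phantom):
        """Every consecutive window pair overlaps: each fragment starts
        within reach of its predecessor's end (the inherited seed)."""
        seed, bp = boundary_seed(disk_phantom)
        res = run_lcpm(
            disk_phantom.image, first_center=(int(bp[0]), int(bp[1])), seed_points=seed
        )
        frags = res.fragments
        assert len(frags) >= 5
        for prev, nxt in zip(frags, frags[1:]):
            if not len(nxt.points) or not len(prev.points):
                continue
            gap = np.linalg.norm(nxt.points[0] - prev.points[-1])
            assert gap <= 2.0

    def test_gap_phantom_closes_across_the_gap(self):
        ph = gen_phantom(PhantomSpec(shape="disk", gaps=((0.0, 10.0),)))
        seed, bp = boundary_seed(ph)
        res = run_lcpm(ph.image, first_center=(int(bp[0]), int(bp[1])), seed_points=seed)
        assert res.contour.closed
        assert dice(res.mask, ph.mask) >= 0.95

    def test_noisy_inhomogeneous_ellipse(self):
        ph = gen_phantom(
            PhantomSpec(
                shape="ellipse", intensity="ramp", noise_sigma=0.03,
                axis_ratio=0.75, angle_deg=-20.0, seed=1,
            )
        )
        seed, bp = boundary_seed(ph)
        res = run_lcpm(ph.image, first_center=(int(bp[0]), int(bp[1])), seed_points=seed)
        assert res.contour.closed
        assert dice(res.mask, ph.mask) >= 0.95

    def test_identical_runs_identical_contours(self, disk_phantom):
        seed, bp = boundary_seed(disk_phantom)
        r1 = run_lcpm(disk_phantom.image, (int(bp[0]), int(bp[1])), seed_points=seed)
        r2 = run_lcpm(disk_phantom.image, (int(bp[0]), int(bp[1])), seed_points=seed)
        assert r1.contour.to_json() == r2.contour.to_json()
        assert np.array_equal(r1.mask, r2.mask)

    def test_blank_first_window_rejected(self):
        img = np.full((64, 64), 0.5)
        with pytest.raises(LcpmError):
            run_lcpm(img, first_center=(32, 32), seed_points=np.array([[30.0, 30.0], [30.0, 33.0]]))


class TestContourJson:
    def test_roundtrip_fields(self, disk_phantom):
        seed, bp = boundary_seed(disk_phantom)
        res = run_lcpm(disk_phantom.image, (int(bp[0]), int(bp[1])), seed_points=seed)
        payload = json.loads(res.contour.to_json(config_echo={"window": {"L": 15}}))
        assert payload["closed"] is True
        assert payload["config"]["window"]["L"] == 15
        assert len(payload["points"]) == len(res.contour.points)
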