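"""Phantom generator: determinism, ground truth, gap and noise semantics."""

import numpy as np
import pytest

from crackseg import PhantomSpec, gen_groove_plate, gen_noise, gen_phantom
from crackseg.image_transform import gaussian_gradient
from crackseg.synthetic import PhantomSpecError, preset


class TestGenPhantom:
    def test_disk_mask_area_matches_circle(self):
        ph = gen_phantom(PhantomSpec(shape="disk", radius=30.0, size=128))
        area = ph.mask.sum()
        assert area == pytest.approx(np.pi * 30.0**2, rel=0.01)

    def test_same_spec_same_seed_bit_identical(self):
        spec = PhantomSpec(shape="blob", noise_sigma=0.03, seed=5)
        a = gen_phantom(spec)
        b = gen_phantom(spec)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.mask, b.mask)

    def test_different_seeds_differ(self):
        a = gen_phantom(PhantomSpec(shape="blob", seed=1))
        b = gen_phantom(PhantomSpec(shape="blob", seed=2))
        assert not np.array_equal(a.image.pixels, b.image.pixels)

    def test_truth_mask_untouched_by_noise_and_gaps(self):
        clean = gen_phantom(PhantomSpec(shape="ellipse", seed=4))
        dirty = gen_phantom(
            PhantomSpec(shape="ellipse", seed=4, noise_sigma=0.05, gaps=((30.0, 15.0),))
        )
        assert np.array_equal(clean.mask, dirty.mask)
        assert np.array_equal(clean.boundary, dirty.boundary)

    def test_gap_erases_local_gradient(self):
        """Within the gap arc the boundary contrast vanishes: the gradient
        there drops below 5% of the ungapped arc's mean."""
        base = PhantomSpec(shape="disk", radius=30.0, size=128)
        gapped = PhantomSpec(shape="disk", radius=30.0, size=128, gaps=((0.0, 20.0),))
        g0 = gaussian_gradient(gen_phantom(base).image, 1.0).pixels
        g1 = gaussian_gradient(gen_phantom(gapped).image, 1.0).pixels
        cy = cx = (128 - 1) / 2.0
        th_gap = np.radians(np.linspace(-2.0, 2.0, 9))
        th_ref = np.radians(np.linspace(60.0, 120.0, 31))

        def ring_vals(g, thetas):
            rr = (cy + 30.0 * np.sin(thetas)).round().astype(int)
            cc = (cx + 30.0 * np.cos(thetas)).round().astype(int)
            return g[rr, cc]

        ref_mean = ring_vals(g0, th_ref).mean()
        assert ring_vals(g1, th_gap).max() <= 0.05 * ref_mean
        # away from the gap the two variants agree
        assert np.allclose(ring_vals(g0, th_ref), ring_vals(g1, th_ref))

    def test_gap_covering_whole_boundary_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(gaps=((0.0, 200.0), (180.0, 200.0)))

    def test_presets_exist_and_unknown_rejected(self):
        for name in ("fig4a", "fig4b", "fig4c", "fig4d", "fig4e", "fig3"):
            gen_phantom(preset(name, seed=1))
        with pytest.raises(PhantomSpecError):
            preset("fig99")

    def test_boundary_points_lie_on_mask_edge(self):
        ph = gen_phantom(PhantomSpec(shape="blob", seed=9))
        from crackseg import mask_boundary, hausdorff

        hd = hausdorff(ph.boundary, mask_boundary(ph.mask))
        assert hd <= 1.5  # rasterization only


class TestGrooveplate:
    def test_flat_straight_groove_hits_floor(self):
        h, center = gen_groove_plate(10.0, 9.0, path="straight", size=21, profile="flat")
        assert h.min() == pytest.approx(1.0)
        assert np.all(h[10, :] == 1.0)
        assert np.all(h[0, :] == 10.0)

    def test_quarter_arc_groove_near_analytic_arc(self):
        h, center = gen_groove_plate(10.0, 9.0, path="quarter-arc", size=31, profile="flat", arc_radius=20.0)
        groove_px = np.argwhere(h < 10.0)
        d = np.abs(np.hypot(groove_px[:, 1] + 0.5, groove_px[:, 0] + 0.5) - 20.0)
        assert d.max() <= 0.8

    def test_zero_depth_is_uniform(self):
        h, _ = gen_groove_plate(10.0, 0.0, path="straight", size=15)
        assert np.all(h == 10.0)

    def test_depth_out_of_range(self):
        with pytest.raises(ValueError):
            gen_groove_plate(10.0, 9.5, path="straight")

    def test_smooth_profile_floor_and_far_field(self):
        h, _ = gen_groove_plate(20.0, 19.0, path="straight", size=31)
        assert h.min() == pytest.approx(1.0)
        assert h[0, :].min() >= 19.9  # far from the groove the plate is full


class TestGenNoise:
    def test_zero_sigma_is_identity(self):
        img = np.random.default_rng(0).random((16, 16))
        assert np.array_equal(gen_noise(img, 0.0, seed=1), img)

    def test_sample_std_matches_sigma(self):
        img = np.full((128, 128), 0.5)
        noisy = gen_noise(img, 0.05, seed=2)
        assert 0.045 <= noisy.std() <= 0.055

    def test_two_seeds_differ_but_share_mean(self):
        img = np.full((128, 128), 0.5)
        a = gen_noise(img, 0.05, seed=1)
        b = gen_noise(img, 0.05, seed=2)
        assert not np.array_equal(a, b)
        se = 0.05 / np.sqrt(img.size)
        assert abs(a.mean() - b.mean()) <= 3 * np.sqrt(2) * se
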