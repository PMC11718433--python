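"""Shell morphometry, shape metrics and 2D descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pelletox as px
from pelletox.morpho3d import Mask2D, VoxelImage, shell_bin_volumes


def solid_ball(radius_um: float, voxel_size: float = 2.0,
               fill: float = 1.0, seed: int = 0) -> VoxelImage:
    """Voxelized ball, optionally randomly filled at a given density."""
    n = int(np.ceil(2 * radius_um / voxel_size)) + 5
    c = (n - 1) / 2.0
    z, y, x = np.ogrid[0:n, 0:n, 0:n]
    dist = np.sqrt((z - c)**2 + (y - c)**2 + (x - c)**2) * voxel_size
    ball = dist <= radius_um
    if fill < 1.0:
        rng = np.random.default_rng(seed)
        ball = ball & (rng.random(ball.shape) < fill)
    return VoxelImage(ball.astype(np.uint8), voxel_size)


def solid_ellipsoid(semi_axes, voxel_size: float = 2.0) -> VoxelImage:
    a, b, c_ax = semi_axes
    nz = int(np.ceil(2 * c_ax / voxel_size)) + 5
    ny = int(np.ceil(2 * b / voxel_size)) + 5
    nx = int(np.ceil(2 * a / voxel_size)) + 5
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    z, y, x = np.ogrid[0:nz, 0:ny, 0:nx]
    inside = (((z - cz) * voxel_size / c_ax)**2
              + ((y - cy) * voxel_size / b)**2
              + ((x - cx) * voxel_size / a)**2) <= 1.0
    return VoxelImage(inside.astype(np.uint8), voxel_size)


class TestOtsu:
    def test_two_level_image_separated_exactly(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((20, 20, 20)) < 0.4, 200, 10).astype(np.uint8)
        out = px.binarize_otsu(VoxelImage(img, 1.0))
        assert np.array_equal(out.voxels.astype(bool), img == 200)

    def test_idempotent_on_binary(self):
        rng = np.random.default_rng(1)
        binary = (rng.random((15, 15, 15)) < 0.3).astype(np.uint8)
        out = px.binarize_otsu(VoxelImage(binary, 1.0))
        assert np.array_equal(out.voxels.astype(bool), binary.astype(bool))

    def test_matches_brute_force_between_class_variance(self):
        # bimodal Gaussian mixture phantom vs exhaustive 256-level search
        rng = np.random.default_rng(2)
        lo = rng.normal(60, 12, 6000)
        hi = rng.normal(180, 15, 4000)
        img = np.clip(np.concatenate([lo, hi]), 0, 255).astype(np.uint8)
        img = img.reshape(10, 10, 100)

        vals = img.ravel().astype(float)
        best_t, best_var = 0, -1.0
        for t in range(256):
            w0 = vals <= t
            if w0.all() or not w0.any():
                continue
            p0 = w0.mean()
            var = p0 * (1 - p0) * (vals[w0].mean() - vals[~w0].mean())**2
            if var > best_var:
                best_var, best_t = var, t
        out = px.binarize_otsu(VoxelImage(img, 1.0))
        thr_implied = vals[~out.voxels.astype(bool).ravel()].max()
        assert abs(thr_implied - best_t) <= 5

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            px.binarize_otsu(VoxelImage(np.full((5, 5, 5), 7), 1.0))


class TestShellFractions:
    def test_solid_ball_interior_shells_full(self):
        img = solid_ball(200.0)
        shells = px.shell_hyphal_fraction(img)
        interior = shells.shell_outer_radii <= 180.0
        assert np.all(shells.fractions[interior] >= 0.99)

    def test_random_fill_recovered_within_binomial_error(self):
        img = solid_ball(200.0, fill=0.5, seed=3)
        shells = px.shell_hyphal_fraction(img)
        vox_vol = img.voxel_size**3
        interior = shells.shell_outer_radii <= 180.0
        n_per_shell = shell_bin_volumes(shells)[interior] / vox_vol
        sd = np.sqrt(0.25 / n_per_shell)
        assert np.all(np.abs(shells.fractions[interior] - 0.5) <= 3 * sd)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            px.shell_hyphal_fraction(VoxelImage(np.zeros((10, 10, 10)), 2.0))


class TestBorderFromFraction:
    def test_interpolated_crossing_by_hand(self):
        shells = px.ShellProfile([50.0, 65.0, 80.0], [0.2, 0.2, 0.004])
        # fractions anchored at shell mid-radii (57.5 and 72.5); the 0.005
        # crossing lies inside the third shell:
        # 57.5 + 15*(0.2-0.005)/(0.2-0.004)
        expected = 57.5 + 15.0 * 0.195 / 0.196
        assert px.border_from_fraction(shells) == pytest.approx(expected)
        assert 65.0 < px.border_from_fraction(shells) < 80.0

    def test_no_decline_border_is_last_edge(self):
        radii = 50.0 + 15.0 * np.arange(31)
        shells = px.ShellProfile(radii, np.full(31, 0.2))
        assert px.border_from_fraction(shells) == 500.0

    def test_cutoff_above_all_fractions_rejected(self):
        shells = px.ShellProfile([50.0, 65.0], [0.001, 0.002])
        with pytest.raises(ValueError):
            px.border_from_fraction(shells)


class TestTotalHyphalVolume:
    @pytest.mark.parametrize("ch,expected_factor", [(1.0, 1.0), (0.0, 0.0),
                                                    (0.5, 0.5)])
    def test_uniform_fraction_scales_solid_sphere(self, ch, expected_factor):
        radii = 50.0 + 15.0 * np.arange(31)      # out to 500 um
        shells = px.ShellProfile(radii, np.full(31, ch))
        solid = 4.0 / 3.0 * np.pi * 500.0**3
        assert px.total_hyphal_volume(shells) == pytest.approx(
            expected_factor * solid, rel=1e-12, abs=1e-6)


class TestShapeMetrics:
    def test_ball_classified_spherical(self):
        img = solid_ball(120.0)
        shells = px.shell_hyphal_fraction(img)
        m = px.shape_metrics_3d(img, shells)
        assert m.sphericity >= 0.95
        assert m.axis_ratio >= 0.95
        assert m.is_spherical

    def test_oblate_ellipsoid_axis_ratio_and_filter(self):
        img = solid_ellipsoid((200.0, 200.0, 100.0))
        shells = px.shell_hyphal_fraction(img)
        m = px.shape_metrics_3d(img, shells)
        assert m.axis_ratio == pytest.approx(0.5, abs=0.05)
        assert not m.is_spherical

    def test_sphericity_scale_invariant(self):
        m1 = px.shape_metrics_3d(solid_ball(60.0),
                                 px.shell_hyphal_fraction(solid_ball(60.0)))
        m2 = px.shape_metrics_3d(solid_ball(120.0),
                                 px.shell_hyphal_fraction(solid_ball(120.0)))
        assert m1.sphericity == pytest.approx(m2.sphericity, abs=0.02)

    def test_too_few_voxels_rejected(self):
        vox = np.zeros((5, 5, 5), dtype=np.uint8)
        vox[2, 2, 2] = 1
        shells = px.ShellProfile([50.0], [0.1])
        with pytest.raises(ValueError):
            px.shape_metrics_3d(VoxelImage(vox, 1.0), shells)


class TestDescriptors2D:
    def test_circle_closed_forms(self):
        mask = px.gen_2d_mask("circle", diameter=500.0)
        d = px.descriptors_2d(mask)
        assert d.aesd == pytest.approx(500.0, rel=0.01)
        assert d.solidity == pytest.approx(1.0, abs=0.01)
        assert d.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert d.mn == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        mask = px.gen_2d_mask("ellipse", axes=(200.0, 100.0))
        d = px.descriptors_2d(mask)
        assert d.aspect_ratio == pytest.approx(2.0, rel=0.05)
        assert d.mn < 1.0

    def test_single_pixel_degenerate(self):
        pix = np.zeros((5, 5), dtype=bool)
        pix[2, 2] = True
        d = px.descriptors_2d(Mask2D(pix, 1.0))
        assert d.area == 1.0
        assert d.solidity == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            px.descriptors_2d(Mask2D(np.zeros((5, 5), dtype=bool), 1.0))


class TestMorphologyNumber:
    def test_perfect_circle_scores_one(self):
        # substitute A = pi r^2, S = 1, feret = 2r, AR = 1
        d = px.Descriptors2D(area=np.pi * 250.0**2, solidity=1.0,
                             feret_diameter=500.0, aspect_ratio=1.0)
        assert d.mn == pytest.approx(1.0, rel=1e-12)

    def test_solidity_scaling(self):
        d1 = px.Descriptors2D(area=1000.0, solidity=0.8,
                              feret_diameter=40.0, aspect_ratio=1.2)
        d2 = px.Descriptors2D(area=1000.0, solidity=0.4,
                              feret_diameter=40.0, aspect_ratio=1.2)
        assert d2.mn == pytest.approx(d1.mn / np.sqrt(2), rel=1e-12)

    def test_scale_invariant_on_circle_phantoms(self):
        m1 = px.descriptors_2d(px.gen_2d_mask("circle", 200.0)).mn
        m2 = px.descriptors_2d(px.gen_2d_mask("circle", 400.0)).mn
        assert m1 == pytest.approx(m2, abs=0.02)

    def test_zero_feret_rejected(self):
        d = px.Descriptors2D(area=10.0, solidity=1.0, feret_diameter=4.0,
                             aspect_ratio=1.0)
        d.feret_diameter = 0.0
        with pytest.raises(ValueError):
            px.morphology_number(d)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(a=st.floats(60.0, 300.0), b=st.floats(60.0, 300.0))
    def test_convex_masks_never_exceed_one(self, a, b):
        d = px.descriptors_2d(px.gen_2d_mask("ellipse", axes=(a, b)))
        assert d.mn <= 1.0 + 0.02
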