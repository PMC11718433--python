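"""Oxygen profile processing, alignment, and supply metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pelletox as px
from pelletox.profiles import AlignedPellet, OxygenProfile


def declining_profile(border_depth=100.0, step=10.0, deep=400.0,
                      c_max=6.7, slope=0.08):
    """Plateau at c_max until border_depth, then linear decline (floored 0)."""
    depths = np.arange(0.0, deep + step / 2, step)
    c = np.where(depths <= border_depth, c_max,
                 np.maximum(c_max - slope * (depths - border_depth), 0.0))
    return OxygenProfile(depths, c[None, :])


def uniform_aligned(border=500.0, ch=0.2, zero_below=None, step=10.0):
    radii = np.arange(0.0, border + step / 2, step)
    c = np.full_like(radii, 6.0)
    if zero_below is not None:
        c[radii < zero_below] = 0.0
    n = int(round((border - 50.0) / 15.0))
    shells = px.ShellProfile(50.0 + 15.0 * np.arange(n + 1),
                             np.full(n + 1, ch))
    a = AlignedPellet(radii=radii, ch=np.full_like(radii, ch), c_o2=c,
                      c_max=6.7, border_radius=border, shells=shells)
    return a, shells


class TestMeanReplicateProfile:
    def test_identical_replicates_unchanged(self):
        depths = np.arange(0, 50, 10.0)
        c = np.tile(np.linspace(6.7, 1.0, 5), (3, 1))
        mean = px.mean_replicate_profile(OxygenProfile(depths, c))
        assert np.array_equal(mean.concentrations[0], c[0])
        assert mean.replicate_count == 3

    def test_pointwise_arithmetic_mean(self):
        depths = np.array([0.0, 10.0])
        p = OxygenProfile(depths, np.array([[0.0, 2.0], [0.0, 4.0]]))
        assert np.array_equal(px.mean_replicate_profile(p).concentrations[0],
                              [0.0, 3.0])

    def test_averaging_shrinks_noise_by_sqrt_n(self):
        rng = np.random.default_rng(0)
        depths = np.arange(0, 200, 10.0)
        sds = []
        for _ in range(300):
            c = 5.0 + rng.normal(0, 0.3, (3, depths.size))
            sds.append(px.mean_replicate_profile(
                OxygenProfile(depths, c)).concentrations[0].std())
        assert np.mean(sds) == pytest.approx(0.3 / np.sqrt(3), rel=0.1)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            OxygenProfile(np.array([0.0, 10.0, 25.0]), np.zeros((1, 3)))


class TestOxygenBorder:
    def test_crossing_interpolated_by_hand(self):
        p = declining_profile(border_depth=100.0, slope=0.08)
        depth, c_max = px.oxygen_border(p)
        assert c_max == 6.7
        # threshold 0.95*6.7 = 6.365; decline passes it 0.335/0.08 = 4.1875
        # um after the plateau ends, between the 100 and 110 um samples
        assert depth == pytest.approx(100.0 + 0.335 / 0.08)

    def test_frac_one_returns_argmax(self):
        p = declining_profile()
        depth, _ = px.oxygen_border(p, frac=1.0)
        assert depth == pytest.approx(100.0)

    def test_constant_profile_warns(self):
        depths = np.arange(0, 100, 10.0)
        p = OxygenProfile(depths, np.full((1, depths.size), 6.7))
        with pytest.warns(UserWarning):
            depth, c_max = px.oxygen_border(p)
        assert c_max == 6.7
        assert depth == depths[-1]


class TestAlign:
    def test_depth_to_radius_arithmetic(self):
        # oxygen border at depth 30, fraction border 480:
        # depth 130 must map to radius 380
        # decline tuned so the sample at depth 30 reads exactly 0.95*c_max
        p = declining_profile(border_depth=20.0, slope=0.0335, deep=300.0)
        d_border, _ = px.oxygen_border(p)
        assert d_border == pytest.approx(30.0)
        radii = np.append(50.0 + 15.0 * np.arange(29), 480.0)
        shells = px.ShellProfile(radii, np.full(radii.size, 0.2))
        a = px.align(p, shells)
        assert a.border_radius == 480.0
        # depth 130 maps to radius 480 - (130 - 30) = 380
        assert np.min(np.abs(a.radii - 380.0)) < 1e-9
        # fixed point: the border-depth sample sits at the border radius
        assert np.min(np.abs(a.radii - 480.0)) < 1e-9

    def test_round_trip_preserves_border_and_concentrations(self,
                                                            truth_params):
        spec, _ = px.preset("regular", seed=7, noise_sd=0.0)
        shells = px.gen_radial_hyphal_fraction(spec)
        prof = px.gen_oxygen_profile(shells, truth_params, spec)
        a = px.align(px.mean_replicate_profile(prof), shells)
        assert a.border_radius == pytest.approx(spec.pellet_radius, abs=10.0)
        # alignment maps depths to radii without touching concentrations
        assert np.allclose(np.sort(a.c_o2),
                           np.sort(prof.concentrations[0][
                               prof.concentrations.shape[1] - a.radii.size:]),
                           atol=1e-12)

    def test_too_few_inside_samples_rejected(self):
        depths = np.array([0.0, 10.0, 20.0])
        p = OxygenProfile(depths, np.array([[6.7, 6.7, 6.6]]))
        shells = px.ShellProfile([50.0, 65.0], [0.2, 0.2])
        with pytest.raises(ValueError):
            px.align(p, shells)


class TestMaxCentralGradient:
    def test_linear_series_exact(self):
        v = 3.0 * np.arange(10)
        assert px.max_central_gradient(v, 1.0) == pytest.approx(3.0)

    def test_hand_computed_example(self):
        assert px.max_central_gradient(np.array([0.0, 1.0, 4.0, 9.0]),
                                       1.0) == pytest.approx(4.0)

    def test_quadratic_exact_at_interior_nodes(self):
        x = np.arange(0.0, 10.0)
        v = x**2
        # central differences are exact for quadratics: max at x=8 -> 16
        assert px.max_central_gradient(v, 1.0) == pytest.approx(16.0)

    def test_window_restriction(self):
        x = np.arange(0.0, 10.0)
        assert px.max_central_gradient(x**2, 1.0, window=(0.0, 4.0),
                                       positions=x) == pytest.approx(8.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            px.max_central_gradient(np.array([1.0, 2.0]), 1.0)


class TestPenetrationDepth:
    def test_sharp_front_arithmetic(self):
        a, _ = uniform_aligned(border=500.0, zero_below=300.0)
        # crossing interpolated between the 290 (0) and 300 (6.0) samples
        d = px.penetration_depth(a)
        r0 = 290.0 + 10.0 * (0.05 - 0.0) / 6.0
        assert d == pytest.approx(500.0 - r0)

    def test_fully_oxygenated_equals_border(self):
        a, _ = uniform_aligned()
        assert px.penetration_depth(a) == 500.0

    def test_anoxic_everywhere_warns_zero(self):
        a, _ = uniform_aligned()
        a.c_o2[:] = 0.0
        with pytest.warns(UserWarning):
            assert px.penetration_depth(a) == 0.0

    def test_monotone_nonincreasing_in_threshold(self, truth_params):
        spec, _ = px.preset("regular", seed=13)
        shells = px.gen_radial_hyphal_fraction(spec)
        a, _ = px.gen_aligned_pellet(shells, truth_params, spec)
        depths = [px.penetration_depth(a, zero_threshold=t)
                  for t in (0.02, 0.05, 0.1, 0.5, 1.0)]
        assert np.all(np.diff(depths) <= 1e-9)

    def test_preset_depths_in_reported_range(self):
        # strain-typical synthetic pellets with the literature parameter
        # set: supplied layer 90-290 um
        for name, seed in (("regular", 1), ("hyperbranching", 2)):
            spec, params = px.preset(name, seed=seed)
            shells = px.gen_radial_hyphal_fraction(spec)
            a, _ = px.gen_aligned_pellet(shells, params, spec)
            d = px.penetration_depth(a)
            assert 90.0 <= d <= 290.0


class TestActivePartPercentage:
    def test_uniform_fraction_closed_form(self):
        a, shells = uniform_aligned(border=500.0)
        app = px.active_part_percentage(a, shells, 200.0)
        assert app == pytest.approx(100.0 * (1 - (300.0 / 500.0)**3),
                                    rel=0.01)

    def test_full_depth_is_hundred_percent(self):
        a, shells = uniform_aligned()
        assert px.active_part_percentage(a, shells, 500.0) == \
            pytest.approx(100.0)

    def test_zero_depth_is_zero(self):
        a, shells = uniform_aligned()
        assert px.active_part_percentage(a, shells, 0.0) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(d1=st.floats(0.0, 500.0), d2=st.floats(0.0, 500.0))
    def test_monotone_in_depth_and_matches_closed_form(self, d1, d2):
        a, shells = uniform_aligned(border=500.0)
        lo, hi = sorted((d1, d2))
        app_lo = px.active_part_percentage(a, shells, lo)
        app_hi = px.active_part_percentage(a, shells, hi)
        assert app_lo <= app_hi + 1e-9
        closed = 100.0 * (1 - ((500.0 - hi) / 500.0)**3)
        assert app_hi == pytest.approx(closed, abs=1.0)
        assert 0.0 <= app_hi <= 100.0
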