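import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mumri import (
    GeometryError,
    ParameterWarning,
    Phantom,
    canonical_fixtures,
    firing_probability,
    make_territory,
    plan_coarse_schedule,
    plan_fine_schedule,
    simulate_series,
)
from mumri.morphometry import component_gap, compute_csa, compute_feret

VOXEL = (1.5, 1.5)


class TestFiringProbability:
    def test_midpoint_is_exactly_half(self):
        assert firing_probability(10.0, 10.0, 0.05) == 0.5
        assert firing_probability(10.0, 10.0, 0.0) == 0.5  # step convention

    def test_saturation(self):
        assert firing_probability(1e6, 10.0, 0.05) == 1.0
        assert firing_probability(0.0, 10.0, 0.001) == pytest.approx(0.0)

    def test_zero_width_is_step(self):
        assert firing_probability(10.01, 10.0, 0.0) == 1.0
        assert firing_probability(9.99, 10.0, 0.0) == 0.0

    @given(
        st.floats(0.0, 30.0),
        st.floats(0.0, 30.0),
        st.floats(5.0, 15.0),
        st.floats(0.0, 0.5),
    )
    def test_monotone_in_current(self, c1, c2, thr, width):
        lo, hi = sorted([c1, c2])
        assert firing_probability(lo, thr, width) <= firing_probability(hi, thr, width)

    def test_empirical_frequency_matches_probability(self):
        # hold one current, many repeats: firing frequency ~ Binomial(p)
        sched = plan_fine_schedule(10.0, 0.01, 400, 1)
        labels = np.zeros((12, 12), int)
        labels[2:10, 2:10] = 1
        from mumri import MuscleMask

        unit = make_territory(
            "circular", (5.5, 5.5), {"radius_mm": 3.0}, (12, 12), VOXEL,
            threshold_mA=9.98, firing_width_mA=0.02,
        )
        phantom = Phantom(MuscleMask(labels, {1: "TA"}), [unit], 100.0, 0.0, VOXEL)
        _, fired = simulate_series(phantom, sched, seed=7)
        p = firing_probability(10.0, 9.98, 0.02)
        freq = fired[0].mean()
        # 4 sigma binomial band
        assert abs(freq - p) < 4 * np.sqrt(p * (1 - p) / 400)


class TestMakeTerritory:
    def test_ellipse_area_converges_to_analytic(self):
        analytic = np.pi * 5.0 * 2.0  # 10 x 4 mm axes
        errs = {}
        for h in (1.5, 0.25):
            g = int(30 / h)
            u = make_territory(
                "ellipse", (g / 2 - 0.5, g / 2 - 0.5),
                {"axes_mm": (10.0, 4.0), "angle_deg": 30.0}, (g, g), (h, h),
            )
            errs[h] = abs(compute_csa(u.territory, (h, h)) - analytic)
        assert errs[1.5] / analytic < 0.2  # acquisition grid: bounded error
        assert errs[0.25] / analytic < 0.02  # refined grid: converged

    def test_circular_is_nearly_isotropic(self):
        # voxel-centred placement: symmetric odd-diameter rasterisation
        u = make_territory("circular", (11, 11), {"radius_mm": 4.5}, (24, 24), VOXEL)
        fmax, fmin = compute_feret(u.territory, VOXEL)
        assert fmax / fmin < 1.2

    def test_split_gap_rounds_to_request(self):
        u = make_territory(
            "split", (11.5, 11.5), {"radius_mm": 2.4, "gap_mm": 4.3}, (24, 32), VOXEL
        )
        gap = component_gap(u.territory, VOXEL)
        assert abs(gap - 4.3) <= 0.75  # half a voxel

    def test_spider_has_core_and_arms(self):
        u = make_territory(
            "spider", (15.5, 15.5),
            {"core_mm": 2.2, "arm_length_mm": 9.0, "n_arms": 4, "arm_width_mm": 1.8},
            (32, 32), VOXEL,
        )
        from mumri.morphometry import solidity

        assert solidity(u.territory, VOXEL) < 0.6

    def test_shape_exceeding_grid_rejected(self):
        with pytest.raises(GeometryError):
            make_territory("circular", (3.5, 3.5), {"radius_mm": 20.0}, (8, 8), VOXEL)


class TestSimulateSeries:
    def test_no_units_zero_noise_is_constant_baseline(self, rect_mask):
        mask = rect_mask((16, 16))
        phantom = Phantom(mask, [], 100.0, 0.0, VOXEL)
        sched = plan_fine_schedule(10.0, 0.01, 5, 4)
        series, fired = simulate_series(phantom, sched, seed=0)
        assert fired.shape == (0, 20)
        inside = series.pixels[mask.foreground]
        assert np.all(inside == 100.0)
        assert np.all(series.pixels[~mask.foreground] == 0.0)

    def test_void_depth_is_exact_without_noise(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.0, threshold=5.0)
        sched = plan_fine_schedule(10.0, 0.01, 5, 4)  # far above threshold
        series, fired = simulate_series(phantom, sched, seed=1)
        assert fired.all()
        inside = series.pixels[unit.territory]
        outside = series.pixels[phantom.mask.foreground & ~unit.void_region()]
        assert np.all(inside == 100.0 * unit.void_fraction)
        assert np.all(outside == 100.0)

    def test_same_seed_is_bit_identical(self, single_unit_phantom):
        phantom, _ = single_unit_phantom()
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        s1, f1 = simulate_series(phantom, sched, seed=11)
        s2, f2 = simulate_series(phantom, sched, seed=11)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(f1, f2)

    def test_coupling_dilation_widens_the_void(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(
            noise_sigma=0.0, threshold=5.0, coupling_dilation_vox=1
        )
        sched = plan_fine_schedule(10.0, 0.01, 1, 1)
        series, _ = simulate_series(phantom, sched, seed=0)
        halo = unit.void_region() & ~unit.territory
        assert halo.any()
        assert np.all(series.pixels[halo] == 100.0 * unit.void_fraction)


class TestSchedulePlanners:
    def test_coarse_ramp_matches_protocol(self):
        sched = plan_coarse_schedule(8.0, 0.1, 60)
        assert sched.n_dynamics == 60
        assert sched.current_mA[0] == pytest.approx(8.0)
        assert sched.current_mA[-1] == pytest.approx(13.9)
        assert np.allclose(np.diff(sched.current_mA), 0.1)

    def test_single_dynamic_ramp(self):
        sched = plan_coarse_schedule(8.0, 0.25, 1)
        assert sched.n_dynamics == 1

    def test_step_outside_range_warns(self):
        with pytest.warns(ParameterWarning):
            plan_coarse_schedule(8.0, 0.05, 10)

    def test_fine_staircase_matches_protocol(self):
        sched = plan_fine_schedule(12.0, 0.01, 5, 216)
        assert sched.n_dynamics == 1080
        assert sched.current_mA[0] == pytest.approx(12.0)
        assert sched.current_mA[-1] == pytest.approx(9.85)
        counts = np.bincount(sched.level_index)
        assert np.all(counts == 5)

    def test_five_fold_larger_step_gives_one_fifth_dynamics(self):
        fine = plan_fine_schedule(12.0, 0.01, 5, 215)
        quick = plan_fine_schedule(12.0, 0.05, 5, 43)
        assert quick.n_dynamics * 5 == fine.n_dynamics
        assert quick.current_mA[-1] == pytest.approx(fine.current_mA[-1] + 0.04)

    def test_repeats_one_is_a_plain_ramp(self):
        sched = plan_fine_schedule(12.0, 0.01, 1, 10)
        assert sched.n_dynamics == 10
        assert np.all(np.diff(sched.current_mA) < 0)

    def test_non_positive_current_rejected(self):
        with pytest.raises(ValueError):
            plan_fine_schedule(1.0, 0.01, 5, 200)


def test_canonical_fixtures_cover_all_classes():
    fixtures = canonical_fixtures()
    classes = [u.shape_class for u in fixtures]
    assert len(fixtures) == 15
    for cls in ("ellipse", "crescent", "circular", "spider", "split"):
        assert classes.count(cls) == 3
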