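import numpy as np
import pytest

from mumri import (
    DynamicSeries,
    FiringVector,
    NoActivityError,
    NoAlternationError,
    alternation_stats,
    build_difference_map,
    cluster_into_units,
    detect_candidate_voxels,
    extract_units,
    group_frames,
    plan_fine_schedule,
    simulate_series,
    threshold_map,
    threshold_sweep,
    voxel_firing_vectors,
)
from mumri.extract import EXCLUDED, FIRED, NOT_FIRED, _two_means_rows

VOXEL = (1.5, 1.5)


def truth_vector(fired_row):
    return FiringVector(np.where(fired_row, FIRED, NOT_FIRED))


class TestTwoMeans:
    def test_recovers_a_known_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(40, 3, 30), rng.normal(100, 3, 70)])
        rng.shuffle(x)
        split = _two_means_rows(x)
        assert split["n_low"] == 30
        assert 40 < split["midpoint"] < 100
        assert split["separation"] > 10

    def test_perfect_split_has_infinite_separation(self):
        split = _two_means_rows(np.array([1.0, 1.0, 5.0, 5.0]))
        assert np.isinf(split["separation"])
        assert split["midpoint"] == pytest.approx(3.0)


class TestCandidateDetection:
    def test_zero_noise_candidates_equal_planted_territory(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.0)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=2)
        cand = detect_candidate_voxels(series, phantom.mask, sched)
        np.testing.assert_array_equal(cand, unit.territory)

    def test_default_noise_candidates_cover_territory(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.03)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=3)
        cand = detect_candidate_voxels(series, phantom.mask, sched)
        overlap = (cand & unit.territory).sum() / unit.territory.sum()
        assert overlap >= 0.8
        assert not (cand & ~unit.void_region()).any()


class TestGroupFrames:
    def test_zero_noise_recovers_ground_truth_exactly(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.0)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, fired = simulate_series(phantom, sched, seed=4)
        firing = group_frames(series, unit.territory, sched)
        np.testing.assert_array_equal(firing.states == FIRED, fired[0])

    def test_noisy_agreement_above_99_percent(self, single_unit_phantom):
        agree = total = 0
        for seed in range(10):
            phantom, unit = single_unit_phantom(noise_sigma=0.03)
            sched = plan_fine_schedule(10.1, 0.01, 5, 20)
            series, fired = simulate_series(phantom, sched, seed=seed)
            firing = group_frames(series, unit.territory, sched)
            agree += ((firing.states == FIRED) == fired[0]).sum()
            total += fired[0].size
        assert agree / total >= 0.99

    def test_region_that_never_fires_signals_no_alternation(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.03, threshold=50.0)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=5)
        with pytest.raises(NoAlternationError):
            group_frames(series, unit.territory, sched)

    def test_window_marks_outside_dynamics_excluded(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.0)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=6)
        firing = group_frames(series, unit.territory, sched, window=(10, 90))
        assert np.all(firing.states[:10] == EXCLUDED)
        assert np.all(firing.states[90:] == EXCLUDED)
        assert np.all(firing.states[10:90] != EXCLUDED)


class TestClusterIntoUnits:
    def test_identical_vectors_share_a_group(self):
        coords = np.array([[1, 1], [1, 2], [5, 5], [5, 6]])
        v = np.zeros((4, 20), bool)
        v[:2, :10] = True  # unit one fires early
        v[2:, 10:] = True  # unit two fires late
        groups = cluster_into_units(coords, v, min_unit_voxels=2)
        assert len(groups) == 2
        assert sorted(len(g) for g in groups) == [2, 2]

    def test_two_planted_units_give_two_groups(self, rect_mask):
        from mumri import Phantom, make_territory

        grid = (32, 32)
        mask = rect_mask(grid)
        a = make_territory("circular", (9, 9), {"radius_mm": 3.0}, grid, VOXEL,
                           threshold_mA=10.0, firing_width_mA=0.02)
        b = make_territory("circular", (22, 22), {"radius_mm": 3.0}, grid, VOXEL,
                           threshold_mA=10.3, firing_width_mA=0.02)
        phantom = Phantom(mask, [a, b], 100.0, 0.03, VOXEL)
        sched = plan_fine_schedule(10.45, 0.01, 5, 70)
        series, _ = simulate_series(phantom, sched, seed=8)
        cand = detect_candidate_voxels(series, mask, sched)
        coords, vecs = voxel_firing_vectors(series, cand)
        groups = cluster_into_units(coords, vecs)
        assert len(groups) == 2
        masks = []
        for g in groups:
            m = np.zeros(grid, bool)
            m[g[:, 0], g[:, 1]] = True
            masks.append(m)
        # each group matches exactly one planted unit
        matches = {
            i: max(range(2), key=lambda j: (masks[i] & [a, b][j].territory).sum())
            for i in range(2)
        }
        assert set(matches.values()) == {0, 1}


class TestDifferenceMap:
    def test_constructed_void_gives_expected_depths(self):
        pixels = np.full((8, 8, 6), 100.0)
        territory = np.zeros((8, 8), bool)
        territory[2:5, 2:5] = True
        fired_dyn = [1, 3, 5]
        for t in fired_dyn:
            pixels[territory, t] = 30.0
        series = DynamicSeries(pixels, VOXEL)
        states = np.where(np.isin(np.arange(6), fired_dyn), FIRED, NOT_FIRED)
        diff = build_difference_map(series, FiringVector(states))
        assert np.all(diff[territory] == 70.0)
        assert np.all(diff[~territory] == 0.0)

    def test_identical_groups_give_zero_map(self):
        series = DynamicSeries(np.full((6, 6, 4), 50.0), VOXEL)
        states = np.array([FIRED, NOT_FIRED, FIRED, NOT_FIRED])
        assert np.all(build_difference_map(series, FiringVector(states)) == 0.0)

    def test_linearity_under_intensity_scaling(self):
        rng = np.random.default_rng(0)
        pixels = rng.random((8, 8, 10)) * 100
        states = np.array([FIRED] * 5 + [NOT_FIRED] * 5)
        d1 = build_difference_map(DynamicSeries(pixels, VOXEL), FiringVector(states))
        d2 = build_difference_map(DynamicSeries(2.5 * pixels, VOXEL), FiringVector(states))
        np.testing.assert_allclose(d2, 2.5 * d1)

    def test_empty_group_is_an_error(self):
        series = DynamicSeries(np.full((6, 6, 4), 50.0), VOXEL)
        with pytest.raises(ValueError):
            build_difference_map(series, FiringVector([FIRED] * 4))


class TestThresholdMap:
    def test_half_threshold_keeps_voxels_at_or_above_half_max(self):
        m = np.zeros((8, 8))
        m[2, 2] = 200.0
        m[3, 3] = 120.0
        m[4, 4] = 99.0
        normalized, terr = threshold_map(m, 0.5, min_unit_voxels=1)
        assert normalized[2, 2] == 1.0
        assert terr[2, 2] and terr[3, 3] and not terr[4, 4]

    def test_fraction_one_keeps_only_argmax(self):
        rng = np.random.default_rng(0)
        m = rng.random((8, 8))
        _, terr = threshold_map(m, 1.0, min_unit_voxels=1)
        assert terr.sum() == 1
        assert terr[np.unravel_index(np.argmax(m), m.shape)]

    def test_uniform_positive_map_keeps_everything(self):
        _, terr = threshold_map(np.full((6, 6), 5.0), 0.5, min_unit_voxels=1)
        assert terr.all()

    def test_negative_map_signals_no_activity(self):
        with pytest.raises(NoActivityError):
            threshold_map(-np.ones((6, 6)), 0.5)

    def test_territories_shrink_monotonically_with_fraction(self):
        rng = np.random.default_rng(1)
        m = rng.random((16, 16)) * 100
        prev = None
        for f in (0.2, 0.4, 0.6, 0.8, 1.0):
            _, terr = threshold_map(m, f, min_unit_voxels=1)
            if prev is not None:
                assert np.all(terr <= prev)  # set inclusion
            prev = terr

    def test_small_components_dropped(self):
        m = np.zeros((12, 12))
        m[2:5, 2:5] = 100.0  # 9-voxel component
        m[9, 9] = 100.0  # single stray voxel
        _, terr = threshold_map(m, 0.5, min_unit_voxels=3)
        assert terr[3, 3] and not terr[9, 9]


class TestThresholdSweep:
    def test_csa_non_increasing_and_matches_threshold_map(self):
        rng = np.random.default_rng(2)
        m = rng.random((16, 16)) * 100
        table = threshold_sweep(m, [0.3, 0.5, 0.7], VOXEL, min_unit_voxels=1)
        assert np.all(np.diff(table["csa_mm2"]) <= 0)
        _, terr = threshold_map(m, 0.5, min_unit_voxels=1)
        row = table[table["fraction"] == 0.5].iloc[0]
        assert row["n_voxels"] == terr.sum()


class TestAlternationStats:
    def make_firing(self, sched, fired_fraction_per_level):
        states = np.full(sched.n_dynamics, NOT_FIRED, np.int8)
        for lev, frac in fired_fraction_per_level.items():
            dyn = sched.dynamics_of_level(lev)
            n = int(round(frac * dyn.size))
            states[dyn[:n]] = FIRED
        return FiringVector(states)

    def test_constructed_mixed_zone_gives_direct_count_range(self):
        # staircase 5.40 down to 5.01; mixed outcomes only at 5.10..5.30
        sched = plan_fine_schedule(5.40, 0.01, 5, 40)
        currents = sched.level_currents()
        frac = {}
        for lev, cur in zip(sched.level_ids(), currents):
            if cur > 5.30 + 1e-9:
                frac[lev] = 1.0
            elif cur >= 5.10 - 1e-9:
                frac[lev] = 0.6  # 3 of 5: mixed
            else:
                frac[lev] = 0.0
        firing = self.make_firing(sched, frac)
        stats = alternation_stats(firing, sched)
        assert stats.alternation_range_mA == pytest.approx(0.20)
        assert stats.activation_threshold_mA == pytest.approx(5.10)
        assert not stats.right_censored

    def test_deterministic_unit_has_zero_range(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.0, width=0.0)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, fired = simulate_series(phantom, sched, seed=9)
        stats = alternation_stats(truth_vector(fired[0]), sched)
        assert stats.alternation_range_mA <= 0.01 + 1e-9

    def test_always_firing_unit_is_right_censored(self):
        sched = plan_fine_schedule(5.10, 0.01, 5, 10)
        stats = alternation_stats(FiringVector([FIRED] * 50), sched)
        assert stats.right_censored

    def test_never_firing_unit_is_an_error(self):
        sched = plan_fine_schedule(5.10, 0.01, 5, 10)
        with pytest.raises(ValueError):
            alternation_stats(FiringVector([NOT_FIRED] * 50), sched)

    def test_near_zero_width_threshold_matches_planted_midpoint(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.03, width=0.003)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=10)
        firing = group_frames(series, unit.territory, sched)
        stats = alternation_stats(firing, sched)
        assert abs(stats.activation_threshold_mA - 10.0) <= 0.02


class TestExtractUnits:
    def test_single_unit_end_to_end(self, single_unit_phantom):
        phantom, unit = single_unit_phantom(noise_sigma=0.03)
        sched = plan_fine_schedule(10.1, 0.01, 5, 20)
        series, _ = simulate_series(phantom, sched, seed=12)
        dets = extract_units(series, phantom.mask, sched)
        assert len(dets) == 1
        np.testing.assert_array_equal(dets[0].territory, unit.territory)
        assert dets[0].normalized_map.max() == 1.0
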