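"""Simulation studies that quantify how well the pipeline recovers known
ground truth from phantoms, plus brute-force geometric cross-checks.

Each study fixes its own conditions (grid, noise, firing model parameters)
at the package defaults for the standard protocols — fine staircases at
0.01 mA x 5 repeats, coarse ramps at 0.1 mA, Rician noise at 3% of baseline
(2% for the coarse ramp study) — and reports recovery statistics.  They are
used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import coarse as co
from . import extract as ex
from . import morphometry as morph
from . import phantom as ph
from .errors import AnalysisSignal
from .io import MuscleMask

VOXEL = (1.5, 1.5)
VOXEL_AREA = VOXEL[0] * VOXEL[1]


# ---------------------------------------------------------------------------
# Brute-force Feret oracle (independent of the rotating-calipers code path)


def feret_projection_sweep(
    points: np.ndarray, coarse_step_deg: float = 0.1, refine_rounds: int = 4
) -> tuple[float, float]:
    """Max/min Feret diameter by exhaustive projection sweep.

    Projects the point cloud onto directions on a 0.1 degree base grid and
    takes the extremal projection extents, then refines the grid locally
    around each optimum (the width function of a polygon has kinked minima,
    so pure grid sweeps converge only linearly).  Uses no convex-hull or
    caliper machinery.
    """
    pts = np.asarray(points, dtype=float)

    def extent(thetas: np.ndarray) -> np.ndarray:
        d = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        proj = pts @ d.T
        return proj.max(axis=0) - proj.min(axis=0)

    thetas = np.deg2rad(np.arange(0.0, 180.0, coarse_step_deg))
    w = extent(thetas)
    t_hi, t_lo = thetas[np.argmax(w)], thetas[np.argmin(w)]
    w_hi, w_lo = float(w.max()), float(w.min())
    step = np.deg2rad(coarse_step_deg)
    offsets = np.arange(-50, 51)
    for _ in range(refine_rounds):
        step /= 50.0
        local = t_hi + offsets * step
        wl = extent(local)
        i = int(np.argmax(wl))
        t_hi, w_hi = local[i], max(w_hi, float(wl[i]))
        local = t_lo + offsets * step
        wl = extent(local)
        i = int(np.argmin(wl))
        t_lo, w_lo = local[i], min(w_lo, float(wl[i]))
    return w_hi, w_lo


def feret_oracle_deviation(n_masks: int = 200, seed: int = 0) -> dict:
    """Max absolute deviation (mm) between the caliper Feret implementation
    and the projection-sweep oracle over random binary masks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_masks):
        mask = rng.random((12, 12)) < 0.35
        if not mask.any():
            mask[6, 6] = True
        fmax, fmin = morph.compute_feret(mask, VOXEL)
        pts = morph.voxel_corner_points(mask, VOXEL)
        omax, omin = feret_projection_sweep(pts)
        worst = max(worst, abs(fmax - omax), abs(fmin - omin))
    return {"max_abs_deviation_mm": worst, "n": n_masks}


# ---------------------------------------------------------------------------
# Shared phantom helpers


def _rect_mask(grid: tuple[int, int], margin: int = 2, name: str = "TA") -> MuscleMask:
    labels = np.zeros(grid, dtype=int)
    labels[margin : grid[0] - margin, margin : grid[1] - margin] = 1
    return MuscleMask(labels, {1: name})


def _truth_firing(fired_row: np.ndarray) -> ex.FiringVector:
    return ex.FiringVector(np.where(fired_row, ex.FIRED, ex.NOT_FIRED))


# ---------------------------------------------------------------------------
# Morphometric recovery (fine-grain, planted ellipses)


def morphometric_recovery(n_runs: int = 50, seed: int = 0) -> dict:
    """Recovery of CSA and Feret dimensions of planted elliptical units.

    Conditions: 48x48 grid, 1.5 mm voxels, coupling dilation 0, Rician noise
    3% of baseline, fine staircase through the unit threshold.  Success:
    recovered CSA within 3 voxel areas (6.75 mm^2) and both Feret dimensions
    within one voxel (1.5 mm) of the planted territory.
    """
    rng = np.random.default_rng(seed)
    grid = (48, 48)
    mask = _rect_mask(grid)
    schedule = ph.plan_fine_schedule(10.15, 0.01, 5, 30)
    n_ok = 0
    csa_err, fmax_err, fmin_err, detected = [], [], [], 0
    for _ in range(n_runs):
        major = rng.uniform(8.0, 16.0)
        minor = rng.uniform(4.0, 7.0)
        angle = rng.uniform(0.0, 180.0)
        unit = ph.make_territory(
            "ellipse",
            (23.5 + rng.uniform(-2, 2), 23.5 + rng.uniform(-2, 2)),
            {"axes_mm": (major, minor), "angle_deg": angle},
            grid,
            VOXEL,
            threshold_mA=10.0,
            firing_width_mA=0.02,
        )
        phantom = ph.Phantom(mask, [unit], 100.0, 0.03, VOXEL)
        series, _ = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
        dets = ex.extract_units(series, mask, schedule)
        best, best_iou = None, 0.0
        for det in dets:
            inter = np.logical_and(det.territory, unit.territory).sum()
            union = np.logical_or(det.territory, unit.territory).sum()
            if union and inter / union > best_iou:
                best, best_iou = det, inter / union
        if best is None:
            csa_err.append(np.nan)
            fmax_err.append(np.nan)
            fmin_err.append(np.nan)
            continue
        detected += 1
        pm = morph.measure_unit(unit.territory, VOXEL)
        dm = morph.measure_unit(best.territory, VOXEL)
        ce = dm.csa_mm2 - pm.csa_mm2
        fe = dm.feret_max_mm - pm.feret_max_mm
        me = dm.feret_min_mm - pm.feret_min_mm
        csa_err.append(ce)
        fmax_err.append(fe)
        fmin_err.append(me)
        if abs(ce) <= 3 * VOXEL_AREA and abs(fe) <= VOXEL[0] and abs(me) <= VOXEL[0]:
            n_ok += 1
    return {
        "success_rate": n_ok / n_runs,
        "detected": detected,
        "mean_abs_csa_error_mm2": float(np.nanmean(np.abs(csa_err))),
        "mean_abs_feret_max_error_mm": float(np.nanmean(np.abs(fmax_err))),
        "mean_abs_feret_min_error_mm": float(np.nanmean(np.abs(fmin_err))),
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# Alternation recovery (range vs planted width; threshold recovery)


def alternation_recovery(n_runs: int = 100, seed: int = 0) -> dict:
    """Alternation range vs planted logistic width, and activation-threshold
    measurement error.

    One circular unit per run, logistic width swept over 0.002-0.05 mA,
    staircase at 0.01 mA x 5 repeats spanning the alternation zone.  The
    firing vector recovered from the image data is compared with the
    ground-truth firing draws: both are reduced with the same alternation
    statistics, so the threshold error isolates frame-grouping mistakes.
    """
    rng = np.random.default_rng(seed)
    grid = (32, 32)
    mask = _rect_mask(grid, margin=1)
    schedule = ph.plan_fine_schedule(10.30, 0.01, 5, 60)
    widths = np.linspace(0.002, 0.05, n_runs)
    ranges, thr_errs = [], []
    for w in widths:
        unit = ph.make_territory(
            "circular",
            (15.5, 15.5),
            {"radius_mm": 3.0},
            grid,
            VOXEL,
            threshold_mA=10.0,
            firing_width_mA=float(w),
        )
        phantom = ph.Phantom(mask, [unit], 100.0, 0.03, VOXEL)
        series, fired = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
        firing = ex.group_frames(series, unit.territory, schedule)
        est = ex.alternation_stats(firing, schedule)
        truth = ex.alternation_stats(_truth_firing(fired[0]), schedule)
        ranges.append(est.alternation_range_mA)
        thr_errs.append(abs(est.activation_threshold_mA - truth.activation_threshold_mA))
    r = float(np.corrcoef(widths, ranges)[0, 1])
    return {
        "range_width_pearson_r": r,
        "max_threshold_error_mA": float(np.max(thr_errs)),
        "mean_range_mA": float(np.mean(ranges)),
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# Co-firing discrimination (same unit vs different units)


def cofire_discrimination(n_runs: int = 50, seed: int = 0) -> dict:
    """r-squared between voxels of one planted unit vs across two units with
    different thresholds; reports the fraction of runs where same-unit
    correlation wins, and the mean r-squared of each kind."""
    rng = np.random.default_rng(seed)
    grid = (32, 32)
    mask = _rect_mask(grid, margin=1)
    schedule = ph.plan_fine_schedule(10.45, 0.01, 5, 70)
    unit_a = ph.make_territory(
        "circular", (9, 9), {"radius_mm": 3.0}, grid, VOXEL,
        threshold_mA=10.0, firing_width_mA=0.03,
    )
    unit_b = ph.make_territory(
        "circular", (22, 22), {"radius_mm": 3.0}, grid, VOXEL,
        threshold_mA=10.3, firing_width_mA=0.03,
    )
    wins = 0
    same, cross = [], []
    for _ in range(n_runs):
        phantom = ph.Phantom(mask, [unit_a, unit_b], 100.0, 0.03, VOXEL)
        series, _ = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
        r2_same = morph.cofire_r2(series, (9, 9), (9, 10))
        r2_cross = morph.cofire_r2(series, (9, 9), (22, 22))
        same.append(r2_same)
        cross.append(r2_cross)
        wins += r2_same > r2_cross
    return {
        "discrimination_rate": wins / n_runs,
        "mean_same_unit_r2": float(np.mean(same)),
        "mean_cross_unit_r2": float(np.mean(cross)),
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# Shape classification on canonical fixtures


def shape_classification(noise_sigma: float = 0.0, seed: int = 0) -> dict:
    """Classification accuracy on the 15 canonical fixtures.

    With ``noise_sigma`` 0 the planted territory is classified directly.
    Otherwise each fixture is planted in a phantom, a short fine-grain scan
    is simulated at that Rician noise level, the territory is recovered via
    frame grouping + difference map + 0.5 thresholding, and the recovered
    territory is classified.
    """
    grid = (48, 48)
    fixtures = ph.canonical_fixtures(grid, VOXEL)
    mask = _rect_mask(grid, margin=1)
    schedule = ph.plan_fine_schedule(10.15, 0.01, 5, 25)
    rng = np.random.default_rng(seed)
    n_ok = 0
    for fixture in fixtures:
        territory = fixture.territory
        if noise_sigma > 0:
            unit = ph.UnitTerritory(
                fixture.shape_class, fixture.territory,
                threshold_mA=10.0, firing_width_mA=0.02,
            )
            phantom = ph.Phantom(mask, [unit], 100.0, noise_sigma, VOXEL)
            series, _ = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
            try:
                firing = ex.group_frames(series, unit.territory, schedule)
                diff = ex.build_difference_map(series, firing, mask)
                _, territory = ex.threshold_map(diff, 0.5, mask)
            except AnalysisSignal:
                continue
        if morph.classify_shape(territory, VOXEL) == fixture.shape_class:
            n_ok += 1
    return {"accuracy": n_ok / len(fixtures), "n": len(fixtures)}


# ---------------------------------------------------------------------------
# False-positive control (pure noise)


def false_positive_control(n_runs: int = 50, seed: int = 0) -> dict:
    """Fraction of pure-noise fine-grain series yielding zero detected units."""
    rng = np.random.default_rng(seed)
    grid = (48, 48)
    mask = _rect_mask(grid)
    schedule = ph.plan_fine_schedule(10.15, 0.01, 5, 30)
    clean = 0
    for _ in range(n_runs):
        phantom = ph.Phantom(mask, [], 100.0, 0.03, VOXEL)
        series, _ = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
        dets = ex.extract_units(series, mask, schedule)
        clean += len(dets) == 0
    return {"zero_unit_rate": clean / n_runs, "n": n_runs}


# ---------------------------------------------------------------------------
# Coarse-ramp inflection recovery


def inflection_recovery(n_runs: int = 100, seed: int = 0) -> dict:
    """Recovery of the planted first-activation current on a coarse ramp.

    A pool of 18 small units with thresholds 10.2, 10.3, ..., 11.9 mA (the
    progressive-recruitment picture behind a smooth recruitment curve) is
    stimulated along a 0.1 mA ramp from 8.0 mA, 40 dynamics, ending while
    recruitment is still in progress (the protocol stops once contrast is
    clear), at noise sigma 2% of baseline.  Success is a detected inflection
    within one ramp step of the lowest planted threshold, 10.2 mA.
    """
    rng = np.random.default_rng(seed)
    grid = (28, 28)
    mask = _rect_mask(grid)
    schedule = ph.plan_coarse_schedule(8.0, 0.1, 40)
    centers = [(4 + 6 * (k // 5) + (k % 2), 3 + 5 * (k % 5)) for k in range(18)]
    units = [
        ph.make_territory(
            "circular", c, {"radius_mm": 1.7}, grid, VOXEL,
            threshold_mA=10.2 + 0.1 * k, firing_width_mA=0.05,
        )
        for k, c in enumerate(centers)
    ]
    hits = 0
    for _ in range(n_runs):
        phantom = ph.Phantom(mask, units, 100.0, 0.02, VOXEL)
        series, _ = ph.simulate_series(phantom, schedule, int(rng.integers(2**31)))
        profile = co.roi_profile(series, mask, 1, schedule)
        try:
            inflection = co.detect_inflection(profile)
        except AnalysisSignal:
            continue
        if abs(inflection - 10.2) <= 0.1 + 1e-9:
            hits += 1
    return {"within_one_level_rate": hits / n_runs, "n": n_runs}
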