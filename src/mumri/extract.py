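"""Motor unit extraction from fine-grain series.

The fine-grain staircase holds each current for five repeats while stepping
down in 0.01 mA increments; near its activation threshold a unit fires
probabilistically in an all-or-none fashion, so a spatially consistent
region flickers between baseline and void intensity (alternation).  The
extraction chain automates the published manual analysis:

1. :func:`detect_candidate_voxels` — voxels whose intensity trace is
   bimodal (two-means split with a separation criterion) and whose low
   (void) state recurs often enough.
2. :func:`cluster_into_units` — candidates grouped by co-firing: binary
   firing vectors whose pairwise r-squared exceeds a criterion are linked,
   connected groups are putative units.
3. :func:`group_frames` — frames grouped into fired / not-fired from the
   two-means split of the seed-region mean trace.
4. :func:`build_difference_map` — mean(not fired) - mean(fired).
5. :func:`threshold_map` — normalise to the map maximum and keep voxels at
   or above a fraction (0.5 by default) of it.
6. :func:`alternation_stats` — activation threshold and alternation current
   range from the firing vector and the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .errors import NoActivityError, NoAlternationError
from .io import DynamicSeries, MuscleMask, StimulationSchedule

FIRED = 1
NOT_FIRED = 0
EXCLUDED = -1

#: Default analysis parameters (all overridable per call).
DEFAULT_SEPARATION = 4.0  # two-means cluster separation, in pooled within-SD
DEFAULT_COFIRE_R2 = 0.6
DEFAULT_MIN_EVENTS = 3
DEFAULT_MIN_UNIT_VOXELS = 3
DEFAULT_THRESHOLD_FRACTION = 0.5


@dataclass
class FiringVector:
    """Per-dynamic firing state of one unit: fired / not fired / excluded."""

    states: np.ndarray
    unit_id: int | str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, [FIRED, NOT_FIRED, EXCLUDED]).all():
            raise ValueError("states must be FIRED, NOT_FIRED or EXCLUDED")

    @property
    def n_dynamics(self) -> int:
        return int(self.states.size)

    @property
    def fired(self) -> np.ndarray:
        return np.flatnonzero(self.states == FIRED)

    @property
    def not_fired(self) -> np.ndarray:
        return np.flatnonzero(self.states == NOT_FIRED)


@dataclass
class AlternationStats:
    """Recruitment statistics of one unit over the staircase."""

    activation_threshold_mA: float
    alternation_range_mA: float
    right_censored: bool
    mixed_level_currents: np.ndarray


@dataclass
class UnitDetection:
    """One extracted unit: firing vector, maps and derived statistics."""

    unit_id: int
    seed_region: np.ndarray
    firing: FiringVector
    difference_map: np.ndarray
    normalized_map: np.ndarray
    territory: np.ndarray
    stats: AlternationStats | None = None


# ---------------------------------------------------------------------------
# Two-means splitting of 1D samples (vectorised over rows)


def _two_means_rows(x: np.ndarray):
    """Optimal two-cluster split of each row of ``x`` (exhaustive over the
    sorted order, which is optimal for 1D k-means).

    Returns dict of per-row arrays: ``midpoint`` (decision threshold),
    ``n_low``, ``mean_low``, ``mean_high``, ``separation`` (cluster mean gap
    in units of the pooled within-cluster SD; inf for a perfect split).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    xs = np.sort(x, axis=1)
    c1 = np.cumsum(xs, axis=1)
    c2 = np.cumsum(xs * xs, axis=1)
    k = np.arange(1, n, dtype=float)
    ss_low = c2[:, :-1] - c1[:, :-1] ** 2 / k
    sum_hi = c1[:, -1:] - c1[:, :-1]
    ss_hi = (c2[:, -1:] - c2[:, :-1]) - sum_hi**2 / (n - k)
    ss = np.maximum(ss_low + ss_hi, 0.0)
    j = np.argmin(ss, axis=1)
    rows = np.arange(x.shape[0])
    n_low = j + 1
    mean_low = c1[rows, j] / n_low
    mean_high = sum_hi[rows, j] / (n - n_low)
    midpoint = 0.5 * (xs[rows, j] + xs[rows, j + 1])
    sd = np.sqrt(ss[rows, j] / max(n - 2, 1))
    gap = mean_high - mean_low
    with np.errstate(divide="ignore", invalid="ignore"):
        sep = np.where(sd > 0, gap / np.where(sd > 0, sd, 1.0), np.where(gap > 0, np.inf, 0.0))
    out = {
        "midpoint": midpoint,
        "n_low": n_low,
        "mean_low": mean_low,
        "mean_high": mean_high,
        "separation": sep,
    }
    if squeeze:
        out = {key: val[0] for key, val in out.items()}
    return out


def _window_slice(window, n_dynamics: int) -> slice:
    if window is None:
        return slice(0, n_dynamics)
    start, stop = int(window[0]), int(window[1])
    if not 0 <= start < stop <= n_dynamics:
        raise ValueError(f"window {window} outside the series' {n_dynamics} dynamics")
    return slice(start, stop)


# ---------------------------------------------------------------------------
# Candidate detection and clustering


def detect_candidate_voxels(
    series: DynamicSeries,
    mask: MuscleMask,
    schedule: StimulationSchedule | None = None,
    window: tuple[int, int] | None = None,
    min_separation: float = DEFAULT_SEPARATION,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> np.ndarray:
    """Boolean map of voxels that alternate within the analysis window.

    A voxel qualifies when its within-window trace splits into two clusters
    whose mean gap exceeds ``min_separation`` pooled within-cluster SDs and
    whose low (void) state recurs on at least ``min_events`` dynamics.  Pure
    noise clusters separate by only ~2.7 within-SD, well below the default
    criterion of 4.
    """
    sl = _window_slice(window, series.n_dynamics)
    inside = mask.foreground
    traces = series.pixels[inside][:, sl]
    if traces.shape[1] < 2 * min_events:
        raise ValueError("analysis window too short for the event criterion")
    split = _two_means_rows(traces)
    n_win = traces.shape[1]
    ok = (
        (split["separation"] >= min_separation)
        & (split["n_low"] >= min_events)
        & (split["n_low"] <= n_win - 1)
    )
    candidates = np.zeros(series.grid_shape, dtype=bool)
    candidates[inside] = ok
    return candidates


def voxel_firing_vectors(
    series: DynamicSeries,
    candidates: np.ndarray,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary per-voxel firing vectors (True = void/fired) for candidates.

    Returns ``(coords, fired)``: coords is (N, 2) ``(row, col)`` and fired
    is (N, n_window) boolean, thresholded at each voxel's own two-means
    midpoint.
    """
    sl = _window_slice(window, series.n_dynamics)
    coords = np.argwhere(candidates)
    if coords.size == 0:
        return coords.reshape(0, 2), np.zeros((0, sl.stop - sl.start), bool)
    traces = series.pixels[candidates][:, sl]
    split = _two_means_rows(traces)
    fired = traces < split["midpoint"][:, None]
    return coords, fired


def cluster_into_units(
    coords: np.ndarray,
    firing: np.ndarray,
    cofire_r2: float = DEFAULT_COFIRE_R2,
    min_unit_voxels: int = DEFAULT_MIN_UNIT_VOXELS,
) -> list[np.ndarray]:
    """Group candidate voxels into putative units by co-firing.

    Voxels whose binary firing vectors correlate *positively* with pairwise
    r-squared at or above ``cofire_r2`` are linked; connected groups under
    this relation form one unit.  (The sign gate matters: two voxels that
    fire on exactly complementary frames have r-squared 1 but are certainly
    not one unit.)  Groups smaller than ``min_unit_voxels`` are dropped.
    Returns a list of (K, 2) coordinate arrays, ordered by first voxel.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(coords)
    if n == 0:
        return []
    x = firing.astype(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(np.atleast_2d(r), nan=0.0)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    adj = (r > 0) & ((r * r) >= cofire_r2)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for lab in np.unique(labels):
        sel = np.flatnonzero(labels == lab)
        if sel.size >= min_unit_voxels:
            groups.append(coords[sel])
    groups.sort(key=lambda g: (g[0, 0], g[0, 1]))
    return groups


# ---------------------------------------------------------------------------
# Frame grouping, difference maps, thresholding


def group_frames(
    series: DynamicSeries,
    seed_region: np.ndarray,
    schedule: StimulationSchedule | None = None,
    window: tuple[int, int] | None = None,
    min_separation: float = DEFAULT_SEPARATION,
    unit_id: int | str | None = None,
) -> FiringVector:
    """Group dynamics into fired / not-fired from the seed-region trace.

    The mean intensity over ``seed_region`` is two-cluster partitioned; the
    lower cluster (signal void present) is the fired state.  Dynamics
    outside ``window`` are marked excluded.  Raises
    :class:`NoAlternationError` when the clusters are indistinguishable
    (separation below ``min_separation``).
    """
    seed_region = np.asarray(seed_region, dtype=bool)
    if not seed_region.any():
        raise ValueError("seed region is empty")
    sl = _window_slice(window, series.n_dynamics)
    trace = series.pixels[seed_region].mean(axis=0)
    split = _two_means_rows(trace[sl])
    if not np.isinf(split["separation"]) and split["separation"] < min_separation:
        raise NoAlternationError(
            f"seed region trace separation {split['separation']:.2f} below "
            f"criterion {min_separation}"
        )
    states = np.full(series.n_dynamics, EXCLUDED, dtype=np.int8)
    states[sl] = np.where(trace[sl] < split["midpoint"], FIRED, NOT_FIRED)
    return FiringVector(states, unit_id)


def build_difference_map(
    series: DynamicSeries,
    firing: FiringVector,
    mask: MuscleMask | None = None,
) -> np.ndarray:
    """Mean(not-fired images) - mean(fired images), per voxel.

    Linear in the series intensities; zero outside the muscle mask when one
    is supplied.
    """
    if firing.n_dynamics != series.n_dynamics:
        raise ValueError("firing vector length does not match the series")
    fired, quiet = firing.fired, firing.not_fired
    if fired.size == 0 or quiet.size == 0:
        raise ValueError("need at least one fired and one not-fired dynamic")
    diff = series.pixels[:, :, quiet].mean(axis=2) - series.pixels[:, :, fired].mean(axis=2)
    if mask is not None:
        diff = np.where(mask.foreground, diff, 0.0)
    return diff


def threshold_map(
    difference_map: np.ndarray,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    mask: MuscleMask | None = None,
    min_unit_voxels: int = DEFAULT_MIN_UNIT_VOXELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a difference map and threshold it into a binary territory.

    Negative values are clipped to zero, the map is divided by its maximum,
    and voxels with normalised value >= ``fraction`` form the territory
    (connected components smaller than ``min_unit_voxels`` are dropped,
    8-connectivity).  Raises :class:`NoActivityError` if the map has no
    positive values.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = np.clip(np.asarray(difference_map, dtype=float), 0.0, None)
    if mask is not None:
        m = np.where(mask.foreground, m, 0.0)
    peak = m.max()
    if peak <= 0:
        raise NoActivityError("difference map has no positive signal")
    normalized = m / peak
    territory = normalized >= fraction
    if min_unit_voxels > 1:
        territory = morphology.remove_small_objects(
            territory, max_size=min_unit_voxels - 1, connectivity=2
        )
    return normalized, territory


def threshold_sweep(
    difference_map: np.ndarray,
    fractions,
    voxel_size_mm: tuple[float, float],
    mask: MuscleMask | None = None,
    min_unit_voxels: int = DEFAULT_MIN_UNIT_VOXELS,
):
    """Territory metrics for each threshold fraction (threshold-choice QC).

    Returns a DataFrame with one row per fraction: CSA, Feret max/min,
    voxel and component counts.  Rows where the territory is empty hold
    zero CSA and NaN Feret values.
    """
    import pandas as pd

    from .morphometry import compute_csa, compute_feret, label_components

    rows = []
    for f in fractions:
        try:
            _, terr = threshold_map(difference_map, f, mask, min_unit_voxels)
        except NoActivityError:
            terr = np.zeros_like(np.asarray(difference_map), dtype=bool)
        if terr.any():
            csa = compute_csa(terr, voxel_size_mm)
            fmax, fmin = compute_feret(terr, voxel_size_mm)
            _, keep = label_components(terr, min_unit_voxels)
            ncomp = max(len(keep), 1)
        else:
            csa, fmax, fmin, ncomp = 0.0, np.nan, np.nan, 0
        rows.append(
            {
                "fraction": f,
                "csa_mm2": csa,
                "feret_max_mm": fmax,
                "feret_min_mm": fmin,
                "n_voxels": int(terr.sum()),
                "n_components": ncomp,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Alternation statistics


def alternation_stats(
    firing: FiringVector, schedule: StimulationSchedule
) -> AlternationStats:
    """Activation threshold and alternation current range of one unit.

    Per current level (excluded dynamics ignored): the activation threshold
    is the lowest current with at least one fired repeat; levels where 1 to
    (repeats-1) of the repeats fired form the alternation zone, and the
    alternation range is the current span of that zone (0 when no level has
    a mixed outcome).  When the unit fires at every level the range is
    right-censored (flagged): the staircase did not reach currents where
    the unit stays quiet.
    """
    if firing.n_dynamics != schedule.n_dynamics:
        raise ValueError("firing vector length does not match the schedule")
    currents, frac_mixed, any_fired, all_fired = [], [], [], []
    for lev in schedule.level_ids():
        dyn = schedule.dynamics_of_level(lev)
        states = firing.states[dyn]
        states = states[states != EXCLUDED]
        if states.size == 0:
            continue
        n_f = int((states == FIRED).sum())
        currents.append(schedule.current_mA[dyn[0]])
        any_fired.append(n_f >= 1)
        all_fired.append(n_f == states.size)
        frac_mixed.append(0 < n_f < states.size)
    currents = np.asarray(currents)
    any_fired = np.asarray(any_fired)
    all_fired = np.asarray(all_fired)
    frac_mixed = np.asarray(frac_mixed)
    if not any_fired.any():
        raise ValueError("unit never fires: alternation statistics undefined")
    threshold = float(currents[any_fired].min())
    mixed_currents = np.sort(currents[frac_mixed])
    alt_range = float(mixed_currents.max() - mixed_currents.min()) if mixed_currents.size else 0.0
    censored = bool(any_fired.all())
    return AlternationStats(threshold, alt_range, censored, mixed_currents)


def alternation_window(
    firing: FiringVector,
    schedule: StimulationSchedule,
    pad_levels: int = 5,
) -> tuple[int, int]:
    """Dynamic range spanning a unit's alternation zone, padded by
    ``pad_levels`` levels on each side.

    The zone is the span of levels with mixed outcomes; for a deterministic
    unit (no mixed level) it is the transition between the last all-fired
    and first none-fired level.  Restricting analysis to this window keeps
    frames where *other* units (with different thresholds) change state out
    of the difference maps — without it, the fired/not-fired split of one
    unit correlates with the recruitment of every unit above it in the
    staircase, and their territories leak into the map.
    """
    if firing.n_dynamics != schedule.n_dynamics:
        raise ValueError("firing vector length does not match the schedule")
    level_ids = schedule.level_ids()
    kinds = []  # per level: 'mixed' | 'all' | 'none' | None
    for lev in level_ids:
        dyn = schedule.dynamics_of_level(lev)
        states = firing.states[dyn]
        states = states[states != EXCLUDED]
        if states.size == 0:
            kinds.append(None)
            continue
        n_f = int((states == FIRED).sum())
        kinds.append("all" if n_f == states.size else "none" if n_f == 0 else "mixed")
    mixed = [i for i, k in enumerate(kinds) if k == "mixed"]
    if mixed:
        lo, hi = min(mixed), max(mixed)
    else:
        fired_any = [i for i, k in enumerate(kinds) if k == "all"]
        quiet = [i for i, k in enumerate(kinds) if k == "none"]
        if not fired_any or not quiet:
            # nothing to bracket: the whole series is the window
            return 0, schedule.n_dynamics
        lo = min(max(fired_any), min(quiet))
        hi = max(max(fired_any), min(quiet))
    lo = max(lo - pad_levels, 0)
    hi = min(hi + pad_levels, len(level_ids) - 1)
    dyn = np.concatenate(
        [schedule.dynamics_of_level(level_ids[i]) for i in range(lo, hi + 1)]
    )
    return int(dyn.min()), int(dyn.max()) + 1


# ---------------------------------------------------------------------------
# High-level extraction


def extract_units(
    series: DynamicSeries,
    mask: MuscleMask,
    schedule: StimulationSchedule,
    window: tuple[int, int] | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    cofire_r2: float = DEFAULT_COFIRE_R2,
    min_unit_voxels: int = DEFAULT_MIN_UNIT_VOXELS,
    min_events: int = DEFAULT_MIN_EVENTS,
    min_separation: float = DEFAULT_SEPARATION,
    window_pad_levels: int = 5,
) -> list[UnitDetection]:
    """Full extraction chain: candidates -> co-firing clusters -> per-unit
    firing vectors, difference maps, territories and alternation statistics.

    Each cluster is first grouped over the full series (or the supplied
    ``window``) to locate its alternation zone, then regrouped within that
    zone (:func:`alternation_window`), so that the difference map contrasts
    only frames where *this* unit changes state.  Clusters that fail any
    stage (no alternation, no positive difference signal, empty thresholded
    territory) are dropped.  Units are returned ordered by increasing
    activation threshold.
    """
    candidates = detect_candidate_voxels(
        series, mask, schedule, window, min_separation, min_events
    )
    coords, firing_vecs = voxel_firing_vectors(series, candidates, window)
    groups = cluster_into_units(coords, firing_vecs, cofire_r2, min_unit_voxels)
    units: list[UnitDetection] = []
    for gid, group in enumerate(groups):
        seed = np.zeros(series.grid_shape, dtype=bool)
        seed[group[:, 0], group[:, 1]] = True
        try:
            coarse_firing = group_frames(
                series, seed, schedule, window, min_separation, unit_id=gid
            )
            unit_window = alternation_window(coarse_firing, schedule, window_pad_levels)
            firing = group_frames(
                series, seed, schedule, unit_window, min_separation, unit_id=gid
            )
            diff = build_difference_map(series, firing, mask)
            normalized, territory = threshold_map(
                diff, threshold_fraction, mask, min_unit_voxels
            )
            if not territory.any():
                continue
            stats = alternation_stats(firing, schedule)
        except (NoAlternationError, NoActivityError, ValueError):
            continue
        units.append(UnitDetection(gid, seed, firing, diff, normalized, territory, stats))
    units.sort(key=lambda u: (u.stats.activation_threshold_mA, u.unit_id))
    for i, u in enumerate(units):
        u.unit_id = i
        u.firing.unit_id = i
    return units
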