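"""Synthetic phantom: dynamic series with known ground-truth motor units.

The simulator emulates what a fine- or coarse-grain scan sees: a muscle with
uniform baseline signal, one or more planted unit territories, all-or-none
signal voids drawn per stimulus from a logistic firing probability around
each unit's activation threshold, optional mechanical-coupling dilation of
the void, and Rician (magnitude-MRI) noise.

The firing model is the package's own parameterisation of probabilistic
all-or-none recruitment: P(fire | I) = logistic((I - threshold) / width).
At I = threshold the probability is exactly 0.5; ``width`` controls the
current span of the alternation zone (roughly 4*width between 10% and 90%
firing probability).  ``width = 0`` is a step function, 0.5 at threshold by
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, GeometryError, ParameterWarning
from .io import DynamicSeries, MuscleMask, StimulationSchedule

SHAPE_CLASSES = ("ellipse", "crescent", "circular", "spider", "split")


@dataclass
class UnitTerritory:
    """A planted motor unit: its territory map and firing behaviour.

    ``threshold_mA`` is the logistic midpoint (50% firing probability),
    ``firing_width_mA`` the logistic scale, ``void_fraction`` the
    multiplicative signal drop in active voxels, ``coupling_dilation_vox``
    the mechanical-coupling halo (voxels of binary dilation applied to the
    void region when the unit fires).
    """

    shape_class: str
    territory: np.ndarray
    threshold_mA: float = 10.0
    firing_width_mA: float = 0.05
    void_fraction: float = 0.4
    coupling_dilation_vox: int = 0

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        self.territory = np.asarray(self.territory, dtype=bool)
        if self.territory.ndim != 2 or not self.territory.any():
            raise ValueError("territory must be a non-empty 2D binary map")
        if not 0.0 < self.void_fraction < 1.0:
            raise ValueError("void_fraction must be in (0, 1)")
        if self.firing_width_mA < 0:
            raise ValueError("firing_width_mA must be >= 0")
        if self.coupling_dilation_vox < 0:
            raise ValueError("coupling_dilation_vox must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(self.territory.sum())

    def void_region(self) -> np.ndarray:
        """Territory dilated by the mechanical-coupling halo (8-connected)."""
        if self.coupling_dilation_vox == 0:
            return self.territory
        return ndimage.binary_dilation(
            self.territory,
            structure=np.ones((3, 3), bool),
            iterations=self.coupling_dilation_vox,
        )


@dataclass
class Phantom:
    """A muscle mask plus planted units and signal/noise parameters.

    ``baseline_intensity`` is either a scalar (all muscles) or a mapping
    label -> intensity.  ``noise_sigma`` is the Rician noise scale expressed
    as a fraction of the (maximum) baseline.
    """

    mask: MuscleMask
    units: list[UnitTerritory] = field(default_factory=list)
    baseline_intensity: float | dict[int, float] = 100.0
    noise_sigma: float = 0.03
    voxel_size_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 7.5
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        fg = self.mask.foreground
        for i, unit in enumerate(self.units):
            if unit.territory.shape != self.mask.labels.shape:
                raise ConsistencyError(f"unit {i} territory shape != mask shape")
            labs = np.unique(self.mask.labels[unit.territory])
            if 0 in labs:
                raise ConsistencyError(f"unit {i} territory leaves the muscle mask")
            if labs.size != 1:
                raise ConsistencyError(f"unit {i} territory spans {labs.size} muscles")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        del fg

    def baseline_map(self) -> np.ndarray:
        base = np.zeros(self.mask.labels.shape, dtype=float)
        if isinstance(self.baseline_intensity, dict):
            for lab, val in self.baseline_intensity.items():
                base[self.mask.labels == lab] = float(val)
        else:
            base[self.mask.foreground] = float(self.baseline_intensity)
        return base

    def reference_intensity(self) -> float:
        if isinstance(self.baseline_intensity, dict):
            return float(max(self.baseline_intensity.values()))
        return float(self.baseline_intensity)


# ---------------------------------------------------------------------------
# Territory geometry


def _center_coords(grid_shape, voxel_size_mm):
    rows, cols = grid_shape
    rmm, cmm = voxel_size_mm
    y = (np.arange(rows) + 0.5) * rmm
    x = (np.arange(cols) + 0.5) * cmm
    return np.meshgrid(y, x, indexing="ij")


def _check_extent(grid_shape, voxel_size_mm, center_rc, reach_mm):
    rows, cols = grid_shape
    rmm, cmm = voxel_size_mm
    cy, cx = (center_rc[0] + 0.5) * rmm, (center_rc[1] + 0.5) * cmm
    if (
        cy - reach_mm < 0
        or cx - reach_mm < 0
        or cy + reach_mm > rows * rmm
        or cx + reach_mm > cols * cmm
    ):
        raise GeometryError(
            f"shape with reach {reach_mm:.1f} mm at {center_rc} exceeds the grid"
        )


def _raster_disc(grid_shape, voxel_size_mm, center_rc, radius_mm):
    yy, xx = _center_coords(grid_shape, voxel_size_mm)
    rmm, cmm = voxel_size_mm
    cy, cx = (center_rc[0] + 0.5) * rmm, (center_rc[1] + 0.5) * cmm
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_mm**2


def make_territory(
    shape_class: str,
    center: tuple[float, float],
    size_params: dict,
    grid_shape: tuple[int, int],
    voxel_size_mm: tuple[float, float] = (1.5, 1.5),
    seed: int | None = None,
    **unit_kwargs,
) -> UnitTerritory:
    """Rasterise one of the five canonical territory shapes.

    Parameters
    ----------
    shape_class
        ``ellipse`` (``axes_mm=(major, minor)``, ``angle_deg``),
        ``circular`` (``radius_mm``),
        ``crescent`` (``outer_mm``, ``inner_mm``, ``span_deg``, ``angle_deg``),
        ``spider`` (``core_mm``, ``arm_length_mm``, ``n_arms``,
        ``arm_width_mm``, ``angle_deg``),
        ``split`` (``radius_mm`` or ``radii_mm=(r1, r2)``, ``gap_mm``).
    center
        Voxel coordinates ``(row, col)`` of the shape centre (floats allowed).
    seed
        Optional; when given, randomises the shape orientation.
    unit_kwargs
        Forwarded to :class:`UnitTerritory` (threshold, width, ...).

    The split gap is realised as an integer number of empty voxel columns, so
    the planted border-to-border distance is ``round(gap_mm / col_mm)``
    columns — within half a voxel of the request.
    """
    if shape_class not in SHAPE_CLASSES:
        raise ValueError(f"unknown shape class {shape_class!r}")
    rng = np.random.default_rng(seed)
    angle = float(size_params.get("angle_deg", 0.0))
    if seed is not None and "angle_deg" not in size_params:
        angle = float(rng.uniform(0, 180))
    rmm, cmm = voxel_size_mm
    yy, xx = _center_coords(grid_shape, voxel_size_mm)
    cy, cx = (center[0] + 0.5) * rmm, (center[1] + 0.5) * cmm
    dy, dx = yy - cy, xx - cx
    th = np.deg2rad(angle)
    # coordinates in the shape frame (rotated by -angle)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)

    if shape_class in ("ellipse", "circular"):
        if shape_class == "circular":
            r = float(size_params["radius_mm"])
            a = b = r
        else:
            a, b = (float(s) / 2.0 for s in size_params["axes_mm"])
        _check_extent(grid_shape, voxel_size_mm, center, max(a, b))
        terr = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    elif shape_class == "crescent":
        outer = float(size_params["outer_mm"])
        inner = float(size_params["inner_mm"])
        span = float(size_params.get("span_deg", 150.0))
        if not 0 < inner < outer:
            raise ValueError("crescent needs 0 < inner_mm < outer_mm")
        _check_extent(grid_shape, voxel_size_mm, center, outer)
        rad = np.hypot(u, v)
        ang = np.degrees(np.arctan2(v, u))
        terr = (rad >= inner) & (rad <= outer) & (np.abs(ang) <= span / 2.0)

    elif shape_class == "spider":
        core = float(size_params.get("core_mm", 2.0))
        arm_len = float(size_params["arm_length_mm"])
        n_arms = int(size_params.get("n_arms", 4))
        arm_w = float(size_params.get("arm_width_mm", 1.6))
        if n_arms < 3:
            raise ValueError("spider needs >= 3 arms")
        _check_extent(grid_shape, voxel_size_mm, center, arm_len)
        terr = np.hypot(u, v) <= core
        for k in range(n_arms):
            phi = np.deg2rad(k * 360.0 / n_arms)
            au, av = np.cos(phi), np.sin(phi)
            along = u * au + v * av
            across = -u * av + v * au
            terr |= (along >= 0) & (along <= arm_len) & (np.abs(across) <= arm_w / 2.0)

    elif shape_class == "split":
        if "radii_mm" in size_params:
            r1, r2 = (float(r) for r in size_params["radii_mm"])
        else:
            r1 = r2 = float(size_params["radius_mm"])
        gap_mm = float(size_params["gap_mm"])
        gap_cols = max(1, round(gap_mm / cmm))
        d1 = _raster_disc(grid_shape, voxel_size_mm, center, r1)
        d2 = _raster_disc(grid_shape, voxel_size_mm, center, r2)
        if not (d1.any() and d2.any()):
            raise GeometryError("split component radius smaller than half a voxel")
        c1max = int(np.flatnonzero(d1.any(axis=0)).max())
        c2min = int(np.flatnonzero(d2.any(axis=0)).min())
        shift = (c1max + 1 + gap_cols) - c2min
        if c2min + shift < 0 or int(np.flatnonzero(d2.any(axis=0)).max()) + shift >= grid_shape[1]:
            raise GeometryError("split shape exceeds the grid")
        d2 = np.roll(d2, shift, axis=1)
        terr = d1 | d2

    else:  # pragma: no cover - guarded above
        raise ValueError(shape_class)

    if not terr.any():
        raise GeometryError("requested shape rasterises to an empty map")
    return UnitTerritory(shape_class, terr, **unit_kwargs)


# ---------------------------------------------------------------------------
# Firing model and simulation


def firing_probability(current_mA, threshold_mA, firing_width_mA):
    """Logistic firing probability; exactly 0.5 at threshold; step at width 0."""
    current = np.asarray(current_mA, dtype=float)
    thr = np.asarray(threshold_mA, dtype=float)
    width = np.asarray(firing_width_mA, dtype=float)
    if np.any(width < 0):
        raise ValueError("firing_width_mA must be >= 0")
    delta = current - thr
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        z = np.where(width > 0, delta / np.where(width > 0, width, 1.0), np.inf * np.sign(delta))
        p = np.where(
            width > 0,
            1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))),
            np.where(delta > 0, 1.0, np.where(delta < 0, 0.0, 0.5)),
        )
    return p if p.ndim else float(p)


def simulate_series(
    phantom: Phantom, schedule: StimulationSchedule, seed: int
) -> tuple[DynamicSeries, np.ndarray]:
    """Simulate a dynamic scan; returns the series and the ground-truth
    firing matrix (units x dynamics, boolean).

    Per dynamic, each unit fires (all-or-none across its whole territory)
    with its logistic probability at that dynamic's current.  Fired units
    multiply the signal by ``void_fraction`` over the territory dilated by
    the coupling halo.  Rician noise is applied last.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n_dyn = schedule.n_dynamics
    base = phantom.baseline_map()
    signal = np.repeat(base[:, :, None], n_dyn, axis=2)
    n_units = len(phantom.units)
    fired = np.zeros((n_units, n_dyn), dtype=bool)
    for i, unit in enumerate(phantom.units):
        p = firing_probability(schedule.current_mA, unit.threshold_mA, unit.firing_width_mA)
        fired[i] = rng.random(n_dyn) < p
        if fired[i].any():
            rr, cc = np.nonzero(unit.void_region())
            tt = np.flatnonzero(fired[i])
            signal[rr[:, None], cc[:, None], tt[None, :]] *= unit.void_fraction
    if phantom.noise_sigma > 0:
        sig = phantom.noise_sigma * phantom.reference_intensity()
        g1 = rng.normal(0.0, sig, signal.shape)
        g2 = rng.normal(0.0, sig, signal.shape)
        signal = np.hypot(signal + g1, g2)
    series = DynamicSeries(
        signal,
        phantom.voxel_size_mm,
        phantom.slice_thickness_mm,
        phantom.tr_s,
    )
    return series, fired


# ---------------------------------------------------------------------------
# Schedule planners


def plan_coarse_schedule(
    start_mA: float, step_mA: float, n_dynamics: int
) -> StimulationSchedule:
    """Ascending ramp, one dynamic per current level (the coarse-grain scan).

    The usual ramp step is 0.1-0.5 mA; values outside that range are allowed
    but flagged with a :class:`ParameterWarning`.
    """
    if n_dynamics < 1:
        raise ValueError("n_dynamics must be >= 1")
    if step_mA <= 0:
        raise ValueError("step_mA must be > 0")
    if not 0.1 <= step_mA <= 0.5:
        warnings.warn(
            f"coarse ramp step {step_mA} mA outside the usual 0.1-0.5 mA range",
            ParameterWarning,
            stacklevel=2,
        )
    currents = start_mA + step_mA * np.arange(n_dynamics)
    return StimulationSchedule(
        currents, np.arange(n_dynamics), np.zeros(n_dynamics, int), step_mA
    )


def plan_fine_schedule(
    i_max_mA: float,
    step_mA: float = 0.01,
    repeats: int = 5,
    n_levels: int = 216,
) -> StimulationSchedule:
    """Descending staircase from ``i_max_mA``: each level held for
    ``repeats`` consecutive dynamics, stepping down ``step_mA`` per level.

    Defaults give the standard fine-grain protocol: 216 levels x 5 repeats =
    1080 dynamics at 0.01 mA steps.
    """
    if step_mA <= 0 or repeats < 1 or n_levels < 1:
        raise ValueError("step_mA > 0, repeats >= 1, n_levels >= 1 required")
    lowest = i_max_mA - (n_levels - 1) * step_mA
    if lowest <= 0:
        raise ValueError(
            f"staircase reaches non-positive current ({lowest:.3f} mA); "
            "reduce n_levels or step"
        )
    level = np.repeat(np.arange(n_levels), repeats)
    currents = i_max_mA - step_mA * level
    repeat = np.tile(np.arange(repeats), n_levels)
    return StimulationSchedule(currents, level, repeat, step_mA)


# ---------------------------------------------------------------------------
# Canonical shape fixtures


def canonical_fixtures(
    grid_shape: tuple[int, int] = (48, 48),
    voxel_size_mm: tuple[float, float] = (1.5, 1.5),
) -> list[UnitTerritory]:
    """Three noise-free exemplars per shape class (15 territories).

    Sizes are chosen to sit comfortably inside each class's defining
    geometry (solidity / aspect bands), at the scale of in-vivo territories
    (CSA of order 10-60 mm^2 at 1.5 mm voxels).
    """
    c = (grid_shape[0] / 2 - 0.5, grid_shape[1] / 2 - 0.5)
    specs: list[tuple[str, dict]] = [
        ("ellipse", {"axes_mm": (16.0, 6.0), "angle_deg": 0.0}),
        ("ellipse", {"axes_mm": (14.0, 5.5), "angle_deg": 40.0}),
        ("ellipse", {"axes_mm": (20.0, 8.0), "angle_deg": 110.0}),
        ("circular", {"radius_mm": 4.0}),
        ("circular", {"radius_mm": 4.5}),
        ("circular", {"radius_mm": 6.0}),
        ("crescent", {"outer_mm": 9.0, "inner_mm": 5.0, "span_deg": 150.0, "angle_deg": 0.0}),
        ("crescent", {"outer_mm": 10.5, "inner_mm": 6.0, "span_deg": 140.0, "angle_deg": 65.0}),
        ("crescent", {"outer_mm": 8.0, "inner_mm": 4.5, "span_deg": 160.0, "angle_deg": 200.0}),
        ("spider", {"core_mm": 2.2, "arm_length_mm": 9.0, "n_arms": 4, "arm_width_mm": 1.8, "angle_deg": 0.0}),
        ("spider", {"core_mm": 2.5, "arm_length_mm": 10.5, "n_arms": 5, "arm_width_mm": 1.8, "angle_deg": 20.0}),
        ("spider", {"core_mm": 2.0, "arm_length_mm": 8.0, "n_arms": 3, "arm_width_mm": 1.8, "angle_deg": 45.0}),
        ("split", {"radius_mm": 2.4, "gap_mm": 4.3}),
        ("split", {"radii_mm": (2.2, 3.2), "gap_mm": 1.5}),
        ("split", {"radius_mm": 3.0, "gap_mm": 6.0}),
    ]
    return [
        make_territory(cls, c, params, grid_shape, voxel_size_mm)
        for cls, params in specs
    ]
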