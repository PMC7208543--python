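"""Morphometry of binary unit territories: CSA, Feret (caliper) diameters,
split-component gaps, the five-class shape taxonomy, and voxel co-firing.

Geometry is computed on the union of voxel *squares* (corner polygons), not
voxel centres, so a single voxel has a physical extent: its minimum Feret
diameter equals the voxel edge and its maximum the voxel diagonal.
Components are labelled with 8-connectivity (diagonally touching voxels are
one region).  For multi-component territories, Feret diameters are measured
over all components jointly: one caliper pair restricts the whole object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .errors import DegenerateInputError
from .io import DynamicSeries

#: Shape-class decision thresholds.  The taxonomy (elliptical, crescent,
#: circular, spider, split) follows the field's visual classification; the
#: numeric cutoffs below are this package's operational definitions and are
#: configurable.
SPIDER_SOLIDITY = 0.6
CRESCENT_SOLIDITY = 0.85
CIRCULAR_ASPECT = 1.3


@dataclass
class UnitMetrics:
    """Morphometric summary of one motor unit territory."""

    csa_mm2: float
    feret_max_mm: float
    feret_min_mm: float
    shape_class: str
    n_components: int
    component_gap_mm: float | None = None
    activation_threshold_mA: float | None = None
    alternation_range_mA: float | None = None

    def to_dict(self) -> dict:
        return {
            "csa_mm2": self.csa_mm2,
            "feret_max_mm": self.feret_max_mm,
            "feret_min_mm": self.feret_min_mm,
            "shape_class": self.shape_class,
            "n_components": self.n_components,
            "component_gap_mm": self.component_gap_mm,
            "activation_threshold_mA": self.activation_threshold_mA,
            "alternation_range_mA": self.alternation_range_mA,
        }


# ---------------------------------------------------------------------------
# Basic geometry helpers


def voxel_corner_points(
    territory: np.ndarray, voxel_size_mm: tuple[float, float]
) -> np.ndarray:
    """(x, y) corners in mm of every occupied voxel square (deduplicated).

    x runs along columns, y along rows.
    """
    territory = np.asarray(territory, dtype=bool)
    rr, cc = np.nonzero(territory)
    if rr.size == 0:
        raise ValueError("territory is empty")
    rmm, cmm = float(voxel_size_mm[0]), float(voxel_size_mm[1])
    corners = set()
    for r, c in zip(rr.tolist(), cc.tolist()):
        for dr in (0, 1):
            for dc in (0, 1):
                corners.add(((c + dc) * cmm, (r + dr) * rmm))
    return np.array(sorted(corners), dtype=float)


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points)
    return points[hull.vertices]


def compute_csa(territory: np.ndarray, voxel_size_mm: tuple[float, float]) -> float:
    """Cross-sectional area: voxel count x voxel area (mm^2)."""
    territory = np.asarray(territory, dtype=bool)
    n = int(territory.sum())
    if n == 0:
        warnings.warn("empty territory: CSA is 0", stacklevel=2)
        return 0.0
    return n * float(voxel_size_mm[0]) * float(voxel_size_mm[1])


def compute_feret(
    territory: np.ndarray, voxel_size_mm: tuple[float, float]
) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters in mm.

    Feret diameter at an orientation is the distance between the two
    parallel supporting lines of the object at that orientation.  The
    maximum is the convex-hull diameter (max pairwise vertex distance); the
    minimum is the smallest width over hull edges (rotating calipers: the
    minimum width of a convex polygon is attained perpendicular to one of
    its edges).
    """
    pts = voxel_corner_points(territory, voxel_size_mm)
    verts = _hull_vertices(pts)
    # hull diameter
    diff = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diff**2).sum(-1)).max())
    # minimum width over edges
    nv = len(verts)
    feret_min = np.inf
    for i in range(nv):
        p0 = verts[i]
        p1 = verts[(i + 1) % nv]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        ex, ey = edge / norm
        d = verts - p0
        width = np.abs(ex * d[:, 1] - ey * d[:, 0]).max()  # 2D cross product
        feret_min = min(feret_min, float(width))
    return feret_max, feret_min


def solidity(territory: np.ndarray, voxel_size_mm: tuple[float, float]) -> float:
    """Pixelated area divided by convex-hull area (both on voxel squares)."""
    pts = voxel_corner_points(territory, voxel_size_mm)
    hull = ConvexHull(pts)
    area = compute_csa(territory, voxel_size_mm)
    return float(area / hull.volume)  # in 2D, .volume is the hull area


def label_components(territory: np.ndarray, min_unit_voxels: int = 1):
    """8-connected component labels and the labels of significant components."""
    lab = measure.label(np.asarray(territory, bool), connectivity=2)
    keep = [
        int(v) for v in np.unique(lab) if v != 0 and (lab == v).sum() >= min_unit_voxels
    ]
    return lab, keep


def component_gap(
    territory: np.ndarray,
    voxel_size_mm: tuple[float, float],
    min_unit_voxels: int = 1,
) -> float:
    """Minimum border-to-border distance (mm) between the two nearest
    disjoint components of a split territory.

    Boundaries are the voxel-square outlines; touching components (including
    diagonal contact, which 8-connectivity merges anyway) give 0.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    lab, keep = label_components(territory, min_unit_voxels)
    if len(keep) < 2:
        raise DegenerateInputError("component gap undefined: fewer than 2 components")
    rmm, cmm = float(voxel_size_mm[0]), float(voxel_size_mm[1])
    polys = []
    for v in keep:
        rr, cc = np.nonzero(lab == v)
        polys.append(
            unary_union(
                [
                    box(c * cmm, r * rmm, (c + 1) * cmm, (r + 1) * rmm)
                    for r, c in zip(rr.tolist(), cc.tolist())
                ]
            )
        )
    gaps = [
        polys[i].distance(polys[j])
        for i in range(len(polys))
        for j in range(i + 1, len(polys))
    ]
    return float(min(gaps))


def classify_shape(
    territory: np.ndarray,
    voxel_size_mm: tuple[float, float],
    min_unit_voxels: int = 3,
    spider_solidity: float = SPIDER_SOLIDITY,
    crescent_solidity: float = CRESCENT_SOLIDITY,
    circular_aspect: float = CIRCULAR_ASPECT,
) -> str:
    """Classify a territory into one of the five canonical shape classes.

    Rule cascade: *split* if >= 2 disjoint components (each with at least
    ``min_unit_voxels`` voxels); otherwise by solidity s = area / hull area
    and aspect a = FeretMax / FeretMin: *spider* if s < ``spider_solidity``;
    *crescent* if s < ``crescent_solidity``; *circular* if a <
    ``circular_aspect``; *ellipse* otherwise.
    """
    territory = np.asarray(territory, bool)
    if not territory.any():
        raise ValueError("territory is empty")
    _, keep = label_components(territory, min_unit_voxels)
    if len(keep) >= 2:
        return "split"
    s = solidity(territory, voxel_size_mm)
    fmax, fmin = compute_feret(territory, voxel_size_mm)
    aspect = fmax / fmin
    if s < spider_solidity:
        return "spider"
    if s < crescent_solidity:
        return "crescent"
    if aspect < circular_aspect:
        return "circular"
    return "ellipse"


def cofire_r2(
    series: DynamicSeries,
    voxel_a: tuple[int, int],
    voxel_b: tuple[int, int],
    window: tuple[int, int] | None = None,
) -> float:
    """Squared Pearson correlation of two voxel time series over a window.

    ``window`` is a half-open dynamic range ``(start, stop)``; ``None`` uses
    the whole series.  High r-squared between voxel pairs is the signature
    of co-firing (same unit); pairs from units with different thresholds
    decorrelate.
    """
    sl = slice(*window) if window is not None else slice(None)
    a = series.pixels[voxel_a[0], voxel_a[1], sl].astype(float)
    b = series.pixels[voxel_b[0], voxel_b[1], sl].astype(float)
    if a.size < 3:
        raise ValueError("co-firing window must cover at least 3 dynamics")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("co-firing r^2 undefined for a zero-variance trace")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def measure_unit(
    territory: np.ndarray,
    voxel_size_mm: tuple[float, float],
    min_unit_voxels: int = 3,
    activation_threshold_mA: float | None = None,
    alternation_range_mA: float | None = None,
) -> UnitMetrics:
    """Full morphometric summary of one binary territory."""
    shape_class = classify_shape(territory, voxel_size_mm, min_unit_voxels)
    fmax, fmin = compute_feret(territory, voxel_size_mm)
    _, keep = label_components(territory, min_unit_voxels)
    gap = (
        component_gap(territory, voxel_size_mm, min_unit_voxels)
        if len(keep) >= 2
        else None
    )
    return UnitMetrics(
        csa_mm2=compute_csa(territory, voxel_size_mm),
        feret_max_mm=fmax,
        feret_min_mm=fmin,
        shape_class=shape_class,
        n_components=max(len(keep), 1),
        component_gap_mm=gap,
        activation_threshold_mA=activation_threshold_mA,
        alternation_range_mA=alternation_range_mA,
    )
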