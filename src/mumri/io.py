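"""File formats: dynamic image series (NIfTI), stimulation schedules (CSV)
and muscle masks (NIfTI or PNG).

Conventions
-----------
* Pixel arrays are addressed row-major ``(row, col)``; the dynamic axis is
  last.  A two-slice acquisition is stored as one file per slice — a single
  slice is the unit of analysis.
* All indices are 0-based.  Physical units are fixed: mm, mA, seconds.
* Schedule CSV dialect: comma separator, dot decimal, mandatory header
  ``dynamic_index,current_mA,level_index,repeat_index``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

SCHEDULE_COLUMNS = ("dynamic_index", "current_mA", "level_index", "repeat_index")

#: Muscles activated by common fibular / tibial nerve stimulation.
FIBULAR_MUSCLES = {1: "TA", 2: "EDL", 3: "PL"}
TIBIAL_MUSCLES = {1: "SOL", 2: "GM", 3: "GL"}


@dataclass
class DynamicSeries:
    """A 2D slice imaged repeatedly over time (one dynamic per TR).

    Parameters
    ----------
    pixels
        Signal intensity, shape ``(rows, cols, dynamics)``, arbitrary
        scanner units, non-negative.
    voxel_size_mm
        In-plane voxel dimensions ``(row_mm, col_mm)``.
    slice_thickness_mm
        Through-plane thickness of the imaged slice.
    tr_s
        Repetition time; the time between consecutive dynamics.
    """

    pixels: np.ndarray
    voxel_size_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 7.5
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] < 1:
            raise FormatError(
                f"pixels must be (rows, cols, dynamics>=1); got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise FormatError("pixel intensities must be non-negative")
        self.voxel_size_mm = (float(self.voxel_size_mm[0]), float(self.voxel_size_mm[1]))
        if min(self.voxel_size_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise FormatError("voxel dimensions must be positive")
        if self.tr_s <= 0:
            raise FormatError("TR must be positive")

    @property
    def n_dynamics(self) -> int:
        return self.pixels.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_size_mm[0] * self.voxel_size_mm[1]


@dataclass
class StimulationSchedule:
    """Per-dynamic stimulation currents with level/repeat structure.

    Entry *i* describes dynamic *i* (dense, 0-based).  Within one
    ``level_index`` the current is constant and ``repeat_index`` counts
    0..(repeats-1) in acquisition order.
    """

    current_mA: np.ndarray
    level_index: np.ndarray
    repeat_index: np.ndarray
    step_mA: float | None = None

    def __post_init__(self) -> None:
        self.current_mA = np.asarray(self.current_mA, dtype=float)
        self.level_index = np.asarray(self.level_index, dtype=int)
        self.repeat_index = np.asarray(self.repeat_index, dtype=int)
        n = self.current_mA.size
        if n < 1 or self.level_index.size != n or self.repeat_index.size != n:
            raise FormatError("schedule arrays must be non-empty and equal length")
        if np.any(self.current_mA < 0) or not np.all(np.isfinite(self.current_mA)):
            raise FormatError("currents must be finite and >= 0")
        for lev in np.unique(self.level_index):
            sel = self.level_index == lev
            cur = self.current_mA[sel]
            if np.ptp(cur) > 0:
                raise ConsistencyError(
                    f"current varies within level {lev}: {sorted(set(cur.tolist()))}"
                )
            reps = self.repeat_index[sel]
            if not np.array_equal(np.sort(reps), np.arange(reps.size)):
                raise ConsistencyError(f"repeat_index within level {lev} must count 0..n-1")
        if self.step_mA is None:
            self.step_mA = self._infer_step()

    def _infer_step(self) -> float:
        cur = self.level_currents()
        if cur.size < 2:
            return 0.0
        return float(np.median(np.abs(np.diff(cur))))

    @property
    def n_dynamics(self) -> int:
        return int(self.current_mA.size)

    @property
    def dynamic_index(self) -> np.ndarray:
        return np.arange(self.n_dynamics)

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.level_index).size)

    def level_ids(self) -> np.ndarray:
        """Level indices in order of first appearance (acquisition order)."""
        _, first = np.unique(self.level_index, return_index=True)
        return self.level_index[np.sort(first)]

    def level_currents(self) -> np.ndarray:
        """One current per level, in acquisition order."""
        return np.array(
            [self.current_mA[self.level_index == lev][0] for lev in self.level_ids()]
        )

    def dynamics_of_level(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.level_index == level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dynamic_index": self.dynamic_index,
                "current_mA": self.current_mA,
                "level_index": self.level_index,
                "repeat_index": self.repeat_index,
            }
        )


@dataclass
class MuscleMask:
    """Integer label image: 0 = background, k > 0 = muscle *k*."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("mask must be a 2D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise FormatError("mask must be integer-valued")
            self.labels = np.round(self.labels).astype(int)
        self.names = {int(k): str(v) for k, v in self.names.items()}
        for lab in self.present_labels():
            if lab not in self.names:
                raise ConsistencyError(f"label {lab} present in mask but has no name")

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# NIfTI series I/O


def load_dynamic_series(path: str | Path) -> DynamicSeries:
    """Read a dynamic series from NIfTI; the last axis is dynamics.

    Accepts 3D ``(rows, cols, dynamics)`` volumes (in-plane voxel sizes in
    pixdim 1-2, slice thickness in pixdim 3, TR in pixdim 4 when set) and 4D
    ``(rows, cols, 1, dynamics)`` volumes with TR in pixdim 4.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    # nibabel silently "repairs" zero pixdims at load; validate the raw
    # on-disk header so a missing geometry is reported, not invented
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        pixdim = nib.Nifti1Header.from_fileobj(fh, check=False)["pixdim"]
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise FormatError("4D series must have a single slice (shape[2] == 1)")
        data = data[:, :, 0, :]
        tr = float(pixdim[4])
    elif data.ndim == 3:
        tr = float(pixdim[4]) if pixdim[4] > 0 else 1.0
    else:
        raise FormatError(f"expected a 3D/4D NIfTI series, got {data.ndim}D")
    row_mm, col_mm, thick = float(pixdim[1]), float(pixdim[2]), float(pixdim[3])
    if row_mm <= 0 or col_mm <= 0:
        raise FormatError("in-plane pixel dimensions missing or zero in NIfTI header")
    if thick <= 0:
        thick = 7.5
    if tr <= 0:
        tr = 1.0
    return DynamicSeries(data, (row_mm, col_mm), thick, tr)


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a series as 3D NIfTI with geometry and TR in the header."""
    row_mm, col_mm = series.voxel_size_mm
    affine = np.diag([row_mm, col_mm, series.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(series.pixels.astype(np.float64), affine)
    img.header["pixdim"][1:5] = [row_mm, col_mm, series.slice_thickness_mm, series.tr_s]
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Schedule I/O


def load_schedule(path: str | Path) -> StimulationSchedule:
    """Read a stimulation schedule CSV and validate its structure."""
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"schedule CSV missing columns {missing}")
    df = df.sort_values("dynamic_index").reset_index(drop=True)
    idx = df["dynamic_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        raise FormatError("dynamic_index must be dense, 0-based and unique")
    return StimulationSchedule(
        df["current_mA"].to_numpy(float),
        df["level_index"].to_numpy(int),
        df["repeat_index"].to_numpy(int),
    )


def write_schedule(schedule: StimulationSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mask I/O


def load_mask(path: str | Path, names: dict[int, str]) -> MuscleMask:
    """Read a muscle mask from NIfTI or PNG and attach muscle names."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
        if arr.ndim == 3:  # greyscale stored as RGB(A): require identical channels
            if np.ptp(arr[..., :3], axis=-1).max() > 0:
                raise FormatError("PNG mask must be single-channel / greyscale")
            arr = arr[..., 0]
        labels = arr
    else:
        img = nib.load(str(path))
        labels = np.asanyarray(img.dataobj)
        labels = np.squeeze(labels)
        if labels.ndim != 2:
            raise FormatError("mask NIfTI must be a single 2D slice")
    return MuscleMask(np.asarray(labels), names)


def write_mask(mask: MuscleMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        if int(mask.labels.max(initial=0)) > 255:
            raise FormatError("PNG masks support labels up to 255")
        Image.fromarray(mask.labels.astype(np.uint8)).save(path)
    else:
        img = nib.Nifti1Image(mask.labels.astype(np.int16), np.eye(4))
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Joint consistency & QC export


def check_consistency(
    series: DynamicSeries,
    mask: MuscleMask | None = None,
    schedule: StimulationSchedule | None = None,
) -> None:
    """Raise :class:`ConsistencyError` on any spatial/temporal mismatch."""
    if mask is not None and mask.labels.shape != series.grid_shape:
        raise ConsistencyError(
            f"mask shape {mask.labels.shape} != series grid {series.grid_shape}"
        )
    if schedule is not None and schedule.n_dynamics != series.n_dynamics:
        raise ConsistencyError(
            f"schedule has {schedule.n_dynamics} dynamics, series has {series.n_dynamics}"
        )


def export_qc_png(map2d: np.ndarray, path: str | Path, title: str | None = None) -> None:
    """Save a 2D map (e.g. a difference map) as a PNG for visual QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(map2d, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
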