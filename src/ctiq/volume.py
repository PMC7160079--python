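"""HU image volumes, circular ROIs, file I/O and acquisition-metadata arithmetic.

An :class:`ImageVolume` is the in-memory container shared by every metric in the
package: a 3-D grid of Hounsfield units indexed ``(slice, row, col)`` together
with its physical voxel spacing.  In-plane physical coordinates are expressed in
millimetres with the origin at the image centre (a proxy for the CT isocentre):
pixel ``(row, col)`` has its centre at

    x = (col - (ncols - 1)/2) * dx,        y = ((nrows - 1)/2 - row) * dy,

so +x points right and +y points up, matching the clock-position conventions of
phantom QA protocols ("12 o'clock" is +y).

On-disk format: multi-page TIFF (float32) with a JSON sidecar carrying the
spacings and acquisition metadata.  DICOM series can be read when ``pydicom`` is
installed; it is an optional dependency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

__all__ = [
    "CTIQError",
    "FormatError",
    "ROIError",
    "AcquisitionMeta",
    "ImageVolume",
    "CircularROI",
    "effective_mas",
    "rescale_to_hu",
    "extract_roi_pixels",
    "roi_mask",
    "read_volume",
    "write_volume",
]


class CTIQError(ValueError):
    """Base class for domain errors raised by this package."""


class FormatError(CTIQError):
    """Raised for unreadable, inconsistent or incomplete image files."""


class ROIError(CTIQError):
    """Raised when a region of interest is invalid or out of bounds."""


@dataclass
class AcquisitionMeta:
    """Scan parameters relevant to dose and QA bookkeeping.

    ``tube_current`` in mA, ``rotation_time`` in s, ``pitch`` is the
    dimensionless helical pitch, ``kvp`` in kV and ``ctdi_vol`` in mGy.
    ``mode_label`` is free text (e.g. NR / HR / SHR / MDCT).
    """

    tube_current: float = 0.0
    rotation_time: float = 1.0
    pitch: float = 1.0
    kvp: float = 120.0
    ctdi_vol: Optional[float] = None
    mode_label: str = ""

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise CTIQError(f"pitch must be > 0, got {self.pitch}")
        if self.rotation_time <= 0:
            raise CTIQError(f"rotation_time must be > 0, got {self.rotation_time}")
        if self.tube_current < 0:
            raise CTIQError(f"tube_current must be >= 0, got {self.tube_current}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**d)


def effective_mas(meta: AcquisitionMeta) -> float:
    """Effective tube-current-time product, mAs: ``mA * rotation time / pitch``.

    For a helical scan the pitch divides the plain mAs because overlapping
    rotations re-irradiate each z position.  Example: 260 mA, 0.5 s rotation,
    pitch 0.813 gives 159.9 mAs (160 after rounding).
    """
    if meta.pitch <= 0:
        raise CTIQError("pitch must be > 0 to compute effective mAs")
    return meta.tube_current * meta.rotation_time / meta.pitch


def rescale_to_hu(raw: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Apply the linear stored-value -> HU rescale ``HU = slope * raw + intercept``."""
    return np.asarray(raw, dtype=float) * float(slope) + float(intercept)


@dataclass
class ImageVolume:
    """A stack of reconstructed CT slices in HU with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values; stored as float internally.
    dx, dy : float
        In-plane pixel spacing along columns / rows, mm.
    dz : float
        Slice increment, mm.
    origin_z : float
        z position of the first slice, mm.
    meta : AcquisitionMeta, optional
    """

    voxels: np.ndarray
    dx: float
    dy: float
    dz: float
    origin_z: float = 0.0
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise CTIQError(
                f"voxels must be 3-D (slice, row, col), got ndim={self.voxels.ndim}"
            )
        if self.voxels.size == 0:
            raise CTIQError("voxels must be non-empty")
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise CTIQError(f"{name} must be strictly positive, got {v}")
        if not np.all(np.isfinite(self.voxels)):
            raise CTIQError("voxels contain non-finite values")

    # -- geometry ---------------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[2]

    @property
    def nyquist(self) -> float:
        """In-plane Nyquist frequency 1/(2*max(dx, dy)), lp/mm."""
        return 1.0 / (2.0 * max(self.dx, self.dy))

    def z_positions(self) -> np.ndarray:
        return self.origin_z + self.dz * np.arange(self.n_slices)

    def x_coords(self) -> np.ndarray:
        """Physical x (mm) of pixel-column centres; origin at the image centre."""
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.dx

    def y_coords(self) -> np.ndarray:
        """Physical y (mm) of pixel-row centres; +y is up (row 0 on top)."""
        return ((self.n_rows - 1) / 2.0 - np.arange(self.n_rows)) * self.dy

    def phys_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Map physical (x, y) mm to fractional (row, col)."""
        col = x / self.dx + (self.n_cols - 1) / 2.0
        row = (self.n_rows - 1) / 2.0 - y / self.dy
        return row, col


@dataclass
class CircularROI:
    """A circular region of interest in physical in-plane coordinates.

    ``cx, cy`` in mm relative to the image centre, ``diameter`` in mm.
    Either a single ``slice_index`` or an inclusive ``slice_range``
    ``(first, last)`` selects the slices the ROI applies to.
    """

    cx: float = 0.0
    cy: float = 0.0
    diameter: float = 10.0
    slice_index: Optional[int] = None
    slice_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ROIError(f"ROI diameter must be > 0, got {self.diameter}")
        if self.slice_index is not None and self.slice_range is not None:
            raise ROIError("give either slice_index or slice_range, not both")

    def slices(self, vol: ImageVolume) -> range:
        if self.slice_range is not None:
            lo, hi = self.slice_range
            if lo < 0 or hi >= vol.n_slices or lo > hi:
                raise ROIError(f"slice_range {self.slice_range} outside volume")
            return range(lo, hi + 1)
        idx = 0 if self.slice_index is None else self.slice_index
        if idx < 0 or idx >= vol.n_slices:
            raise ROIError(f"slice_index {idx} outside volume")
        return range(idx, idx + 1)


def roi_mask(vol: ImageVolume, roi: CircularROI) -> np.ndarray:
    """Boolean in-plane mask of pixels whose centre lies within the ROI circle.

    Membership is inclusive: a pixel centre exactly on the boundary counts.
    Raises :class:`ROIError` if the circle extends beyond the pixel-centre grid.
    """
    r = roi.diameter / 2.0
    x = vol.x_coords()
    y = vol.y_coords()
    if (roi.cx - r < x[0] - vol.dx / 2 or roi.cx + r > x[-1] + vol.dx / 2
            or roi.cy - r < y[-1] - vol.dy / 2 or roi.cy + r > y[0] + vol.dy / 2):
        raise ROIError(
            f"ROI (cx={roi.cx}, cy={roi.cy}, d={roi.diameter}) extends outside image"
        )
    xx, yy = np.meshgrid(x, y)
    return (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= r * r + 1e-12


def extract_roi_pixels(vol: ImageVolume, roi: CircularROI) -> np.ndarray:
    """HU values of all pixels inside the ROI, concatenated over its slices."""
    mask = roi_mask(vol, roi)
    if not mask.any():
        raise ROIError("ROI contains no pixel centres")
    return np.concatenate([vol.voxels[k][mask] for k in roi.slices(vol)])


# ---------------------------------------------------------------------------
# File I/O: TIFF + JSON sidecar (canonical), DICOM series (optional read)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: ImageVolume, path: str | Path, format: str = "tiff") -> list[Path]:
    """Write a volume to disk; returns the paths written.

    Only the TIFF + JSON-sidecar format is supported for writing.  Voxels are
    stored as float32 pages, lossless for integer HU; spacings are stored in
    the sidecar with full double precision.
    """
    if format not in ("tiff", "tif"):
        raise FormatError(f"unsupported write format {format!r}; use 'tiff'")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.voxels.astype(np.float32),
                     photometric="minisblack")
    side = {
        "dx": vol.dx,
        "dy": vol.dy,
        "dz": vol.dz,
        "origin_z": vol.origin_z,
        "meta": vol.meta.to_dict(),
    }
    sc = _sidecar_path(path)
    sc.write_text(json.dumps(side, indent=1, sort_keys=True))
    return [path, sc]


def _read_tiff(path: Path) -> ImageVolume:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(
            f"missing sidecar {sc.name}: non-DICOM input needs dx/dy/dz spacing"
        )
    side = json.loads(sc.read_text())
    for key in ("dx", "dy", "dz"):
        if key not in side:
            raise FormatError(f"sidecar {sc.name} missing required field {key!r}")
    meta = AcquisitionMeta.from_dict(side.get("meta", {}))
    return ImageVolume(arr, side["dx"], side["dy"], side["dz"],
                       origin_z=side.get("origin_z", 0.0), meta=meta)


def _read_dicom_series(path: Path) -> ImageVolume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError(
            "reading DICOM series requires the optional dependency 'pydicom'"
        ) from exc
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    spacings = {tuple(float(v) for v in d.PixelSpacing) for d in datasets}
    if len(spacings) != 1:
        raise FormatError(f"inconsistent PixelSpacing across series: {sorted(spacings)}")
    dy, dx = spacings.pop()  # DICOM PixelSpacing is (row, col)
    zs = [float(d.ImagePositionPatient[2]) for d in datasets]
    dz = float(np.diff(zs).mean()) if len(zs) > 1 else float(
        getattr(datasets[0], "SliceThickness", 0) or 0)
    if dz <= 0:
        raise FormatError("cannot determine slice increment from DICOM series")
    slices = []
    for d in datasets:
        slope = float(getattr(d, "RescaleSlope", 1.0))
        inter = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(rescale_to_hu(d.pixel_array, slope, inter))
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice dimensions across series: {sorted(shapes)}")
    return ImageVolume(np.stack(slices), dx, dy, dz, origin_z=zs[0])


def _read_raw(path: Path) -> ImageVolume:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"raw stack needs a sidecar {sc.name} with shape/dtype/spacing")
    side = json.loads(sc.read_text())
    for key in ("shape", "dtype", "dx", "dy", "dz"):
        if key not in side:
            raise FormatError(f"sidecar {sc.name} missing required field {key!r}")
    arr = np.fromfile(path, dtype=np.dtype(side["dtype"])).reshape(side["shape"])
    arr = rescale_to_hu(arr, side.get("rescale_slope", 1.0),
                        side.get("rescale_intercept", 0.0))
    meta = AcquisitionMeta.from_dict(side.get("meta", {}))
    return ImageVolume(arr, side["dx"], side["dy"], side["dz"],
                       origin_z=side.get("origin_z", 0.0), meta=meta)


def read_volume(path: str | Path, format_hint: Optional[str] = None) -> ImageVolume:
    """Read a CT volume in HU from a DICOM directory, TIFF stack or raw stack.

    DICOM rescale slope/intercept are applied and slices sorted by physical z.
    Non-DICOM inputs require a JSON sidecar ``<file>.<ext>.json`` giving at
    least ``dx``, ``dy`` and ``dz`` (mm).
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix.lower() in (".tif", ".tiff"):
            fmt = "tiff"
        elif path.suffix.lower() == ".raw":
            fmt = "raw"
        else:
            raise FormatError(f"cannot infer format of {path}; pass format_hint")
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt in ("tiff", "tif"):
        return _read_tiff(path)
    if fmt == "raw":
        return _read_raw(path)
    raise FormatError(f"unknown format {fmt!r}")
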