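"""Read and write CT DICOM series and convert slices to 8-bit PNG.

A CT series is one DICOM file per axial slice.  Only the header fields the
pipeline actually consumes are modelled: image rows/columns, in-plane pixel
spacing (mm/px), slice thickness (mm), the slice's position in the stack and
the linear rescale from stored pixel values to Hounsfield units (HU),
``HU = stored * RescaleSlope + RescaleIntercept``.

Voxel index convention, shared package-wide: arrays are indexed
``(row, col, slice)``, 0-based, with row = image Y (top to bottom) and
col = image X (left to right).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from PIL import Image

logger = logging.getLogger(__name__)

_SPACING_ATOL = 1e-6


@dataclass(frozen=True)
class SliceMeta:
    """Per-slice geometry and rescale metadata extracted from the header."""

    rows: int
    cols: int
    pixel_spacing_x: float  # mm per pixel along image X (columns)
    pixel_spacing_y: float  # mm per pixel along image Y (rows)
    slice_thickness: float  # mm along the scan axis
    slice_index: int
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.pixel_spacing_x <= 0 or self.pixel_spacing_y <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


@dataclass
class VolumeGrid:
    """HU voxel volume indexed (row, col, slice) with per-slice metadata.

    All slices of a valid series share rows/cols/spacing/thickness; the
    meta list is ordered by ascending slice_index and voxels are already
    rescaled to HU.
    """

    voxels: np.ndarray
    meta: list[SliceMeta]
    series_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (row, col, slice) array")
        if len(self.meta) != self.voxels.shape[2]:
            raise ValueError(
                f"meta length {len(self.meta)} does not match slice count "
                f"{self.voxels.shape[2]}"
            )
        m0 = self.meta[0]
        for m in self.meta:
            if (m.rows, m.cols) != (self.voxels.shape[0], self.voxels.shape[1]):
                raise ValueError("slice meta rows/cols do not match voxel array")
            if not (
                np.isclose(m.pixel_spacing_x, m0.pixel_spacing_x, atol=_SPACING_ATOL)
                and np.isclose(m.pixel_spacing_y, m0.pixel_spacing_y, atol=_SPACING_ATOL)
                and np.isclose(m.slice_thickness, m0.slice_thickness, atol=_SPACING_ATOL)
            ):
                raise ValueError("heterogeneous series: spacing/thickness differ across slices")
        idx = [m.slice_index for m in self.meta]
        if len(set(idx)) != len(idx):
            raise ValueError("slice_index values must be unique")
        if idx != sorted(idx):
            raise ValueError("meta must be ordered by ascending slice_index")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(dx, dy, dz) in mm: pixel spacing X, Y and slice thickness."""
        m = self.meta[0]
        return (m.pixel_spacing_x, m.pixel_spacing_y, m.slice_thickness)


def _require_tag(ds: pydicom.Dataset, name: str, path: Path):
    if name not in ds:
        raise ValueError(f"incomplete header: {path.name} is missing {name}")
    return ds.get(name)


def read_series(directory: str | Path) -> VolumeGrid:
    """Read every DICOM file in *directory* into an HU volume.

    Slices are sorted by the slice-position tag (ImagePositionPatient z,
    falling back to SliceLocation, then InstanceNumber) and stored voxel
    values are rescaled to HU.  Raises ``ValueError`` for an empty
    directory ("no series found"), for slices whose geometry disagrees
    ("heterogeneous series") and for missing spacing/thickness tags
    ("incomplete header").
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.glob("*") if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:  # non-DICOM stray file
            continue
        datasets.append((p, ds))
    if not datasets:
        raise ValueError(f"no series found in {directory}")

    def sort_key(item):
        _, ds = item
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        if "SliceLocation" in ds:
            return float(ds.SliceLocation)
        return float(ds.get("InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    metas = []
    for k, (p, ds) in enumerate(datasets):
        rows = int(_require_tag(ds, "Rows", p))
        cols = int(_require_tag(ds, "Columns", p))
        spacing = _require_tag(ds, "PixelSpacing", p)
        thickness = float(_require_tag(ds, "SliceThickness", p))
        if "RescaleSlope" in ds and "RescaleIntercept" in ds:
            slope = float(ds.RescaleSlope)
            intercept = float(ds.RescaleIntercept)
        else:
            warnings.warn(
                f"{p.name}: rescale tags absent, assuming slope=1 intercept=0",
                stacklevel=2,
            )
            slope, intercept = 1.0, 0.0
        # PixelSpacing is (row spacing, col spacing) = (dy, dx)
        meta = SliceMeta(
            rows=rows,
            cols=cols,
            pixel_spacing_x=float(spacing[1]),
            pixel_spacing_y=float(spacing[0]),
            slice_thickness=thickness,
            slice_index=k,
            rescale_slope=slope,
            rescale_intercept=intercept,
        )
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        if hu.shape != (rows, cols):
            raise ValueError(f"heterogeneous series: {p.name} pixel data shape mismatch")
        slices.append(hu)
        metas.append(meta)

    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError("heterogeneous series: rows/cols differ across slices")
    m0 = metas[0]
    for m in metas:
        if not (
            np.isclose(m.pixel_spacing_x, m0.pixel_spacing_x, atol=_SPACING_ATOL)
            and np.isclose(m.pixel_spacing_y, m0.pixel_spacing_y, atol=_SPACING_ATOL)
            and np.isclose(m.slice_thickness, m0.slice_thickness, atol=_SPACING_ATOL)
        ):
            raise ValueError("heterogeneous series: spacing/thickness differ across slices")

    voxels = np.stack(slices, axis=2)
    ds0 = datasets[0][1]
    series_uid = str(ds0.get("SeriesDescription", "") or ds0.get("SeriesInstanceUID", ""))
    logger.info("read_series: %d slices of %dx%d from %s", len(metas), m0.rows, m0.cols, directory)
    return VolumeGrid(voxels=voxels, meta=metas, series_id=series_uid)


def write_series(volume: VolumeGrid, directory: str | Path) -> list[Path]:
    """Write *volume* as one CT DICOM file per slice.

    HU values are stored as unsigned 16-bit with slope 1 / intercept −1024,
    so ``read_series(write_series(v))`` reproduces the voxels exactly for
    integer-valued HU volumes (CT HU are integral in practice).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    intercept = -1024.0
    stored = np.round(volume.voxels - intercept)
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError("HU values outside the storable range [-1024, 64511]")
    stored = stored.astype(np.uint16)

    written = []
    for k, meta in enumerate(volume.meta):
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = CTImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid()
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=file_meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        if volume.series_id:
            ds.SeriesDescription = volume.series_id
        ds.Modality = "CT"
        ds.Rows = meta.rows
        ds.Columns = meta.cols
        ds.PixelSpacing = [meta.pixel_spacing_y, meta.pixel_spacing_x]
        ds.SliceThickness = meta.slice_thickness
        ds.InstanceNumber = meta.slice_index + 1
        z = meta.slice_index * meta.slice_thickness
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = z
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0  # unsigned
        ds.PixelData = np.ascontiguousarray(stored[:, :, k]).tobytes()

        path = directory / f"slice_{meta.slice_index:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        written.append(path)
    logger.info("write_series: wrote %d slices to %s", len(written), directory)
    return written


def to_png(
    volume: VolumeGrid,
    directory: str | Path,
    window: tuple[float, float] = (-200.0, 1800.0),
) -> list[Path]:
    """Convert each slice to an 8-bit greyscale PNG using an HU window.

    HU at or below ``window[0]`` map to 0, at or above ``window[1]`` to 255,
    linearly in between with round-half-away-from-zero, so the window
    midpoint maps to 128.  Filenames encode the slice index and sort
    lexically in slice order.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window: need lower < upper, got {window}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for k, meta in enumerate(volume.meta):
        scaled = (volume.voxels[:, :, k] - lo) / (hi - lo) * 255.0
        # round half away from zero (values are non-negative after clipping)
        img = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8)
        path = directory / f"slice_{meta.slice_index:04d}.png"
        Image.fromarray(img, mode="L").save(path)
        written.append(path)
    return written


def png_window_for(volume: VolumeGrid) -> tuple[float, float]:
    """Default bone-visualisation window spanning soft tissue to cortical bone."""
    return (-200.0, 1800.0)
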