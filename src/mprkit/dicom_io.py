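"""Reading and writing single-frame CT DICOM series.

Only uncompressed (explicit/implicit VR little endian), single-frame CT
objects are supported: the reconstruction pipeline needs pixels and
geometry, not codec breadth.  Stored pixel values are kept as integers;
conversion to Hounsfield units via the modality rescale is an explicit,
separate step (`apply_rescale`), so interpolation operates on stored
values exactly as a viewer pipeline does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from mprkit.errors import (
    InconsistentSeriesError,
    NoDicomInputError,
    ParameterError,
    UnsupportedDicomError,
)

log = logging.getLogger(__name__)

_ORIENT_TOL = 1e-4


@dataclass
class SliceRecord:
    """One parsed axial DICOM slice: pixel matrix plus geometry/display metadata.

    ``pixel_matrix`` holds raw stored values (no modality rescale applied).
    Optional DICOM attributes that are absent in the file are ``None`` —
    never silently defaulted; downstream fallbacks are decided by the
    geometry stage.
    """

    pixel_matrix: np.ndarray
    image_position: tuple[float, float, float] | None
    orientation: tuple[float, float, float, float, float, float]
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float | None = None
    spacing_between_slices: float | None = None
    instance_number: int | None = None
    slice_location: float | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    window_center: float | None = None
    window_width: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixel_matrix = np.asarray(self.pixel_matrix)
        if self.pixel_matrix.ndim != 2 or self.pixel_matrix.size == 0:
            raise ValueError("pixel_matrix must be a nonempty 2D array")
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise ValueError("pixel spacings must be positive")
        r = np.asarray(self.orientation[:3], dtype=float)
        c = np.asarray(self.orientation[3:], dtype=float)
        if abs(np.linalg.norm(r) - 1.0) > _ORIENT_TOL or abs(np.linalg.norm(c) - 1.0) > _ORIENT_TOL:
            raise ValueError("orientation triplets must have unit norm")
        if abs(float(np.dot(r, c))) > _ORIENT_TOL:
            raise ValueError("orientation triplets must be orthogonal")

    @property
    def rows(self) -> int:
        return self.pixel_matrix.shape[0]

    @property
    def cols(self) -> int:
        return self.pixel_matrix.shape[1]


def _get(ds: Dataset, keyword: str, default=None):
    value = getattr(ds, keyword, None)
    return default if value is None else value


def _first(value):
    # Window Center/Width may be multi-valued; the first entry is the
    # primary preset.
    try:
        return float(value[0])
    except (TypeError, IndexError):
        return float(value)


def record_from_dataset(ds: Dataset, source_path: str = "") -> SliceRecord:
    """Build a SliceRecord from an in-memory pydicom dataset."""
    n_frames = int(_get(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise UnsupportedDicomError(
            f"{source_path or '<dataset>'}: multi-frame objects are not supported"
        )
    position = _get(ds, "ImagePositionPatient")
    orientation = _get(ds, "ImageOrientationPatient")
    spacing = _get(ds, "PixelSpacing")
    if orientation is None or spacing is None:
        raise UnsupportedDicomError(
            f"{source_path or '<dataset>'}: missing orientation or pixel spacing"
        )
    wc = _get(ds, "WindowCenter")
    ww = _get(ds, "WindowWidth")
    thickness = _get(ds, "SliceThickness")
    between = _get(ds, "SpacingBetweenSlices")
    instance = _get(ds, "InstanceNumber")
    location = _get(ds, "SliceLocation")
    return SliceRecord(
        pixel_matrix=ds.pixel_array,
        image_position=None if position is None else tuple(float(x) for x in position),
        orientation=tuple(float(x) for x in orientation),
        # DICOM Pixel Spacing is (row spacing, column spacing)
        pixel_spacing_row=float(spacing[0]),
        pixel_spacing_col=float(spacing[1]),
        slice_thickness=None if thickness is None else float(thickness),
        spacing_between_slices=None if between is None else float(between),
        instance_number=None if instance is None else int(instance),
        slice_location=None if location is None else float(location),
        rescale_slope=float(_get(ds, "RescaleSlope", 1.0)),
        rescale_intercept=float(_get(ds, "RescaleIntercept", 0.0)),
        window_center=None if wc is None else _first(wc),
        window_width=None if ww is None else _first(ww),
        source_path=source_path,
    )


def read_series(directory: str | Path) -> list[SliceRecord]:
    """Read every valid single-frame DICOM file in *directory*.

    Files are visited in sorted-name order (discovery order); slices are
    never reordered or dropped beyond skipping non-DICOM files, which are
    logged as warnings.  Raises NoDicomInputError if nothing readable is
    found and InconsistentSeriesError on mixed matrix dimensions.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NoDicomInputError(f"no DICOM input: {directory} is not a directory")
    records: list[SliceRecord] = []
    for path in sorted(p for p in directory.iterdir() if p.is_file()):
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, ValueError, OSError):
            log.warning("skipping non-DICOM file %s", path)
            continue
        tsyntax = getattr(ds.file_meta, "TransferSyntaxUID", None)
        if tsyntax is not None and tsyntax.is_compressed:
            raise UnsupportedDicomError(
                f"{path}: compressed transfer syntax {tsyntax} is not supported"
            )
        records.append(record_from_dataset(ds, source_path=str(path)))
    if not records:
        raise NoDicomInputError(f"no DICOM input in {directory}")
    shapes = {rec.pixel_matrix.shape for rec in records}
    if len(shapes) > 1:
        raise InconsistentSeriesError(
            f"inconsistent series: matrix dimensions {sorted(shapes)}"
        )
    return records


def _deterministic_uid(*parts) -> str:
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def write_series(slices: list[SliceRecord], directory: str | Path) -> list[Path]:
    """Write one uncompressed little-endian DICOM part-10 file per slice.

    Round-trip guarantee: ``read_series(write_series(x))`` reproduces every
    SliceRecord field, including absence of optional tags.
    """
    if not slices:
        raise ParameterError("write_series: empty slice list")
    shapes = {rec.pixel_matrix.shape for rec in slices}
    if len(shapes) > 1:
        raise InconsistentSeriesError("write_series: inconsistent matrix dimensions")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    series_uid = _deterministic_uid("series", len(slices), slices[0].pixel_matrix.tobytes())
    study_uid = _deterministic_uid("study", series_uid)
    paths: list[Path] = []
    for idx, rec in enumerate(slices):
        sop_uid = _deterministic_uid(series_uid, idx)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.ImageOrientationPatient = [f"{x:.10g}" for x in rec.orientation]
        ds.PixelSpacing = [f"{rec.pixel_spacing_row:.10g}", f"{rec.pixel_spacing_col:.10g}"]
        if rec.image_position is not None:
            ds.ImagePositionPatient = [f"{x:.10g}" for x in rec.image_position]
        if rec.slice_thickness is not None:
            ds.SliceThickness = f"{rec.slice_thickness:.10g}"
        if rec.spacing_between_slices is not None:
            ds.SpacingBetweenSlices = f"{rec.spacing_between_slices:.10g}"
        if rec.instance_number is not None:
            ds.InstanceNumber = rec.instance_number
        if rec.slice_location is not None:
            ds.SliceLocation = f"{rec.slice_location:.10g}"
        if rec.window_center is not None:
            ds.WindowCenter = f"{rec.window_center:.10g}"
        if rec.window_width is not None:
            ds.WindowWidth = f"{rec.window_width:.10g}"
        ds.RescaleSlope = f"{rec.rescale_slope:.10g}"
        ds.RescaleIntercept = f"{rec.rescale_intercept:.10g}"

        pixels = np.asarray(rec.pixel_matrix)
        if not np.issubdtype(pixels.dtype, np.integer):
            raise ParameterError("write_series: pixel matrices must be integer-typed")
        if pixels.min() < -32768 or pixels.max() > 32767:
            raise ParameterError("write_series: stored values exceed int16 range")
        pixels = pixels.astype(np.int16)
        ds.Rows, ds.Columns = pixels.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = pixels.tobytes()

        path = directory / f"slice_{idx:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def apply_rescale(stored_value, slope: float, intercept: float):
    """Modality LUT: stored value -> Hounsfield units (value*slope + intercept)."""
    if slope == 0 or not math.isfinite(slope):
        raise ParameterError("invalid rescale slope")
    return stored_value * slope + intercept
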