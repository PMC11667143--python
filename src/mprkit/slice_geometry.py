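"""Slice ordering, spacing classification and z-step planning.

Slices are ordered along the scan axis by the signed projection of
Image Position (Patient) onto the stack normal (robust to oblique
acquisitions); ties are broken by instance number, then slice location.
Every inter-slice interval is then classified as contiguous, gap, or
overlap relative to the series' nominal spacing, and a BuildPlan maps
the acquired slice count onto a requested output depth (the "z step").

Nominal spacing: the smallest positive value among the Spacing Between
Slices tag and the Slice Thickness tag, falling back to the median
observed interval.  Taking the minimum handles the two degenerate tag
regimes seen in clinical peripheral-artery CT: a spacing tag of 0 with
5 mm slices (thickness wins), and 0.625 mm slices acquired every 5 mm,
where the pitch exceeds the slab width and every interval is a physical
gap that volume building must fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mprkit.dicom_io import SliceRecord
from mprkit.errors import (
    EmptySeriesError,
    GeometryError,
    InsufficientSeriesError,
    MixedOrientationError,
    ParameterError,
)

CONTIGUOUS = "contiguous"
GAP = "gap"
OVERLAP = "overlap"

#: default interval tolerance: 1% of nominal spacing, floored at 0.01 mm
DEFAULT_TOL_FRACTION = 0.01
DEFAULT_TOL_FLOOR_MM = 0.01


@dataclass
class SeriesGeometry:
    """Ordered slices with per-interval spacing classification."""

    slices: list[SliceRecord]
    normal: np.ndarray
    z_positions: np.ndarray
    nominal_spacing: float
    interval_labels: list[str] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class BuildPlan:
    """How an acquired slice count expands to the requested volume depth.

    z_step is the expansion factor (output planes per input slice);
    planes_per_interval[i] synthesized planes are inserted between input
    planes i and i+1 so that n_files + sum(planes_per_interval) equals
    target_depth exactly (remainder goes to the last interval).
    """

    z_step: float
    target_depth: int
    planes_per_interval: list[int]


def slice_normal(orientation) -> np.ndarray:
    """Unit normal of a slice: row axis x column axis."""
    row = np.asarray(orientation[:3], dtype=float)
    col = np.asarray(orientation[3:6], dtype=float)
    n = np.cross(row, col)
    norm = np.linalg.norm(n)
    if norm < 1e-6:
        raise GeometryError("degenerate orientation: row and column axes are parallel")
    return n / norm


def default_tolerance(nominal_spacing: float) -> float:
    return max(DEFAULT_TOL_FRACTION * nominal_spacing, DEFAULT_TOL_FLOOR_MM)


def _nominal_spacing(slices: list[SliceRecord], z: np.ndarray | None) -> float:
    candidates = []
    for rec in slices:
        if rec.spacing_between_slices is not None and rec.spacing_between_slices > 0:
            candidates.append(rec.spacing_between_slices)
        if rec.slice_thickness is not None and rec.slice_thickness > 0:
            candidates.append(rec.slice_thickness)
    if candidates:
        return float(min(candidates))
    if z is not None and len(z) >= 2:
        dz = np.diff(z)
        dz = dz[dz > 0]
        if dz.size:
            return float(np.median(dz))
    raise GeometryError("cannot determine nominal spacing: no tags and no distinct positions")


def order_slices(slices: list[SliceRecord]) -> SeriesGeometry:
    """Sort slices along the stack normal and classify their intervals.

    Primary key: signed projected distance z = position . normal; ties by
    instance number, then slice location.  When Image Position is absent
    the chain falls back to instance number, then slice location.
    """
    if len(slices) < 2:
        raise InsufficientSeriesError("insufficient series: need >= 2 slices")

    normals = [slice_normal(rec.orientation) for rec in slices]
    normal = normals[0]
    for n in normals[1:]:
        if np.linalg.norm(n - normal) > 1e-3:
            raise MixedOrientationError("mixed orientation within series")

    have_positions = all(rec.image_position is not None for rec in slices)

    def z_of(rec: SliceRecord) -> float:
        return float(np.dot(np.asarray(rec.image_position, dtype=float), normal))

    big = float("inf")
    if have_positions:
        def key(rec: SliceRecord):
            return (
                z_of(rec),
                rec.instance_number if rec.instance_number is not None else big,
                rec.slice_location if rec.slice_location is not None else big,
            )
    else:
        def key(rec: SliceRecord):
            return (
                rec.instance_number if rec.instance_number is not None else big,
                rec.slice_location if rec.slice_location is not None else big,
            )

    ordered = sorted(slices, key=key)

    if have_positions:
        z = np.array([z_of(rec) for rec in ordered])
    elif all(rec.slice_location is not None for rec in ordered):
        z = np.array([float(rec.slice_location) for rec in ordered])
        if np.any(np.diff(z) < 0):
            # locations disagree with the instance ordering; fall through to ordinals
            z = None
    else:
        z = None

    nominal = _nominal_spacing(ordered, z)
    if z is None:
        z = np.arange(len(ordered), dtype=float) * nominal

    geometry = SeriesGeometry(
        slices=ordered, normal=normal, z_positions=z, nominal_spacing=nominal
    )
    geometry.interval_labels = classify_intervals(geometry)
    return geometry


def classify_intervals(geometry: SeriesGeometry, tolerance: float | None = None) -> list[str]:
    """Label each interval dz = z[i+1]-z[i] as contiguous / gap / overlap.

    contiguous if |dz - nominal| <= tol; gap if dz > nominal + tol;
    overlap if dz < nominal - tol (including dz = 0 duplicates).
    """
    if tolerance is None:
        tolerance = default_tolerance(geometry.nominal_spacing)
    nominal = geometry.nominal_spacing
    labels = []
    for dz in np.diff(geometry.z_positions):
        if dz < 0:
            raise GeometryError("internal invariant violation: negative interval after ordering")
        if dz > nominal + tolerance:
            labels.append(GAP)
        elif dz < nominal - tolerance:
            labels.append(OVERLAP)
        else:
            labels.append(CONTIGUOUS)
    geometry.interval_labels = labels
    return labels


def compute_z_step(n_files: int, target_depth: int) -> BuildPlan:
    """Derive the z step and per-interval plane counts for a target depth.

    Zero input files is an explicitly handled error; when the file count
    already matches the requested z dimension the z step is 1 and no
    planes are synthesized.  Otherwise planes are distributed uniformly,
    with the remainder absorbed by the last interval so that
    n_files + sum(planes_per_interval) == target_depth exactly.
    """
    if target_depth < 1:
        raise ParameterError("target_depth must be >= 1")
    if n_files == 0:
        raise EmptySeriesError("empty series: 0 input files")
    if n_files == target_depth:
        return BuildPlan(z_step=1.0, target_depth=target_depth,
                         planes_per_interval=[0] * max(n_files - 1, 0))
    if target_depth < n_files:
        raise ParameterError(
            f"target_depth {target_depth} below slice count {n_files}: decimation unsupported"
        )
    if n_files == 1:
        raise ParameterError("cannot expand a single slice: no interval to interpolate")
    z_step = target_depth / n_files
    extra = target_depth - n_files
    n_intervals = n_files - 1
    per = extra // n_intervals
    planes = [per] * n_intervals
    planes[-1] += extra - per * n_intervals
    return BuildPlan(z_step=z_step, target_depth=target_depth, planes_per_interval=planes)
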