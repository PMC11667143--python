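"""Measurement tools and validation statistics.

The clinical tool set (length, angle, probe, ROI statistics) reports mm
and HU, never raw pixels: points are (row, col) pixel coordinates and
are converted to physical units through the view's spacings.

Validation machinery automates the manual cross-view accuracy protocol:
structure extents are located with half-maximum subpixel edge
localization on intensity profiles (the point where the profile crosses
midway between its extremes, linearly interpolated between samples), and
agreement between views is summarized as the mean absolute error
Error = (1/n) * sum |M_i - G_i| over paired measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from mprkit.dicom_io import SliceRecord, apply_rescale
from mprkit.errors import (
    BoundsError,
    EmptyRoiError,
    GeometryError,
    NoEdgesError,
    ParameterError,
    StructureNotFoundError,
)
from mprkit.mpr_views import ViewImage

RECTANGLE = "rectangle"
ELLIPSE = "ellipse"
FREEHAND = "freehand"


@dataclass
class MeasurementSet:
    """Paired measured/ground-truth values and their mean absolute error (mm)."""

    measured: list[float]
    ground_truth: list[float]

    def __post_init__(self) -> None:
        if len(self.measured) != len(self.ground_truth):
            raise ParameterError("measured and ground-truth lists differ in length")
        if not self.measured:
            raise ParameterError("need at least one measurement pair")

    @property
    def n(self) -> int:
        return len(self.measured)

    @property
    def error(self) -> float:
        """Mean absolute difference: (1/n) * sum |M_i - G_i|."""
        return float(
            np.mean(np.abs(np.asarray(self.measured) - np.asarray(self.ground_truth)))
        )


@dataclass
class RoiShape:
    """Rectangle/ellipse (two corner points) or freehand simple polygon (>=3 vertices).

    Vertices are (row, col) pixel coordinates.
    """

    kind: str
    vertices: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind in (RECTANGLE, ELLIPSE):
            if len(self.vertices) != 2:
                raise ParameterError(f"{self.kind} ROI needs exactly 2 corner points")
        elif self.kind == FREEHAND:
            if len(self.vertices) < 3:
                raise ParameterError("freehand ROI needs >= 3 vertices")
        else:
            raise ParameterError(f"unknown ROI kind {self.kind!r}")


def length(p1, p2, spacing_h: float, spacing_v: float) -> float:
    """Euclidean distance in mm between two (row, col) points."""
    if spacing_h <= 0 or spacing_v <= 0:
        raise ParameterError("spacings must be positive")
    dr = (p2[0] - p1[0]) * spacing_v
    dc = (p2[1] - p1[1]) * spacing_h
    return math.hypot(dr, dc)


def angle(p1, vertex, p2, spacing_h: float = 1.0, spacing_v: float = 1.0) -> float:
    """Interior angle at *vertex* in degrees, computed in physical coordinates."""
    a = np.array([(p1[0] - vertex[0]) * spacing_v, (p1[1] - vertex[1]) * spacing_h])
    b = np.array([(p2[0] - vertex[0]) * spacing_v, (p2[1] - vertex[1]) * spacing_h])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise GeometryError("angle arms must not coincide with the vertex")
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cos))


def probe(slice_record: SliceRecord, p) -> float:
    """HU value at the pixel nearest to (row, col) point *p*."""
    r, c = int(round(p[0])), int(round(p[1]))
    if not (0 <= r < slice_record.rows and 0 <= c < slice_record.cols):
        raise BoundsError(f"probe point {p} outside image")
    stored = int(slice_record.pixel_matrix[r, c])
    return float(
        apply_rescale(stored, slice_record.rescale_slope, slice_record.rescale_intercept)
    )


def roi_membership(shape: tuple[int, int], roi: RoiShape) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI."""
    n_rows, n_cols = shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    if roi.kind == RECTANGLE:
        (r1, c1), (r2, c2) = roi.vertices
        rlo, rhi = min(r1, r2), max(r1, r2)
        clo, chi = min(c1, c2), max(c1, c2)
        return (rr >= rlo) & (rr <= rhi) & (cc >= clo) & (cc <= chi)
    if roi.kind == ELLIPSE:
        (r1, c1), (r2, c2) = roi.vertices
        cr, ccen = (r1 + r2) / 2.0, (c1 + c2) / 2.0
        ar, ac = abs(r2 - r1) / 2.0, abs(c2 - c1) / 2.0
        if ar == 0 or ac == 0:
            return np.zeros(shape, dtype=bool)
        return ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0
    path = MplPath(np.asarray(roi.vertices, dtype=float))
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    return path.contains_points(pts).reshape(shape)


def roi_stats(
    image: np.ndarray, spacing_h: float, spacing_v: float, roi: RoiShape
) -> dict:
    """Statistics over pixels inside the ROI, plus physical area in mm^2."""
    image = np.asarray(image, dtype=float)
    mask = roi_membership(image.shape, roi)
    count = int(mask.sum())
    if count == 0:
        raise EmptyRoiError("empty ROI: no pixel centers inside shape")
    vals = image[mask]
    return {
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "area": count * spacing_h * spacing_v,
        "pixel_count": count,
    }


def error_margin(measured, ground_truth) -> MeasurementSet:
    """Mean absolute error between paired measured and ground-truth values."""
    return MeasurementSet(measured=list(map(float, measured)),
                          ground_truth=list(map(float, ground_truth)))


def locate_edges_subpixel(profile, spacing: float) -> list[float]:
    """Positions (mm) where the profile crosses its half-maximum level.

    The level is (min + max)/2; crossings are linearly interpolated
    between adjacent samples.  A flat profile has no edges.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise ParameterError("profile must have >= 2 samples")
    lo, hi = profile.min(), profile.max()
    if hi == lo:
        raise NoEdgesError("no edges: flat profile")
    level = 0.5 * (lo + hi)
    edges: list[float] = []
    for i in range(profile.size - 1):
        a, b = profile[i], profile[i + 1]
        if a == level and (not edges or edges[-1] != i * spacing):
            edges.append(i * spacing)
        if (a - level) * (b - level) < 0:
            frac = (level - a) / (b - a)
            edges.append((i + frac) * spacing)
    if profile[-1] == level:
        edges.append((profile.size - 1) * spacing)
    return edges


def measure_extent(view: ViewImage, axis: str, line_index: int) -> float:
    """Structure extent (mm) along one line of a view, first-to-last edge.

    axis "h": profile along a pixel row (line_index = row), using
    spacing_h; axis "v": profile along a column, using spacing_v.
    """
    if axis == "h":
        profile = view.pixels[line_index, :]
        spacing = view.spacing_h
    elif axis == "v":
        profile = view.pixels[:, line_index]
        spacing = view.spacing_v
    else:
        raise ParameterError("axis must be 'h' or 'v'")
    try:
        edges = locate_edges_subpixel(profile, spacing)
    except NoEdgesError as exc:
        raise StructureNotFoundError(f"structure not found: {exc}") from exc
    if len(edges) < 2:
        raise StructureNotFoundError("structure not found: fewer than 2 edges on profile")
    return edges[-1] - edges[0]
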