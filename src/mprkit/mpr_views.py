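"""Orthogonal view extraction and display transforms.

Views are exported unresampled: physical aspect is carried in the
per-axis spacings (mm/pixel) rather than baked in by resampling, so
measurements in mm stay exact.  Coordinate convention is 0-based
(row, col, plane); for a canonical axial acquisition the row axis
increases toward the patient's posterior.

Display transforms follow a clinical viewer: a linear window/level map
onto an 8-bit [0, 255] range, value inversion, and a magnifier built on
the same Catmull-Rom kernel used for inter-slice interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from mprkit.errors import BoundsError, GeometryError, ParameterError
from mprkit.volume_builder import VolumeGrid

AXIAL = "axial"
CORONAL = "coronal"
SAGITTAL = "sagittal"
PLANE_KINDS = (AXIAL, CORONAL, SAGITTAL)


@dataclass
class ViewImage:
    """A single extracted view: pixels plus physical pixel spacings.

    spacing_v is the mm size of one step down the pixel rows (vertical),
    spacing_h across the columns (horizontal).
    """

    pixels: np.ndarray
    spacing_h: float
    spacing_v: float
    plane_kind: str
    index: int


@dataclass
class ReferenceLine:
    """Intersection of a source plane drawn on an orthogonal target view."""

    view: str
    endpoints: tuple[tuple[float, float], tuple[float, float]]  # (row, col) pixel coords
    source_plane: tuple[str, int]


def _axis_len(volume: VolumeGrid, plane_kind: str) -> int:
    rows, cols, planes = volume.shape
    return {AXIAL: planes, CORONAL: rows, SAGITTAL: cols}[plane_kind]


def extract_plane(volume: VolumeGrid, plane_kind: str, index: int) -> ViewImage:
    """Slice the volume along one of the three anatomical planes.

    axial    -> voxels[:, :, index], (v, h) spacings (row, col)
    coronal  -> fixed row;    view[p, c] = voxels[index, c, p], spacings (plane, col)
    sagittal -> fixed column; view[p, r] = voxels[r, index, p], spacings (plane, row)
    """
    if plane_kind not in PLANE_KINDS:
        raise ParameterError(f"unknown plane kind {plane_kind!r}")
    if not 0 <= index < _axis_len(volume, plane_kind):
        raise BoundsError(f"{plane_kind} index {index} out of range")
    if plane_kind == AXIAL:
        pixels = volume.voxels[:, :, index]
        spacing_v, spacing_h = volume.spacing_row, volume.spacing_col
    elif plane_kind == CORONAL:
        pixels = volume.voxels[index, :, :].T  # (plane, col)
        spacing_v, spacing_h = volume.spacing_plane, volume.spacing_col
    else:
        pixels = volume.voxels[:, index, :].T  # (plane, row)
        spacing_v, spacing_h = volume.spacing_plane, volume.spacing_row
    return ViewImage(
        pixels=pixels,
        spacing_h=spacing_h,
        spacing_v=spacing_v,
        plane_kind=plane_kind,
        index=index,
    )


def reference_line(
    volume: VolumeGrid, source: tuple[str, int], target: str
) -> ReferenceLine:
    """Line where the *source* plane crosses the *target* view.

    Orthogonal anatomical planes always intersect in an axis-aligned
    segment; e.g. coronal plane r on an axial view is the horizontal line
    at row r.
    """
    source_kind, source_index = source
    if source_kind not in PLANE_KINDS or target not in PLANE_KINDS:
        raise ParameterError("unknown plane kind")
    if source_kind == target:
        raise GeometryError("parallel planes do not intersect in a line")
    if not 0 <= source_index < _axis_len(volume, source_kind):
        raise BoundsError(f"{source_kind} index {source_index} out of range")

    rows, cols, planes = volume.shape
    view_dims = {  # (n_view_rows, n_view_cols) per target
        AXIAL: (rows, cols),
        CORONAL: (planes, cols),
        SAGITTAL: (planes, rows),
    }
    n_rows, n_cols = view_dims[target]

    # Which view axis the source plane pins down, and at which coordinate.
    # Axial view axes: (row, col); coronal: (plane, col); sagittal: (plane, row).
    horizontal = {
        (CORONAL, AXIAL): True,    # row axis pinned -> horizontal line at row r
        (SAGITTAL, AXIAL): False,  # col axis pinned -> vertical line at col c
        (AXIAL, CORONAL): True,    # plane pinned -> horizontal at view row p
        (SAGITTAL, CORONAL): False,
        (AXIAL, SAGITTAL): True,
        (CORONAL, SAGITTAL): False,
    }[(source_kind, target)]
    if horizontal:
        endpoints = ((float(source_index), 0.0), (float(source_index), float(n_cols - 1)))
    else:
        endpoints = ((0.0, float(source_index)), (float(n_rows - 1), float(source_index)))
    return ReferenceLine(view=target, endpoints=endpoints, source_plane=source)


def apply_window(image: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear VOI window: [center - width/2, center + width/2] -> [0, 255].

    Values below the window map to 0, above to 255, linear in between;
    output is rounded half-even to uint8.
    """
    if width < 1:
        raise ParameterError("window width must be >= 1")
    image = np.asarray(image, dtype=float)
    lo = center - width / 2.0
    scaled = np.clip((image - lo) / width, 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def invert(display: np.ndarray) -> np.ndarray:
    """Invert an 8-bit display image: out = 255 - in."""
    display = np.asarray(display)
    if display.min() < 0 or display.max() > 255:
        raise ParameterError("invert expects display values in [0, 255]")
    return (255 - display.astype(np.int64)).astype(display.dtype)


def _cr_weight_matrix(coords: np.ndarray, n_src: int) -> np.ndarray:
    """Sparse-in-spirit Catmull-Rom sampling matrix W: out = W @ src.

    Row o holds the 4 kernel weights for source coordinate coords[o],
    with indices edge-clamped.
    """
    w = np.zeros((coords.size, n_src))
    base = np.floor(coords).astype(int)
    t = coords - base
    # Catmull-Rom weights for samples at offsets -1, 0, 1, 2
    w0 = 0.5 * (-t + 2 * t**2 - t**3)
    w1 = 0.5 * (2 - 5 * t**2 + 3 * t**3)
    w2 = 0.5 * (t + 4 * t**2 - 3 * t**3)
    w3 = 0.5 * (-(t**2) + t**3)
    for off, wk in zip((-1, 0, 1, 2), (w0, w1, w2, w3)):
        idx = np.clip(base + off, 0, n_src - 1)
        np.add.at(w, (np.arange(coords.size), idx), wk)
    return w


def magnify(
    image: np.ndarray,
    center: tuple[float, float],
    factor: float,
    output_size: int | tuple[int, int],
) -> np.ndarray:
    """Magnifier kernel: crop output_size/factor around *center*, upsample bicubically.

    *center* is a (row, col) point.  factor=1 with integral offsets is an
    identity crop; constants are reproduced for any factor.
    """
    if factor < 1:
        raise ParameterError("magnification factor must be >= 1")
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = image.shape
    cr, cc = center
    if not (0 <= cr < n_rows and 0 <= cc < n_cols):
        raise BoundsError("magnify center outside image")
    if isinstance(output_size, int):
        out_h = out_w = output_size
    else:
        out_h, out_w = output_size
    # source coordinate of output pixel o: center - extent/2 + (o + 0.5)/f - 0.5
    rows = cr - out_h / (2 * factor) + (np.arange(out_h) + 0.5) / factor - 0.5
    cols = cc - out_w / (2 * factor) + (np.arange(out_w) + 0.5) / factor - 0.5
    wr = _cr_weight_matrix(rows, n_rows)
    wc = _cr_weight_matrix(cols, n_cols)
    return wr @ image @ wc.T


def resample_isotropic(view: ViewImage) -> ViewImage:
    """Resample a view to square pixels at the finer of its two spacings."""
    target = min(view.spacing_h, view.spacing_v)
    n_rows, n_cols = view.pixels.shape
    out_h = max(int(round(n_rows * view.spacing_v / target)), 1)
    out_w = max(int(round(n_cols * view.spacing_h / target)), 1)
    rows = (np.arange(out_h) + 0.5) * (n_rows / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (n_cols / out_w) - 0.5
    wr = _cr_weight_matrix(rows, n_rows)
    wc = _cr_weight_matrix(cols, n_cols)
    return ViewImage(
        pixels=wr @ view.pixels @ wc.T,
        spacing_h=target,
        spacing_v=target,
        plane_kind=view.plane_kind,
        index=view.index,
    )


def save_view_png(display: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG."""
    path = Path(path)
    Image.fromarray(np.asarray(display, dtype=np.uint8), mode="L").save(path)
    return path
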