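"""Synthetic CT phantom generator with analytic ground truth.

Emits DICOM-ready slice series whose geometry mirrors the parameter
envelope of clinical peripheral-artery CT: 512x512 axial matrices
(64x64 scaled-down default so suites run in seconds), pixel spacing
around 0.78-0.98 mm, slice thickness 0.625-5.0 mm and spacing between
slices 0-5.0 mm, including contiguous, gapped, overlapping,
duplicate-slice and zero-spacing-tag configurations.

Inserts are analytic (block, sphere, linear gradient) sampled at voxel
centers, so the physical extents are known exactly and serve as ground
truth for measurement validation.  By default block edges are snapped to
the nearest half-pixel boundary (in-plane extents to a multiple of the
pixel spacing, the z extent to a multiple of the slice pitch), which
moves each edge by at most half a voxel and makes half-maximum
localization land exactly on the edge; the ``offgrid`` flag disables
snapping and adds a random sub-voxel shift for robustness tests, where
the edge estimate is only guaranteed to within one voxel per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from mprkit.dicom_io import SliceRecord
from mprkit.errors import NoDiscreteExtentsError, ParameterError

BLOCK = "block"
SPHERE = "sphere"
GRADIENT = "gradient"

CONTIGUOUS = "contiguous"
GAP = "gap"
OVERLAP = "overlap"
DUPLICATE = "duplicate"

#: stored values: +200 HU insert vs -1000 HU background under slope 1 / intercept -1024
DEFAULT_INSERT_VALUE = 1224
DEFAULT_BACKGROUND_VALUE = 24


@dataclass
class PhantomSpec:
    """Full description of a synthetic series; same seed => bit-identical output."""

    matrix: tuple[int, int] = (64, 64)
    n_slices: int = 40
    pixel_spacing: float = 0.9
    slice_thickness: float = 3.75
    spacing_between_slices: float | None = 3.75  # may be 0 or None (tag absent)
    insert: str = BLOCK
    insert_extents: tuple[float, float, float] = (20.0, 20.0, 15.0)
    insert_value: int = DEFAULT_INSERT_VALUE
    background_value: int = DEFAULT_BACKGROUND_VALUE
    noise_sigma: float = 0.0
    seed: int = 0
    spacing_mode: str = CONTIGUOUS
    gap_drop_every: int = 3
    offgrid: bool = False
    rescale_slope: float = 1.0
    rescale_intercept: float = -1024.0
    window_center: float = -400.0
    window_width: float = 1600.0

    def __post_init__(self) -> None:
        rows, cols = self.matrix
        if rows < 4 or cols < 4:
            raise ParameterError("phantom matrix must be at least 4x4")
        if self.n_slices < 1:
            raise ParameterError("need at least one slice")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ParameterError("spacings must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.insert not in (BLOCK, SPHERE, GRADIENT):
            raise ParameterError(f"unknown insert {self.insert!r}")
        if self.spacing_mode not in (CONTIGUOUS, GAP, OVERLAP, DUPLICATE):
            raise ParameterError(f"unknown spacing mode {self.spacing_mode!r}")
        if self.insert != GRADIENT:
            fov_x = cols * self.pixel_spacing
            fov_y = rows * self.pixel_spacing
            fov_z = self.pitch * self.n_slices
            ex, ey, ez = self.insert_extents
            if ex > fov_x or ey > fov_y or ez > fov_z:
                raise ParameterError(
                    f"insert extents {self.insert_extents} exceed field of view "
                    f"({fov_x:.1f}, {fov_y:.1f}, {fov_z:.1f}) mm"
                )

    @property
    def pitch(self) -> float:
        """Center-to-center z distance between consecutive acquired slices."""
        if self.spacing_between_slices is not None and self.spacing_between_slices > 0:
            return self.spacing_between_slices
        return self.slice_thickness


def _z_layout(spec: PhantomSpec, rng: np.random.Generator):
    """(z position, instance number) pairs per spacing mode."""
    pitch = spec.pitch
    base = [(k * pitch, k + 1) for k in range(spec.n_slices)]
    if spec.spacing_mode == CONTIGUOUS:
        return base
    if spec.spacing_mode == GAP:
        # Thin-slab regimes (thickness < pitch) are already physically gapped
        # by the acquisition; otherwise drop every k-th slice.
        if spec.slice_thickness < pitch - 1e-9:
            return base
        k = max(spec.gap_drop_every, 2)
        return [pair for i, pair in enumerate(base) if (i + 1) % k != 0]
    if spec.spacing_mode == OVERLAP:
        # extra slices at half-pitch offsets after every 4th slice
        out = list(base)
        next_instance = spec.n_slices + 1
        for i in range(3, spec.n_slices - 1, 4):
            out.append((base[i][0] + 0.5 * pitch, next_instance))
            next_instance += 1
        return sorted(out)
    # DUPLICATE: repeat every 5th slice at identical z with a later instance
    out = list(base)
    next_instance = spec.n_slices + 1
    for i in range(4, spec.n_slices, 5):
        out.append((base[i][0], next_instance))
        next_instance += 1
    return sorted(out)


def _snap_axis(extent: float, step: float, n: int) -> tuple[float, float]:
    """(snapped extent, center shift) placing both edges on voxel boundaries.

    The extent is rounded to the nearest positive multiple of *step*
    (moving it by at most step/2); when the rounded multiple's parity does
    not match the boundary grid of an n-sample axis, the insert center is
    shifted by step/2 so the edges still coincide with boundaries.
    """
    units = max(round(extent / step), 1)
    # boundary grid sits at (integer + b) * step from the axis center
    b = 0.0 if n % 2 == 0 else 0.5
    shift = ((b + units / 2.0) % 1.0) * step
    return units * step, shift


def effective_geometry(spec: PhantomSpec):
    """Block extents and center shifts as generated (grid-snapped unless offgrid)."""
    ex, ey, ez = spec.insert_extents
    if spec.offgrid or spec.insert != BLOCK:
        return (ex, ey, ez), (0.0, 0.0, 0.0)
    rows, cols = spec.matrix
    ps = spec.pixel_spacing
    (sx, cx) = _snap_axis(ex, ps, cols)
    (sy, cy) = _snap_axis(ey, ps, rows)
    (sz, cz) = _snap_axis(ez, spec.pitch, spec.n_slices)
    return (sx, sy, sz), (cx, cy, cz)


def effective_extents(spec: PhantomSpec) -> tuple[float, float, float]:
    """Block extents as generated: edge-snapped to voxel boundaries unless offgrid."""
    return effective_geometry(spec)[0]


def _insert_mask(spec: PhantomSpec, z: float, x: np.ndarray, y: np.ndarray,
                 shift: np.ndarray) -> np.ndarray:
    (ex, ey, ez), snap_shift = effective_geometry(spec)
    cx, cy, cz = np.asarray(shift) + np.asarray(snap_shift)
    z_mid = spec.pitch * (spec.n_slices - 1) / 2.0 + cz
    if spec.insert == BLOCK:
        return (
            (np.abs(x - cx) <= ex / 2.0)
            & (np.abs(y - cy) <= ey / 2.0)
            & (abs(z - z_mid) <= ez / 2.0)
        )
    # sphere: diameter = first extent
    d = ex
    return ((x - cx) ** 2 + (y - cy) ** 2 + (z - z_mid) ** 2) <= (d / 2.0) ** 2


def generate_phantom(spec: PhantomSpec) -> list[SliceRecord]:
    """Generate the axial slice series described by *spec*.

    Voxel value = insert_value where the voxel center lies inside the
    analytic insert, else background_value; Gaussian noise (stored-value
    units) is added with the spec's seed and clipped to the int16 range.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.matrix
    ps = spec.pixel_spacing
    # pixel-center coordinates, FOV centered on the origin
    x = (np.arange(cols) - (cols - 1) / 2.0) * ps  # column axis
    y = (np.arange(rows) - (rows - 1) / 2.0) * ps  # row axis
    xx, yy = np.meshgrid(x, y)

    if spec.offgrid:
        shift = rng.uniform(-0.5, 0.5, size=3) * ps
    else:
        shift = np.zeros(3)

    layout = _z_layout(spec, rng)
    slices: list[SliceRecord] = []
    for z, instance in layout:
        if spec.insert == GRADIENT:
            span = max((spec.n_slices - 1) * spec.pitch, 1.0)
            frac = (xx - x[0]) / max(x[-1] - x[0], ps) + z / span
            plane = spec.background_value + frac * (spec.insert_value - spec.background_value)
        else:
            mask = _insert_mask(spec, z, xx, yy, shift)
            plane = np.where(mask, float(spec.insert_value), float(spec.background_value))
        if spec.noise_sigma > 0:
            plane = plane + rng.normal(0.0, spec.noise_sigma, size=plane.shape)
        pixels = np.clip(np.rint(plane), -32768, 32767).astype(np.int16)
        slices.append(
            SliceRecord(
                pixel_matrix=pixels,
                image_position=(float(x[0]), float(y[0]), float(z)),
                orientation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
                pixel_spacing_row=ps,
                pixel_spacing_col=ps,
                slice_thickness=spec.slice_thickness,
                spacing_between_slices=spec.spacing_between_slices,
                instance_number=instance,
                slice_location=float(z),
                rescale_slope=spec.rescale_slope,
                rescale_intercept=spec.rescale_intercept,
                window_center=spec.window_center,
                window_width=spec.window_width,
            )
        )
    return slices


def ground_truth(spec: PhantomSpec) -> tuple[float, float, float]:
    """Analytic physical extents (mm) per axis (x/col, y/row, z)."""
    if spec.insert == GRADIENT:
        raise NoDiscreteExtentsError("gradient insert has no discrete extents")
    if spec.insert == SPHERE:
        d = spec.insert_extents[0]
        return (d, d, d)
    return tuple(float(e) for e in spec.insert_extents)


def spec_to_json(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(spec), indent=1))
    return path


def spec_from_json(path: str | Path) -> PhantomSpec:
    data = json.loads(Path(path).read_text())
    for key in ("matrix", "insert_extents"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PhantomSpec(**data)
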