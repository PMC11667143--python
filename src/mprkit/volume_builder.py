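"""Volume assembly from an ordered, classified slice series.

The build runs in two phases.  Phase one restores a uniform nominal z
sampling: overlapping/duplicate slices are deduplicated (keep the lowest
instance number per spacing bin — selection, not blending), then each gap
interval is filled with round(dz / nominal) - 1 synthesized planes so a
gapped series and its contiguous twin yield volumes of identical shape.
Phase two expands the uniform base stack to the requested target depth
per the BuildPlan, inserting planes at strictly interior weights
w_j = j/(m+1) so acquired planes are never re-synthesized.  Acquired
planes are placed bit-exactly at their mapped indices and flagged
``original``; everything synthesized is flagged ``interpolated``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mprkit import interpolation_core as icore
from mprkit import slice_geometry as sg
from mprkit.dicom_io import SliceRecord
from mprkit.errors import EmptySeriesError, ParameterError
from mprkit.slice_geometry import BuildPlan, SeriesGeometry

ORIGINAL = "original"
INTERPOLATED = "interpolated"


@dataclass
class VolumeGrid:
    """Reconstructed 3D intensity grid, indexed (row, col, plane)."""

    voxels: np.ndarray
    spacing_row: float
    spacing_col: float
    spacing_plane: float
    origin: np.ndarray
    plane_provenance: list[str]
    normal: np.ndarray
    plane_z: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[2]


@dataclass
class _PlaneEntry:
    data: np.ndarray
    z: float
    provenance: str


def select_slices_overlap(
    geometry: SeriesGeometry, tolerance: float | None = None
) -> SeriesGeometry:
    """Deduplicate overlapping slices by quantizing z to nominal-spacing bins.

    Within each bin the slice with the lowest instance number (ties: first
    in order) is kept, producing strictly increasing z.  A series without
    overlaps is returned unchanged.
    """
    if tolerance is None:
        tolerance = sg.default_tolerance(geometry.nominal_spacing)
    if sg.OVERLAP not in geometry.interval_labels:
        return geometry
    z0 = geometry.z_positions[0]
    nominal = geometry.nominal_spacing
    best: dict[int, int] = {}  # bin -> index into geometry.slices
    for i, z in enumerate(geometry.z_positions):
        b = int(round((z - z0) / nominal))
        if b not in best:
            best[b] = i
        else:
            cur = geometry.slices[best[b]].instance_number
            new = geometry.slices[i].instance_number
            if cur is not None and new is not None and new < cur:
                best[b] = i
    keep = sorted(best.values())
    kept_slices = [geometry.slices[i] for i in keep]
    kept_z = geometry.z_positions[keep]
    out = SeriesGeometry(
        slices=kept_slices,
        normal=geometry.normal,
        z_positions=kept_z,
        nominal_spacing=nominal,
    )
    sg.classify_intervals(out, tolerance)
    return out


def _slice_planes(geometry: SeriesGeometry) -> list[_PlaneEntry]:
    return [
        _PlaneEntry(np.asarray(rec.pixel_matrix, dtype=float), float(z), ORIGINAL)
        for rec, z in zip(geometry.slices, geometry.z_positions)
    ]


def fill_gaps(
    geometry: SeriesGeometry, edge_threshold: float = icore.DEFAULT_EDGE_THRESHOLD
) -> list[_PlaneEntry]:
    """Insert synthesized planes in gap intervals to restore nominal sampling.

    Each gap of width dz receives round(dz / nominal) - 1 planes at uniform
    interior weights; contiguous and residual-overlap intervals pass
    through untouched.  Returns the augmented plane sequence.
    """
    entries = _slice_planes(geometry)
    if not geometry.interval_labels:
        sg.classify_intervals(geometry)
    out: list[_PlaneEntry] = [entries[0]]
    nominal = geometry.nominal_spacing
    for i, label in enumerate(geometry.interval_labels):
        a, b = entries[i], entries[i + 1]
        if label == sg.GAP:
            dz = b.z - a.z
            m = int(round(dz / nominal)) - 1
            if m > 0:
                out.extend(_synthesize(a, b, m, edge_threshold))
        out.append(b)
    return out


def _synthesize(
    a: _PlaneEntry, b: _PlaneEntry, m: int, edge_threshold: float
) -> list[_PlaneEntry]:
    interval = icore.InterpolationInterval(plane_current=a.data, plane_next=b.data)
    mask = icore.classify_edge_pixels(0.5 * (a.data + b.data), edge_threshold)
    planes = []
    for j in range(1, m + 1):
        w = j / (m + 1)
        plane = icore.interpolate_plane(interval, w, mask)
        planes.append(_PlaneEntry(plane, a.z + w * (b.z - a.z), INTERPOLATED))
    return planes


def build_volume(
    geometry: SeriesGeometry,
    plan: BuildPlan,
    edge_threshold: float = icore.DEFAULT_EDGE_THRESHOLD,
) -> VolumeGrid:
    """Execute the reconstruction protocol for an ordered, classified series.

    The plan must be consistent with the series after overlap
    deduplication and gap filling: len(planes_per_interval) must equal the
    base plane count minus one, and base + sum(planes) must equal
    target_depth (``compute_z_step`` on the base count produces such a
    plan).
    """
    if geometry.n_slices == 0:
        raise EmptySeriesError("empty series")
    deduped = select_slices_overlap(geometry)
    base = fill_gaps(deduped, edge_threshold)
    n_base = len(base)
    if len(plan.planes_per_interval) != n_base - 1:
        raise ParameterError(
            f"plan/geometry mismatch: plan has {len(plan.planes_per_interval)} intervals, "
            f"base stack has {n_base - 1}"
        )
    if n_base + sum(plan.planes_per_interval) != plan.target_depth:
        raise ParameterError("plan/geometry mismatch: plane counts do not sum to target depth")

    entries: list[_PlaneEntry] = [base[0]]
    for i, m in enumerate(plan.planes_per_interval):
        a, b = base[i], base[i + 1]
        if m > 0:
            entries.extend(_synthesize(a, b, m, edge_threshold))
        entries.append(b)

    voxels = np.stack([e.data for e in entries], axis=2)
    z = np.array([e.z for e in entries])
    depth = plan.target_depth
    extent = z[-1] - z[0]
    spacing_plane = extent / (depth - 1) if depth > 1 and extent > 0 else deduped.nominal_spacing
    first = deduped.slices[0]
    origin = (
        np.asarray(first.image_position, dtype=float)
        if first.image_position is not None
        else np.zeros(3)
    )
    return VolumeGrid(
        voxels=voxels,
        spacing_row=first.pixel_spacing_row,
        spacing_col=first.pixel_spacing_col,
        spacing_plane=float(spacing_plane),
        origin=origin,
        plane_provenance=[e.provenance for e in entries],
        normal=geometry.normal,
        plane_z=z,
    )


def base_plane_count(
    geometry: SeriesGeometry, edge_threshold: float = icore.DEFAULT_EDGE_THRESHOLD
) -> int:
    """Plane count after overlap dedup and gap fill (what a BuildPlan must match)."""
    return len(fill_gaps(select_slices_overlap(geometry), edge_threshold))


def reconstruct(
    slices: list[SliceRecord],
    target_depth: int | None = None,
    edge_threshold: float = icore.DEFAULT_EDGE_THRESHOLD,
) -> VolumeGrid:
    """Convenience wrapper: order, classify, plan and build in one call.

    ``target_depth=None`` keeps the base plane count (z step 1 after gap
    filling).
    """
    geometry = sg.order_slices(slices)
    n_base = base_plane_count(geometry, edge_threshold)
    depth = n_base if target_depth is None else target_depth
    plan = sg.compute_z_step(n_base, depth)
    return build_volume(geometry, plan, edge_threshold)


def save_volume(volume: VolumeGrid, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write raw little-endian float32 voxels plus a JSON metadata sidecar."""
    prefix = Path(path_prefix)
    raw_path = prefix.with_suffix(".raw")
    json_path = prefix.with_suffix(".json")
    voxels = volume.voxels.astype("<f4")
    raw_path.write_bytes(voxels.tobytes())
    sidecar = {
        "dims": list(volume.shape),
        "index_order": "(row, col, plane), C-contiguous, row increases toward posterior",
        "dtype": "float32-le",
        "spacing_mm": {
            "row": volume.spacing_row,
            "col": volume.spacing_col,
            "plane": volume.spacing_plane,
        },
        "origin_mm": [float(x) for x in volume.origin],
        "normal": [float(x) for x in volume.normal],
        "plane_provenance": volume.plane_provenance,
        "plane_z_mm": [float(z) for z in volume.plane_z],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return raw_path, json_path


def load_volume(path_prefix: str | Path) -> VolumeGrid:
    """Read a volume written by save_volume."""
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    dims = tuple(meta["dims"])
    voxels = np.frombuffer(prefix.with_suffix(".raw").read_bytes(), dtype="<f4")
    voxels = voxels.reshape(dims).astype(float)
    return VolumeGrid(
        voxels=voxels,
        spacing_row=meta["spacing_mm"]["row"],
        spacing_col=meta["spacing_mm"]["col"],
        spacing_plane=meta["spacing_mm"]["plane"],
        origin=np.asarray(meta["origin_mm"], dtype=float),
        plane_provenance=list(meta["plane_provenance"]),
        normal=np.asarray(meta["normal"], dtype=float),
        plane_z=np.asarray(meta["plane_z_mm"], dtype=float),
    )


def volume_to_slices(volume: VolumeGrid, template: SliceRecord) -> list[SliceRecord]:
    """Round volume planes back to integer DICOM slices (round-half-even)."""
    slices = []
    for p in range(volume.n_planes):
        pixels = np.rint(volume.voxels[:, :, p]).astype(np.int16)
        pos = volume.origin + volume.normal * (volume.plane_z[p] - volume.plane_z[0])
        slices.append(
            SliceRecord(
                pixel_matrix=pixels,
                image_position=tuple(float(x) for x in pos),
                orientation=template.orientation,
                pixel_spacing_row=volume.spacing_row,
                pixel_spacing_col=volume.spacing_col,
                slice_thickness=volume.spacing_plane,
                spacing_between_slices=volume.spacing_plane,
                instance_number=p + 1,
                slice_location=float(volume.plane_z[p]),
                rescale_slope=template.rescale_slope,
                rescale_intercept=template.rescale_intercept,
                window_center=template.window_center,
                window_width=template.window_width,
            )
        )
    return slices
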