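"""Inter-slice interpolation kernels.

Synthesized planes between two acquired planes V_i and V_{i+1} are built
per pixel with a weight w in (0,1) giving the fractional z position
inside the interval:

* non-edge interior pixels — weighted bilinear blend of the pixel and
  its two lateral neighbours in both anchor planes:

      P(k)     = P_i(k) + P_{i+1}(k)
      P_i(k)   = (1-w) * (0.5 V_i[k]     + 0.25 V_i[k-1]     + 0.25 V_i[k+1])
      P_{i+1}(k) =  w  * (0.5 V_{i+1}[k] + 0.25 V_{i+1}[k-1] + 0.25 V_{i+1}[k+1])

* array-boundary pixels (first/last column, where a lateral neighbour is
  missing) — the 0.75/0.25 variant: 0.75 for the pixel itself, 0.25 for
  the single available neighbour, blended by the same weight;

* intensity-edge pixels (central-difference gradient magnitude above a
  threshold) — bicubic interpolation along z through a 4x4 Catmull-Rom
  patch assembled from the two anchor planes with replicate-clamped z
  anchors, which preserves sharp boundaries that lateral averaging would
  smear.

All kernels are convex: weights sum to one, so constants are reproduced
exactly and weighted-bilinear output is bounded by the anchor values.
Pixels are addressed by flattened row-major index k; k +/- 1 are
horizontal neighbours, and first/last-column pixels are treated as
boundary pixels so no neighbourhood wraps across rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mprkit.errors import ParameterError

#: default intensity-edge gradient threshold, stored-value units
DEFAULT_EDGE_THRESHOLD = 100.0

#: cubic-convolution kernel parameter (Catmull-Rom)
CUBIC_A = -0.5

# Catmull-Rom basis: p(t) = [1 t t^2 t^3] @ _CR_M @ [p0 p1 p2 p3]^T
_CR_M = 0.5 * np.array(
    [
        [0.0, 2.0, 0.0, 0.0],
        [-1.0, 0.0, 1.0, 0.0],
        [2.0, -5.0, 4.0, -1.0],
        [-1.0, 3.0, -3.0, 1.0],
    ]
)


@dataclass
class InterpolationInterval:
    """A pair of anchor planes and the weights of planes synthesized between them."""

    plane_current: np.ndarray
    plane_next: np.ndarray
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.plane_current = np.asarray(self.plane_current, dtype=float)
        self.plane_next = np.asarray(self.plane_next, dtype=float)
        if self.plane_current.shape != self.plane_next.shape:
            raise ParameterError("anchor planes must have identical shape")
        for w in self.weights:
            if not 0.0 < w < 1.0:
                raise ParameterError(f"interpolation weight {w} outside (0, 1)")

    @property
    def length(self) -> int:
        """Number of pixels per plane (flattened)."""
        return self.plane_current.size


@dataclass
class BicubicPatch:
    """A 4x4 grid of samples and the (u, v) evaluation point in [0,1]^2.

    The interpolation anchor is grid[1][1]: u = v = 0 reproduces it.
    """

    grid: np.ndarray
    u: float
    v: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (4, 4):
            raise ParameterError("bicubic patch must be exactly 4x4")
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ParameterError("u and v must lie in [0, 1]")

    @property
    def coefficients(self) -> np.ndarray:
        """Polynomial coefficients a_ij with value = sum a_ij u^i v^j."""
        return _CR_M @ self.grid @ _CR_M.T


@dataclass
class EdgeMask:
    """Boolean mask of intensity-edge pixels (true = edge -> bicubic path)."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _flat(interval: InterpolationInterval) -> tuple[np.ndarray, np.ndarray]:
    return interval.plane_current.ravel(), interval.plane_next.ravel()


def interp_nonedge(interval: InterpolationInterval, k: int, w: float) -> float:
    """Weighted bilinear value for an interior pixel k."""
    vi, vn = _flat(interval)
    if k - 1 < 0 or k + 1 >= interval.length:
        raise ParameterError("pixel k is at an array boundary; use interp_boundary")
    p_i = (1.0 - w) * (0.5 * vi[k] + 0.25 * vi[k - 1] + 0.25 * vi[k + 1])
    p_next = w * (0.5 * vn[k] + 0.25 * vn[k - 1] + 0.25 * vn[k + 1])
    return float(p_i + p_next)


def interp_boundary(
    interval: InterpolationInterval, k: int, w: float, neighbor: int | None = None
) -> float:
    """0.75/0.25 variant for a pixel missing one lateral neighbour.

    *neighbor* selects the available neighbour explicitly (used for
    first/last-column pixels whose flattened index is interior); by
    default it is inferred from the flattened bounds.  A single-pixel
    plane degenerates to the plain (1-w)/w blend.
    """
    vi, vn = _flat(interval)
    if interval.length == 1:
        return float((1.0 - w) * vi[k] + w * vn[k])
    if neighbor is None:
        if k - 1 < 0:
            neighbor = k + 1
        elif k + 1 >= interval.length:
            neighbor = k - 1
        else:
            raise ParameterError("pixel k is interior; pass the missing-neighbor side")
    p_i = (1.0 - w) * (0.75 * vi[k] + 0.25 * vi[neighbor])
    p_next = w * (0.75 * vn[k] + 0.25 * vn[neighbor])
    return float(p_i + p_next)


def classify_edge_pixels(plane: np.ndarray, threshold: float) -> EdgeMask:
    """Flag pixels whose central-difference gradient magnitude exceeds *threshold*.

    Border pixels are always non-edge: they lack the 4x4 support the
    bicubic path needs.
    """
    plane = np.asarray(plane, dtype=float)
    mask = np.zeros(plane.shape, dtype=bool)
    if plane.shape[0] >= 3 and plane.shape[1] >= 3:
        gy = 0.5 * (plane[2:, 1:-1] - plane[:-2, 1:-1])
        gx = 0.5 * (plane[1:-1, 2:] - plane[1:-1, :-2])
        mask[1:-1, 1:-1] = np.hypot(gx, gy) > threshold
    return EdgeMask(mask=mask, threshold=threshold)


def bicubic_eval(patch: BicubicPatch) -> float:
    """Evaluate sum_{i,j} a_ij u^i v^j via separable Catmull-Rom coefficients."""
    u_vec = np.array([1.0, patch.u, patch.u**2, patch.u**3])
    v_vec = np.array([1.0, patch.v, patch.v**2, patch.v**3])
    return float(u_vec @ patch.coefficients @ v_vec)


def cubic_blend_weight(w) -> np.ndarray | float:
    """Fraction of the next anchor contributed by z-bicubic with clamped anchors.

    With z knots replicated as (V_i, V_i, V_{i+1}, V_{i+1}) the Catmull-Rom
    interpolant reduces to V_i + (V_{i+1} - V_i) * s(w) with
    s(w) = 0.5 w + 1.5 w^2 - w^3, a monotone map with s(0)=0, s(1)=1.
    """
    w = np.asarray(w, dtype=float)
    return 0.5 * w + 1.5 * w**2 - w**3


def bicubic_patch_for_pixel(
    interval: InterpolationInterval, row: int, col: int, w: float
) -> BicubicPatch:
    """Assemble the 4x4 z-interpolation patch for one edge pixel.

    Rows of the patch are the z anchors, replicate-clamped to
    (V_i, V_i, V_{i+1}, V_{i+1}); columns are the in-plane horizontal
    neighbourhood (col-1 .. col+2, edge-clamped).  Evaluating at
    (u=w, v=0) interpolates along z exactly at the pixel's own column,
    since v=0 sits on the in-plane knot.
    """
    cols = interval.plane_current.shape[1]
    idx = np.clip(np.arange(col - 1, col + 3), 0, cols - 1)
    row_i = interval.plane_current[row, idx]
    row_n = interval.plane_next[row, idx]
    return BicubicPatch(grid=np.vstack([row_i, row_i, row_n, row_n]), u=w, v=0.0)


def _lateral(plane: np.ndarray) -> np.ndarray:
    """Per-row lateral blend: 0.5/0.25/0.25 interior, 0.75/0.25 at columns 0 and -1."""
    if plane.shape[1] == 1:
        return plane.copy()
    out = np.empty_like(plane)
    out[:, 1:-1] = 0.5 * plane[:, 1:-1] + 0.25 * plane[:, :-2] + 0.25 * plane[:, 2:]
    out[:, 0] = 0.75 * plane[:, 0] + 0.25 * plane[:, 1]
    out[:, -1] = 0.75 * plane[:, -1] + 0.25 * plane[:, -2]
    return out


def interpolate_plane(
    interval: InterpolationInterval, w: float, edge_mask: EdgeMask
) -> np.ndarray:
    """Synthesize one full plane at weight *w* between the interval anchors.

    Edge-masked pixels take the bicubic z path; everything else takes the
    weighted-bilinear path (with the 0.75/0.25 boundary variant applied in
    the first/last columns).  Output shape equals the anchor shape.
    """
    vi = interval.plane_current
    vn = interval.plane_next
    if edge_mask.mask.shape != vi.shape:
        raise ParameterError("edge mask shape must match plane shape")
    bilinear = (1.0 - w) * _lateral(vi) + w * _lateral(vn)
    if not edge_mask.mask.any():
        return bilinear
    s = cubic_blend_weight(w)
    bicubic = vi + (vn - vi) * s
    return np.where(edge_mask.mask, bicubic, bilinear)
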