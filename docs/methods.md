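# Methods

## Problem and model

Multiplanar reconstruction rebuilds a 3D intensity volume from a stack of
2D axial CT slices so it can be re-sliced along coronal and sagittal
planes. Clinical series are rarely a clean uniform stack: the
center-to-center slice distance may differ from the slab thickness
(gapped or overlapping acquisitions), tags may be missing or zero, and
duplicate slices occur. The pipeline therefore separates three concerns:
geometric normalization of the stack, synthesis of missing planes, and
physically correct re-slicing.

### Slice ordering and spacing

Slices are ordered by the signed projection `z = p · n` of Image Position
(Patient) onto the stack normal `n = row_axis × col_axis`, which is
correct for oblique acquisitions where the raw z coordinate is not.
Ties are broken by instance number, then slice location; when positions
are absent entirely, ordering falls back to instance number, then
location. Ordering is a stable permutation and is idempotent.

The **nominal spacing** is the smallest positive value among the Spacing
Between Slices and Slice Thickness tags, falling back to the median
observed interval when neither tag is usable. Taking the minimum handles
both degenerate tag regimes seen in clinical peripheral-artery CT: a
spacing tag of 0 alongside 5 mm slices (thickness wins), and 0.625 mm
slabs acquired every 5 mm, where the pitch exceeds the slab width and
every interval is a physical gap that must be filled before re-slicing —
otherwise coronal/sagittal aspect would be wrong. An interval `Δz` is
*contiguous* when `|Δz − nominal| ≤ tol`, a *gap* above, an *overlap*
below; the default tolerance is 1% of the nominal spacing with a 0.01 mm
floor, enough to absorb float noise in positions without masking true
gaps.

### Volume building

Building runs in two phases so a gapped series and its contiguous twin
produce volumes of identical shape:

1. *Normalization.* Overlapping/duplicate slices are deduplicated by
   quantizing z into nominal-spacing bins and keeping the lowest instance
   number per bin — selection, not averaging, so kept planes stay
   bit-exact. Each gap then receives `round(Δz/nominal) − 1` synthesized
   planes, restoring uniform sampling.
2. *Expansion.* The uniform base stack of `n` planes is expanded to the
   requested `target_depth` with z step `target_depth / n`. Synthesized
   planes per interval are distributed uniformly with the remainder
   assigned to the last interval (deterministic; always sums exactly to
   the target). `target_depth = n` means a unit z step and no synthesis;
   zero input files is a dedicated error; requesting fewer planes than
   slices (decimation) is rejected as a parameter error rather than
   silently dropping data.

Weights inside an interval are `w_j = j/(m+1)`, strictly interior, so
acquired planes are never re-synthesized; they are placed bit-exactly and
flagged `original` in the per-plane provenance.

### Interpolation

Non-edge pixels use a weighted bilinear blend of the pixel and its two
horizontal neighbours in both anchor planes (weights 0.5/0.25/0.25,
scaled by `1−w` and `w`). Pixels are addressed by flattened row-major
index; first/last-column pixels are treated as boundary pixels (weights
0.75/0.25 toward the single available neighbour) so no neighbourhood
wraps across rows. All weights sum to one: constants are reproduced
exactly and the bilinear output is a convex combination of anchor values.

"Edge pixel" admits two readings — array boundary or intensity edge —
and both are implemented: boundary pixels get the 0.75/0.25 variant,
while intensity edges (central-difference gradient magnitude above
`edge_threshold`, default 100 stored-value units, CLI-tunable) take a
bicubic path that does not average laterally and therefore keeps sharp
boundaries crisp. The bicubic kernel is separable cubic convolution with
Catmull-Rom coefficients (a = −0.5), i.e. coefficients `a_ij` determined
from the 4×4 samples and their finite-difference derivatives; evaluation
is `Σ a_ij u^i v^j`. For inter-plane synthesis the 4×4 patch is built
with replicate-clamped z anchors `(V_i, V_i, V_{i+1}, V_{i+1})` and the
in-plane neighbourhood as the second axis, evaluated at `(u=w, v=0)`;
with clamped anchors this reduces to the closed form
`V_i + (V_{i+1} − V_i)·(0.5w + 1.5w² − w³)`, which the vectorized
implementation uses (a test pins it to `bicubic_eval` on the assembled
patch). Interpolation operates on stored values promoted to float64;
rounding back to integers (half-even) happens only at DICOM export.

### Views, display, measurement

Views are exported unresampled with per-axis mm spacings (axial:
row/col; coronal and sagittal: plane spacing vertically), so mm
measurements are exact; square-pixel resampling is available behind a
flag. Reference lines are the axis-aligned intersections of orthogonal
planes expressed in target-view pixel coordinates. Display mapping is a
linear window/level onto 8-bit [0, 255] (matching web-canvas rendering),
with invert as `255 − v`; the magnifier crops `output/factor` around a
point and upsamples with the same Catmull-Rom kernel.

Measurement tools convert (row, col) points to mm through the view
spacings and report mm/HU only. ROI membership is pixel-center-inside
(no partial-area weighting): rectangles and ellipses by direct
arithmetic, freehand polygons via matplotlib's `Path`; tests check all
three against an independent ray-casting oracle. Structure extents are
located by half-maximum crossings of an intensity profile — the level
`(min+max)/2`, linearly interpolated between samples — which is the
sharpest defensible automation of manual edge-point placement on
high-contrast structures. Accuracy is summarized as the mean absolute
error `(1/n) Σ |M_i − G_i|` between cross-view measurement pairs.

## Synthetic phantom

The generator emits DICOM-ready series spanning the clinical parameter
envelope (matrix 64×64 by default, 512×512 behind a flag; pixel spacing
~0.78–0.98 mm; thickness 0.625–5.0 mm; spacing tag 0–5.0 mm or absent)
in contiguous, gapped, overlapping and duplicate-slice configurations.
Inserts are analytic (block, sphere, gradient) sampled at voxel centers;
Gaussian noise on stored values is seeded and clipped to int16. By
default block edges are snapped to the nearest voxel boundary (extents
move by at most half a voxel; the insert center shifts by half a voxel
when parity requires it), which makes half-maximum localization land
exactly on the edge; an `offgrid` mode disables snapping and applies a
random sub-voxel shift, where localization is only guaranteed to within
one voxel per axis.

What the phantom does *not* emulate: anatomy, partial-volume averaging
across the slab thickness (slices sample the insert at their center
plane), beam hardening, scatter, or correlated CT noise. Passing tests
therefore demonstrate the geometric and numerical correctness of the
pipeline — ordering, spacing normalization, interpolation, view
geometry, measurement — not robustness to scanner physics.

## Validation protocol

`validate` (and `scripts/acceptance.py`) automate the cross-view
accuracy experiment: a noise-free 64×64×40 block phantom (0.9 mm pixels,
3.75 mm slices, 20×20×15 mm block) is reconstructed at target depth
`2·n − 1` — one synthesized plane in every interval, so the interpolation
path is genuinely exercised — and the block extents are measured on
matching physical lines in the axial view (ground truth) and the
reconstructed coronal/sagittal views (measured), at three plane
positions including interpolated planes. The mean absolute error over
the 6 pairs is 0.000 mm: with subpixel localization replacing manual
cursor placement, both views resolve the same edge to the same boundary.
The z extent, which has no axial ground truth, is reported as a
coronal-vs-sagittal consistency check. Problem sizes (64×64 matrices,
tens of slices) were chosen so the full suite and the validation run in
seconds while still covering every protocol branch; the `--full-size`
flag reproduces 512×512 clinical dimensions for benchmarking.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| spacing tolerance | max(1% of nominal, 0.01 mm) | float noise vs true gaps |
| edge_threshold | 100 stored units | ~100 HU: tissue boundaries flag, noise does not |
| cubic kernel a | −0.5 (Catmull-Rom) | interpolating, reproduces linears exactly |
| interval weights | w_j = j/(m+1) | anchors never re-synthesized |
| overlap dedup | keep lowest instance number | selection preserves acquired data bit-exact |
| z-step remainder | last interval | simplest deterministic rule |
| display depth | 8-bit [0,255] | web-canvas convention |
| phantom insert | +200 HU block on −1000 HU | bone-like contrast, unambiguous half-max |

## Known limitations

- Single-frame, uncompressed little-endian CT objects only; compressed
  transfer syntaxes are rejected, multi-frame enhanced CT is out of scope.
- One series per directory (no Series Instance UID splitting), no
  gantry-tilt correction, no localizer detection.
- Oblique reformats, MIP and volume rendering are out of scope.
- When the target depth is not an exact multiple of the base count, the
  last interval absorbs the remainder, so output z sampling is uniform
  except across that interval; `spacing_plane` reports the mean sampling.
- Timing figures logged by `build`/`bench` are hardware-dependent
  diagnostics, deliberately kept out of all result files.
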