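# Methods

This note documents the models, conventions and numerical choices behind
`speleoclean`, and what its synthetic tests do and do not demonstrate about
real data.

## Geometric conventions

Volumes are indexed `(z, y, x)`, 0-based; spacing is `(dx, dy, dz)` mm; the
world position of voxel `(k, j, i)` is `origin + (i·dx, j·dy, k·dz)` in the
scanner patient frame, which is taken as given. Only axial single-frame
series are supported; oblique acquisitions are rejected rather than
resampled, because the whole protocol (contouring, interpolation, erasure)
operates on axial slices. The inter-slice spacing `dz` is always measured
from the slice world positions, never taken from the nominal
slice-thickness tag: overlapping reconstructions (e.g. 0.6 mm slices at a
0.3 mm increment) make the two differ, and only the measured spacing is
self-consistent with the data on disk. Derived series carry a derivation
tag (`crust-template`, `virtually-cleaned`) in the DICOM series
description and image comments.

## Contours and shape-based interpolation

A contour is a closed simple polygon in in-plane mm coordinates.
Normalisation fixes the drawing convention: vertex order clockwise in
image coordinates (negative shoelace area with y growing downward) and the
start vertex at "twelve o'clock" — the vertex of smallest image y, ties
broken by smallest x. Rasterisation uses the pixel-centre even-odd rule
with half-open edge handling and strict inequality at exact crossings;
this is deliberately specified to the bit, rather than matching any
particular viewer's fill dialect, so that masks are reproducible.
Multiple contours on one slice are rasterised independently and unioned;
no attempt is made to match components across slices.

Inter-slice interpolation is shape-based: the signed Euclidean distance
fields (negative inside, computed in mm so anisotropic pixels are
handled) of the two enclosing keyframe masks are blended linearly,
`d = (1−t)·d_a + t·d_b`, and thresholded at zero. The endpoints return
the keyframe masks bit-exactly and the operation is symmetric,
`f(a,b,t) = f(b,a,1−t)`. This is the standard choice for interpolating
binary organ masks: it is exact at keyframes and morphs convex-to-convex
shapes predictably. Which algorithm interactive viewers use internally is
generally undocumented; no claim is made of matching one. If one keyframe
is empty, its field is taken as a constant equal to the grid diagonal, so
the surviving shape erodes toward its skeleton as `t` approaches the
empty side (with this large cap the shape vanishes at small `t`; the
behaviour is deterministic and bounded, which is all that is required of
this edge case). Slices outside the keyframe range stay empty. Manual
correction of interpolated slices is modelled programmatically
(`edit_mask`), with an audit trail in the mask provenance.

## Virtual cleaning

Erasure sets masked voxels to `fill_hu`; the default −2048 lies below any
achievable HU, so no voxel of the original can coincide with the fill
value and the mask is recoverable exactly from (original, template). The
number of coincident voxels is counted and reported for non-default fills.
Subtraction is implemented as difference-support masking: where original
and template agree the output is a uniform `background_hu` (−1024, air);
where they differ the original value is kept. Literal voxelwise
arithmetic would produce HU *offsets* rather than a series showing only
the specimen; the difference-support semantics realises the intended
outcome and makes the erase/subtract round trip bit-exact. The output
value set is always a subset of the original's values plus the
background.

## Surface extraction

Marching cubes at a user-chosen HU threshold; vertices are scaled to world
mm, winding is normalised so outward volume is positive, and degenerate
faces are dropped. The default threshold — midpoint between the
background and the 5th percentile of supra-background voxels — is a
data-driven convenience and is always logged; there is no claim that any
particular published rendering used it. Speckle from residual noise is
suppressed by keeping the connected component of largest enclosed
|volume| (exact ties break to the component containing the smallest
vertex index, with a warning). STL is written binary, little-endian, with
the provenance tag in the 80-byte header (`80 + 4 + 50·m` bytes for `m`
triangles). An ASCII PLY writer with one float scalar per vertex serves
deviation heat maps.

Accuracy caveat: marching cubes reconstructs geometry from *band-limited*
data. On a hard binary sphere the extracted surface has ~9 % excess area
(staircase normals) no matter the implementation, while the enclosed
volume is nearly unbiased. The analytic calibration object
(`phantom.sphere_phantom`) therefore carries a one-voxel linear
partial-volume ramp at its boundary — the profile CT reconstruction
actually produces — and the half-max isosurface then recovers sphere area
within 0.1 % and volume within 0.2 % at 0.5 mm spacing.

## Point-cloud congruence

Clouds are sampled area-weighted uniformly (triangle chosen by area,
position by folded barycentric coordinates), with the exact requested
count. Distances are unsigned point-to-nearest-point (k-d tree; verified
exactly against exhaustive search), asymmetric a→b; "within 1 mm" is
strict (`d < 1`). Reader models are compared in cyclic order. Each mesh's
sampling sub-seed is derived from the shared seed *and the mesh content*,
so identical models receive identical clouds and report exactly zero
deviation — without this, two identical meshes would show a spurious
deviation at the sampling-gap scale. Rigid registration is out of scope:
models segmented from one scan share its frame.

## Osteometry

Caliper measurements are operationalised geometrically:

* **shaft axis** — principal axis of the vertex set (meshes must be
  elongated: first extent ≥ 1.5× second), oriented toward the head end
  (the extremity band with larger cross-sectional extent; overridable),
  then refined as the principal direction of planar cross-section
  centroids through the distal shaft — centroids lie on the true axis
  even when surface sampling is anisotropic.
* **SD** — minimum over 0.5 mm stations along the distal 40 % of the
  axial length of the maximal in-plane caliper width of the mesh–plane
  cross-section.
* **DC** — twice the radius of a least-squares sphere fitted to the head.
  The head region is found by a deterministic consensus (RANSAC) fit over
  the proximal 35 % band: inliers must lie within 0.6 mm of the candidate
  shell *and* have outward normals radial to its centre — the normal test
  rejects the large "everything-ball" that merely grazes head, neck and
  trochanter at once. A fit RMS above 10 % of the radius is an error
  ("head region not spherical"). An explicit axial band can be supplied
  instead and is fitted as given.
* **Bp** — maximal caliper width perpendicular to the shaft axis of the
  vertices in the proximal 35 % of the axial length.

All three are functions of pairwise point distances and are therefore
rigid-invariant to float precision. They are honest renderings of
hands-on caliper definitions, not reproductions of any specific operator's
hand placement: numbers are comparable within-method, and each report
records its parameters. `compare_to_direct` summarises absolute
differences against direct (workstation) measurements as mean ± sample SD.

## Phantom generator

The phantom emulates the conditions that make this problem hard:

* bone = capped cylinder (shaft) + sphere (head, medially offset on a
  neck frustum) + lateral spherical bump (trochanter), so that
  SD = 2·r_shaft, DC = 2·r_head and Bp = (offset_head + r_head) +
  (offset_troch + r_troch) hold in closed form. The bump is a sphere
  purely for testability; no anatomical realism is claimed.
* crust = shell around the bone whose thickness is a smooth random field
  (8 mm correlation length, clipped to [0.25·mean, mean + 3·SD]).
* materials: single-HU-distribution bone N(1300, 150) and calcite
  N(1400, 150) — overlapping by construction, since inter-material
  similarity (not intra-bone structure) is the stated challenge; air
  background −1000 HU.
* degradation: Gaussian blur (σ 0.4 mm) as a partial-volume surrogate,
  then additive N(0, 20 HU) noise. The ground-truth mask is the pre-blur
  rasterisation, so degradation never touches the truth.
* default spacing (0.33, 0.33, 0.67) mm matches the anisotropic clinical
  protocol the pipeline targets; default head radius 15.35 mm and shaft
  radius 14.8 mm give a specimen of realistic proximal-femur scale.

Simulated readers trace the true boundary (sub-pixel marching-squares
polygon) on every k-th bone slice; with noise the polygon is resampled to
`n_vertices` arc-length-uniform points, each jittered radially by
N(0, σ_vertex). With zero noise the exact boundary polygon is kept, and
it rasterises back to the truth mask bit-exactly — the identity that
anchors the interpolation tests. Defaults: every 10th slice, 0.3 mm
jitter, 120 vertices.

What the phantom does **not** model: trabecular texture, beam hardening,
scanner kernels, reader bias (systematic over-/under-inclusion),
topology-changing segmentation mistakes. Passing phantom tests shows the
machinery is correct and stable at clinical voxel sizes and realistic
inter-material contrast; it does not certify accuracy on any particular
real specimen.

## Radiocarbon calibration

The curve is linearly interpolated to a 1-year calendar grid (printed
calibrated ranges are conventionally reported at 1-year resolution);
posterior `∝ exp(−(age−μ(t))²/(2(σ²+σ_curve(t)²)))` under a uniform
prior. HPD ranges are found by descending-density inclusion (the only
construction that yields the multiple disjoint ranges calibration
software prints), merged into contiguous runs. Each range's probability
is its *share of the selected mass* — the "relative area under the
distribution" convention, so the shares of one level sum to 1 — rounded
to 3 decimals. Levels "1σ"/"2σ" map to 0.6827/0.9545. Calendar labels
use no year zero: cal BC = cal BP − 1949 for ages at or before 1950 BP,
endpoints rounded to the nearest year. No curve file is bundled
(distribute IntCal under its own terms); tests run on synthetic identity
and wiggly curves, and the IntCal13 worked example activates when the
user supplies `data/intcal13.14c`. Reservoir corrections, sequence
modelling and fractionation handling are out of scope (inputs are assumed
already fraction-corrected).

## Problem sizes

The test suite exercises coarse phantoms (≈0.5–1 mm voxels, ~60–100
slices) for unit-level checks and the full-size study phantom
(0.33 × 0.33 × 0.67 mm, ~200 slices, ~8.5 M voxels) for the end-to-end
acceptance properties; reader-congruence clouds use 10⁴–10⁵ points per
model (the library default is 10⁶, which simply scales the same
computation). `scripts/acceptance.py` completes in well under a minute
per stage on a single CPU.

## Known limitations

* Contour interpolation is composite-mask based; a topology change
  between keyframes (one component splitting into two) morphs through the
  blended field rather than tracking components.
* Head detection assumes the head is the dominant spherical surface in
  the proximal band; severely eroded heads need the explicit-band
  override.
* The default isosurface threshold is data-driven and should be fixed
  explicitly in any comparative study.
* DICOM support covers single-frame axial CT only (no multi-frame or
  enhanced IODs).
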