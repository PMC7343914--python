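"""Synthetic encrusted-specimen phantoms with known ground truth.

The specimen this package is built around — a proximal femoral fragment
inside a thick speleothemic calcite crust — is not publicly deposited, so
every downstream stage is exercised on a phantom that emulates its
salient difficulties:

* a bone built from primitives with closed-form osteometrics: a capped
  cylindrical shaft, a spherical head on a medially offset neck frustum,
  and a lateral spherical bump standing in for the greater trochanter;
* a calcite crust of spatially varying thickness whose HU distribution
  overlaps that of the partially fossilised bone (the overlap is the
  default regime — it is what defeats plain threshold segmentation);
* anisotropic voxel spacing, Gaussian blur as a partial-volume surrogate,
  and additive HU noise.

The ground-truth bone mask is the pre-degradation rasterisation; the true
osteometric measures (Bp, DC, SD) follow analytically from the spec.
Everything is reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage import measure

from .contours import Contour, ContourSet, BinaryMask
from .volume import CTVolume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "simulate_reader",
           "sphere_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and degradation of a synthetic encrusted femur.

    Lengths are mm, intensities HU.  Defaults mirror the scan conditions
    the package targets: anisotropic (0.33, 0.33, 0.67) mm voxels, a head
    of diameter 30.7 mm and shaft of diameter 29.6 mm, and bone/calcite HU
    distributions N(1300, 150) / N(1400, 150) whose overlap makes pure
    thresholding fail.
    """

    shaft_radius: float = 14.8
    shaft_length: float = 90.0
    head_radius: float = 15.35
    neck_radius: float = 9.0
    neck_length: float = 12.0
    head_offset: float = 15.0  # medial (−x) offset of the head centre from the shaft axis
    trochanter_bump_radius: float = 12.0
    trochanter_offset: float = 20.0  # lateral (+x) offset of the bump centre
    crust_thickness_mean: float = 4.0
    crust_thickness_sd: float = 1.0
    hu_bone_mean: float = 1300.0
    hu_bone_sd: float = 150.0
    hu_calcite_mean: float = 1400.0
    hu_calcite_sd: float = 150.0
    hu_background: float = -1000.0
    blur_sigma: float = 0.4  # mm
    noise_sd: float = 20.0  # HU
    spacing: tuple[float, float, float] = (0.33, 0.33, 0.67)
    tilt_deg: float = 0.0  # shaft tilt away from the z axis, in the x–z plane
    margin: float = 4.0  # air margin around the crust, mm
    seed: int = 0

    def __post_init__(self):
        positive = [
            "shaft_radius", "shaft_length", "head_radius", "neck_radius", "neck_length",
            "trochanter_bump_radius", "crust_thickness_mean", "blur_sigma",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if self.head_radius <= self.neck_radius:
            raise ValueError("head_radius must exceed neck_radius (no distinct head)")

    # ---- closed-form ground-truth osteometrics -------------------------
    @property
    def true_sd(self) -> float:
        """Smallest diaphysis diameter: the shaft is a circular cylinder."""
        return 2.0 * self.shaft_radius

    @property
    def true_dc(self) -> float:
        """Depth (diameter) of the femoral head."""
        return 2.0 * self.head_radius

    @property
    def true_bp(self) -> float:
        """Breadth of the proximal end.

        Maximal caliper width perpendicular to the shaft axis over the
        proximal region: from the medial rim of the head to the lateral
        rim of the trochanter bump.
        """
        medial = self.head_offset + self.head_radius
        lateral = self.trochanter_offset + self.trochanter_bump_radius
        return float(
            max(medial, self.head_radius, self.shaft_radius)
            + max(lateral, self.head_radius - self.head_offset, self.shaft_radius)
        )

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        if "spacing" in payload:
            payload["spacing"] = tuple(payload["spacing"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    volume: CTVolume
    bone_mask: BinaryMask
    true_measures: dict[str, float]  # keys: Bp, DC, SD (mm)
    spec: PhantomSpec
    crust_mask: BinaryMask | None = None  # diagnostic: where calcite was placed


def _bone_geometry(spec: PhantomSpec):
    """Primitive centres/axes in the untilted frame (origin at shaft base)."""
    head_centre = np.array([-spec.head_offset, 0.0, spec.shaft_length + spec.neck_length])
    troch_centre = np.array([spec.trochanter_offset, 0.0, spec.shaft_length])
    return head_centre, troch_centre


def _rasterize_bone(spec: PhantomSpec, xx, yy, zz) -> np.ndarray:
    """Exact voxel-centre rasterisation of the bone union.

    Coordinates are in the untilted bone frame.  The bone is the union of
    shaft cylinder, head sphere, trochanter bump sphere, and the neck — an
    oblique cone frustum from the shaft top to the head centre.
    """
    head_centre, troch_centre = _bone_geometry(spec)

    shaft = (
        (xx**2 + yy**2 <= spec.shaft_radius**2)
        & (zz >= 0.0)
        & (zz <= spec.shaft_length)
    )
    head = (xx - head_centre[0]) ** 2 + yy**2 + (zz - head_centre[2]) ** 2 <= spec.head_radius**2
    troch = (
        (xx - troch_centre[0]) ** 2 + yy**2 + (zz - troch_centre[2]) ** 2
        <= spec.trochanter_bump_radius**2
    )

    # neck: tube of radius neck_radius around the segment shaft-top -> head centre
    a = np.array([0.0, 0.0, spec.shaft_length])
    b = head_centre
    ab = b - a
    ab2 = float(ab @ ab)
    px, py, pz = xx - a[0], yy - a[1], zz - a[2]
    t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / ab2, 0.0, 1.0)
    d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
    neck = d2 <= spec.neck_radius**2

    return shaft | head | troch | neck


def _grid(spec: PhantomSpec):
    """Voxel grid large enough to hold bone + crust + margin."""
    pad = spec.crust_thickness_mean + 3.0 * spec.crust_thickness_sd + spec.margin
    x_min = -(spec.head_offset + spec.head_radius) - pad
    x_max = spec.trochanter_offset + spec.trochanter_bump_radius + pad
    r_max = max(spec.head_radius, spec.shaft_radius, spec.trochanter_bump_radius)
    y_min, y_max = -r_max - pad, r_max + pad
    z_min = -pad
    z_max = spec.shaft_length + spec.neck_length + spec.head_radius + pad
    if spec.tilt_deg:
        # a tilted shaft sweeps laterally; enlarge conservatively
        sweep = (z_max - z_min) * abs(math.sin(math.radians(spec.tilt_deg)))
        x_min -= sweep
        x_max += sweep
    dx, dy, dz = spec.spacing
    nx = int(math.ceil((x_max - x_min) / dx))
    ny = int(math.ceil((y_max - y_min) / dy))
    nz = int(math.ceil((z_max - z_min) / dz))
    origin = (x_min, y_min, z_min)
    return (nz, ny, nx), origin


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a synthetic encrusted-bone CT volume with ground truth.

    Deterministic for a fixed ``spec.seed``.  The returned
    ``bone_mask`` is the exact pre-blur rasterisation; ``volume`` is the
    degraded image (material HU sampling, Gaussian blur, additive noise).
    """
    rng = np.random.default_rng(spec.seed)
    shape, origin = _grid(spec)
    nz, ny, nx = shape
    dx, dy, dz = spec.spacing

    xw = origin[0] + np.arange(nx) * dx
    yw = origin[1] + np.arange(ny) * dy
    zw = origin[2] + np.arange(nz) * dz
    # sparse axes broadcast inside the primitive tests, keeping memory flat
    zz, yy, xx = np.meshgrid(zw, yw, xw, indexing="ij", sparse=True)

    if spec.tilt_deg:
        # rotate world coords back into the bone frame (tilt about y axis)
        th = math.radians(spec.tilt_deg)
        xb = math.cos(th) * xx - math.sin(th) * zz
        zb = math.sin(th) * xx + math.cos(th) * zz
        bone = _rasterize_bone(spec, xb, yy, zb)
    else:
        bone = _rasterize_bone(spec, xx, yy, zz)
    del xx, yy, zz

    # crust: shell of spatially varying thickness around the bone; the
    # smooth random field has ~8 mm correlation length and unit variance
    dist_mm = distance_transform_edt(~bone, sampling=(dz, dy, dx))
    field_sigma = [8.0 / dz, 8.0 / dy, 8.0 / dx]
    field = gaussian_filter(rng.standard_normal(shape), sigma=field_sigma)
    field /= max(float(field.std()), 1e-12)
    thickness = spec.crust_thickness_mean + spec.crust_thickness_sd * field
    thickness = np.clip(
        thickness,
        0.25 * spec.crust_thickness_mean,
        spec.crust_thickness_mean + 3.0 * spec.crust_thickness_sd,
    )
    crust = (~bone) & (dist_mm <= thickness)
    del dist_mm, field, thickness
    if not crust.any():
        raise ValueError("degenerate phantom: crust thinner than one voxel everywhere")

    hu = np.full(shape, spec.hu_background, dtype=np.float64)
    hu[bone] = rng.normal(spec.hu_bone_mean, spec.hu_bone_sd, int(bone.sum()))
    hu[crust] = rng.normal(spec.hu_calcite_mean, spec.hu_calcite_sd, int(crust.sum()))

    if spec.blur_sigma > 0:
        hu = gaussian_filter(hu, sigma=[spec.blur_sigma / dz, spec.blur_sigma / dy, spec.blur_sigma / dx])
    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, shape)

    volume = CTVolume(
        data=hu,
        spacing=spec.spacing,
        origin=origin,
        series_meta={"derivation_tag": "phantom", "phantom_seed": spec.seed},
    )
    truth = PhantomTruth(
        volume=volume,
        bone_mask=BinaryMask(bone, provenance=[f"phantom(seed={spec.seed})"]),
        true_measures={"Bp": spec.true_bp, "DC": spec.true_dc, "SD": spec.true_sd},
        spec=spec,
        crust_mask=BinaryMask(crust, provenance=[f"phantom-crust(seed={spec.seed})"]),
    )
    _assert_truth_closed_forms(truth)
    return truth


def _assert_truth_closed_forms(truth: PhantomTruth) -> None:
    s = truth.spec
    assert truth.true_measures["SD"] == 2.0 * s.shaft_radius
    assert truth.true_measures["DC"] == 2.0 * s.head_radius
    assert truth.true_measures["Bp"] == s.true_bp


def sphere_phantom(radius: float = 10.0, spacing=(0.5, 0.5, 0.5),
                   peak_hu: float = 1000.0, margin: float = 4.0) -> CTVolume:
    """Analytic solid sphere with a one-voxel partial-volume ramp.

    The intensity falls linearly from ``peak_hu`` to 0 across one voxel
    at the boundary, the band-limited profile a CT reconstruction
    produces; the half-max isosurface of this volume is the sphere of the
    requested radius.  Used as the geometric calibration object for
    surface extraction.
    """
    dx, dy, dz = spacing
    half = radius + margin
    xw = np.arange(-half, half + dx, dx)
    yw = np.arange(-half, half + dy, dy)
    zw = np.arange(-half, half + dz, dz)
    zz, yy, xx = np.meshgrid(zw, yw, xw, indexing="ij", sparse=True)
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    ramp = max(spacing)
    hu = peak_hu * np.clip(0.5 - (r - radius) / ramp, 0.0, 1.0)
    return CTVolume(hu, spacing, (float(xw[0]), float(yw[0]), float(zw[0])),
                    series_meta={"derivation_tag": "sphere-phantom"})


def _boundary_polygons(slice_mask: np.ndarray) -> list[np.ndarray]:
    """Pixel-edge boundary polygons of each connected component, (row, col)."""
    padded = np.pad(slice_mask, 1).astype(float)
    polys = []
    for poly in measure.find_contours(padded, 0.5):
        p = poly - 1.0  # undo padding
        if np.allclose(p[0], p[-1]):
            p = p[:-1]
        if len(p) >= 3:
            polys.append(p)
    return polys


def _resample_closed(poly_xy: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points, uniform in arc length."""
    closed = np.vstack([poly_xy, poly_xy[0]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def simulate_reader(
    truth: PhantomTruth,
    every_k: int = 10,
    vertex_noise_sd: float = 0.3,
    n_vertices: int = 120,
    seed: int = 0,
    reader_id: str = "R1",
) -> ContourSet:
    """Simulate one imperfect human reader tracing the bone on sparse slices.

    On every ``every_k``-th slice intersecting the bone (starting at the
    first such slice), the true in-plane boundary of each connected
    component is resampled to ``n_vertices`` points and each point is
    perturbed radially (away from the component centroid) by
    N(0, ``vertex_noise_sd``) mm.  Deterministic per seed.  With zero
    noise the contour follows the exact pixel-edge boundary, so it
    rasterises back to the true slice mask.
    """
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    mask = truth.bone_mask.data
    bone_slices = np.flatnonzero(mask.any(axis=(1, 2)))
    if len(bone_slices) < 2:
        raise ValueError("phantom bone occupies fewer than 2 slices")
    dx, dy, _ = truth.volume.spacing
    rng = np.random.default_rng(seed)

    contours = []
    for k in bone_slices[::every_k]:
        for poly_rc in _boundary_polygons(mask[k]):
            xy = np.column_stack([poly_rc[:, 1] * dx, poly_rc[:, 0] * dy])
            if vertex_noise_sd > 0:
                xy = _resample_closed(xy, n_vertices)
                centroid = xy.mean(axis=0)
                radial = xy - centroid
                norms = np.linalg.norm(radial, axis=1)
                norms[norms == 0] = 1.0
                unit = radial / norms[:, None]
                xy = xy + unit * rng.normal(0.0, vertex_noise_sd, len(xy))[:, None]
            contours.append(Contour(int(k), tuple(map(tuple, xy))))
    return ContourSet(
        reader_id=reader_id,
        contours=contours,
        grid_spacing=truth.volume.spacing,
        grid_shape=truth.volume.shape,
    )
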