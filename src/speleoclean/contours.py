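"""Sparse planar contours and shape-based inter-slice interpolation.

A manual segmentation of an encrusted specimen is a stack of closed
free-form regions of interest (ROIs): on a subset of axial slices
(typically every tenth) a reader traces the bone boundary as a polygon;
the slices in between are filled in computationally.  This module

* normalises contours to the drawing convention (clockwise in image
  coordinates, starting at the "twelve o'clock" vertex),
* rasterises polygons onto the voxel grid with an explicit pixel-centre
  even-odd rule,
* interpolates between keyframe slices by blending signed Euclidean
  distance fields (shape-based interpolation), and
* assembles a dense 3-D :class:`BinaryMask` congruent with the CT volume.

Distance fields are computed in millimetres so anisotropic in-plane
spacing is handled correctly; keyframe slices are reproduced bit-exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt
from shapely.geometry import LineString

from .volume import CTVolume

__all__ = [
    "Contour",
    "ContourSet",
    "BinaryMask",
    "normalize_contour",
    "rasterize_contour",
    "interpolate_masks",
    "build_dense_mask",
    "edit_mask",
    "read_contours",
    "write_contours",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contour:
    """A closed planar polygon on one axial slice.

    Vertices are in-plane ``(x, y)`` mm relative to the slice origin
    (i.e. pixel ``(j, i)`` has centre ``(i*dx, j*dy)``).  The polygon is
    always closed; the last vertex is not repeated.
    """

    slice_index: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=np.float64)


@dataclass
class ContourSet:
    """Per-reader collection of contours on a fixed voxel grid.

    ``grid_spacing`` is ``(dx, dy, dz)`` mm and ``grid_shape`` is
    ``(nz, ny, nx)`` of the annotated volume.  More than one contour per
    slice is allowed (multiply-connected cross-sections).
    """

    reader_id: str
    contours: list[Contour]
    grid_spacing: tuple[float, float, float]
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        nz = self.grid_shape[0]
        for c in self.contours:
            if not (0 <= c.slice_index < nz):
                raise ValueError(f"contour slice index {c.slice_index} outside grid of {nz} slices")

    @property
    def keyframes(self) -> list[int]:
        """Sorted slice indices that carry at least one contour."""
        return sorted({c.slice_index for c in self.contours})

    def on_slice(self, k: int) -> list[Contour]:
        return [c for c in self.contours if c.slice_index == k]


@dataclass
class BinaryMask:
    """Dense 3-D boolean grid congruent with a CT volume."""

    data: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D (z, y, x)")

    @property
    def shape(self):
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area in image coordinates (y grows downward).

    Negative area is defined as clockwise on screen.
    """
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_simple(vertices: np.ndarray) -> bool:
    ring = np.vstack([vertices, vertices[0]])
    return LineString(ring).is_simple


def normalize_contour(contour: Contour) -> Contour:
    """Normalise to the manual-drawing convention.

    The vertex order is made clockwise in image coordinates (negative
    signed area with y growing downward) and the starting vertex is the
    "twelve o'clock" one: maximal anatomical-up (smallest image y)
    relative to the centroid, ties broken by smallest x.  The geometry is
    unchanged — the vertex tuple is only reversed and/or cyclically
    rotated.  Idempotent.
    """
    v = contour.array
    if len(v) < 3:
        raise ValueError(f"contour needs >=3 vertices, got {len(v)}")
    if not _is_simple(v):
        raise ValueError("self-intersecting contour")
    area = _signed_area(v)
    if area == 0:
        raise ValueError("degenerate (zero-area) contour")
    if area > 0:  # counter-clockwise on screen -> reverse
        v = v[::-1]
    # twelve o'clock: minimal image y (maximal y-up), ties to smallest x
    order = np.lexsort((v[:, 0], v[:, 1]))
    start = int(order[0])
    v = np.roll(v, -start, axis=0)
    return Contour(contour.slice_index, tuple(map(tuple, v)))


def _points_in_polygon(px: np.ndarray, py: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, boundary-exclusive.

    A point is inside iff a ray to +x crosses the edges an odd number of
    times, with the half-open rule ``y0 <= py < y1`` on each edge so that
    vertices and horizontal edges are never double-counted.  Points
    exactly on a crossing resolve by strict inequality (outside).
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(vertices)
    for a in range(n):
        x0, y0 = vertices[a]
        x1, y1 = vertices[(a + 1) % n]
        if y0 == y1:
            continue
        crosses = (y0 <= py) != (y1 <= py)
        with np.errstate(invalid="ignore"):
            xi = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < xi)
    return inside


def rasterize_contour(contour: Contour, grid_spacing, grid_shape) -> np.ndarray:
    """Fill one contour on a 2-D slice grid by the pixel-centre rule.

    Pixel ``(j, i)`` is set iff its centre ``(i*dx, j*dy)`` lies strictly
    inside the polygon by the even-odd rule.  Parts of the contour outside
    the grid are clipped with a logged warning.
    """
    dx, dy = float(grid_spacing[0]), float(grid_spacing[1])
    ny, nx = int(grid_shape[-2]), int(grid_shape[-1])
    v = contour.array
    if (
        v[:, 0].min() < -dx / 2
        or v[:, 1].min() < -dy / 2
        or v[:, 0].max() > (nx - 0.5) * dx
        or v[:, 1].max() > (ny - 0.5) * dy
    ):
        logger.warning(
            "contour on slice %d extends outside the %dx%d grid; clipping",
            contour.slice_index, ny, nx,
        )
    # restrict the test to the polygon's bounding box for speed
    i0 = max(0, int(math.floor(v[:, 0].min() / dx)))
    i1 = min(nx - 1, int(math.ceil(v[:, 0].max() / dx)))
    j0 = max(0, int(math.floor(v[:, 1].min() / dy)))
    j1 = min(ny - 1, int(math.ceil(v[:, 1].max() / dy)))
    out = np.zeros((ny, nx), dtype=bool)
    if i1 < i0 or j1 < j0:
        return out
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1))
    out[j0 : j1 + 1, i0 : i1 + 1] = _points_in_polygon(ii * dx, jj * dy, v)
    return out


def _rasterize_slice(contours: list[Contour], grid_spacing, grid_shape) -> np.ndarray:
    """Union of the fills of all contours on one slice."""
    ny, nx = int(grid_shape[-2]), int(grid_shape[-1])
    out = np.zeros((ny, nx), dtype=bool)
    for c in contours:
        out |= rasterize_contour(c, grid_spacing, grid_shape)
    return out


def _signed_distance(mask: np.ndarray, sampling, cap: float) -> np.ndarray:
    """Signed EDT in mm: negative inside, positive outside, ±cap if empty/full."""
    if not mask.any():
        return np.full(mask.shape, cap, dtype=np.float64)
    if mask.all():
        return np.full(mask.shape, -cap, dtype=np.float64)
    outside = distance_transform_edt(~mask, sampling=sampling)
    inside = distance_transform_edt(mask, sampling=sampling)
    return outside - inside


def interpolate_masks(mask_a: np.ndarray, mask_b: np.ndarray, t: float, spacing=(1.0, 1.0)) -> np.ndarray:
    """Shape-based interpolation between two congruent 2-D masks.

    Blends the signed Euclidean distance fields,
    ``d = (1-t)*d_a + t*d_b``, and returns ``d < 0``.  ``t=0`` and ``t=1``
    reproduce the inputs bit-exactly.  If exactly one mask is empty its
    distance field is taken as a large positive constant (the grid
    diagonal), so the non-empty shape shrinks toward its skeleton as ``t``
    moves toward the empty side.

    ``spacing`` is the in-plane ``(dx, dy)`` in mm.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    if not mask_a.any() and not mask_b.any():
        raise ValueError("cannot interpolate between two empty masks")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    if t == 0.0:
        return mask_a.copy()
    if t == 1.0:
        return mask_b.copy()
    dx, dy = float(spacing[0]), float(spacing[1])
    sampling = (dy, dx)  # array axes are (row=y, col=x)
    ny, nx = mask_a.shape
    cap = math.hypot(nx * dx, ny * dy)
    d_a = _signed_distance(mask_a, sampling, cap)
    d_b = _signed_distance(mask_b, sampling, cap)
    return (1.0 - t) * d_a + t * d_b < 0.0


def build_dense_mask(contour_set: ContourSet, volume: CTVolume | None = None) -> BinaryMask:
    """Rasterise keyframes and interpolate every slice in between.

    Keyframe slices equal their rasterised contours exactly; a slice at
    fractional position ``t`` between its enclosing keyframes is filled by
    :func:`interpolate_masks`; slices before the first / after the last
    keyframe stay empty.
    """
    if volume is not None:
        if volume.shape != tuple(contour_set.grid_shape):
            raise ValueError("contour grid and volume shapes differ")
    shape = tuple(contour_set.grid_shape)
    spacing = contour_set.grid_spacing
    keyframes = contour_set.keyframes
    if len(keyframes) < 2:
        raise ValueError(
            "interpolation needs at least 2 keyframe slices; add contours on more slices"
        )
    data = np.zeros(shape, dtype=bool)
    key_masks = {
        k: _rasterize_slice(contour_set.on_slice(k), spacing, shape) for k in keyframes
    }
    for k, m in key_masks.items():
        data[k] = m
    for ka, kb in zip(keyframes[:-1], keyframes[1:]):
        for k in range(ka + 1, kb):
            t = (k - ka) / (kb - ka)
            data[k] = interpolate_masks(key_masks[ka], key_masks[kb], t, spacing[:2])
    stride = keyframes[1] - keyframes[0] if len(keyframes) > 1 else 0
    return BinaryMask(
        data=data,
        provenance=[
            f"build_dense_mask(reader={contour_set.reader_id}, "
            f"keyframes={len(keyframes)}, stride~{stride})"
        ],
    )


def edit_mask(mask: BinaryMask, slice_index: int, replacement_slice: np.ndarray) -> BinaryMask:
    """Programmatic stand-in for manual slice correction.

    Returns a copy of ``mask`` with one slice replaced; the edit is
    appended to the provenance audit trail.
    """
    nz = mask.shape[0]
    if not (0 <= slice_index < nz):
        raise IndexError(f"slice index {slice_index} out of range [0, {nz})")
    replacement = np.asarray(replacement_slice, dtype=bool)
    if replacement.shape != mask.shape[1:]:
        raise ValueError(f"replacement shape {replacement.shape} != slice shape {mask.shape[1:]}")
    data = mask.data.copy()
    data[slice_index] = replacement
    return BinaryMask(
        data=data,
        provenance=mask.provenance + [f"edit_mask(slice={slice_index})"],
    )


def write_contours(contour_set: ContourSet, path) -> Path:
    """Write the ``.contours.json`` interchange format."""
    path = Path(path)
    payload = {
        "reader_id": contour_set.reader_id,
        "spacing": list(contour_set.grid_spacing),
        "shape": list(contour_set.grid_shape),
        "contours": [
            {"slice_index": c.slice_index, "vertices_mm": [list(v) for v in c.vertices]}
            for c in contour_set.contours
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_contours(path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    return ContourSet(
        reader_id=payload["reader_id"],
        contours=[
            Contour(int(c["slice_index"]), tuple(map(tuple, c["vertices_mm"])))
            for c in payload["contours"]
        ],
        grid_spacing=tuple(payload["spacing"]),
        grid_shape=tuple(payload["shape"]),
    )
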