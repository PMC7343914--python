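"""Isosurface extraction and STL export of the cleaned specimen.

A triangulated surface is extracted from the virtually cleaned volume by
marching cubes at a Hounsfield threshold, placed in world millimetre
coordinates, reduced to its dominant connected component (suppressing
speckle from residual noise voxels), and exported as binary STL for
downstream dimensioning.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .volume import CTVolume

__all__ = [
    "SurfaceMesh",
    "extract_isosurface",
    "default_iso_hu",
    "largest_component",
    "write_stl",
    "read_stl",
    "write_ply",
]

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm coordinates.

    ``vertices`` is (n, 3) float ``(x, y, z)``; ``triangles`` is (m, 3)
    vertex indices wound so normals point outward.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh has non-finite vertex coordinates")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def enclosed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward winding."""
        return float(self.to_trimesh().volume)

    def triangle_areas(self) -> np.ndarray:
        return self.to_trimesh().area_faces


def default_iso_hu(volume: CTVolume, background_hu: float) -> float:
    """Default threshold: midpoint between background and the 5th
    percentile of supra-background voxels."""
    supra = volume.data[volume.data > background_hu]
    if supra.size == 0:
        raise ValueError("empty surface: no voxels above background")
    p5 = float(np.percentile(supra, 5))
    return 0.5 * (background_hu + p5)


def extract_isosurface(volume: CTVolume, iso_hu: float) -> SurfaceMesh:
    """Marching-cubes surface of ``volume`` at the HU threshold ``iso_hu``.

    Vertices are scaled by the voxel spacing and offset by the world
    origin; faces are wound so normals point away from the
    supra-threshold (specimen) region.  Degenerate (zero-area) triangles
    are dropped.
    """
    lo, hi = float(volume.data.min()), float(volume.data.max())
    if not (lo < iso_hu < hi):
        raise ValueError(
            f"empty surface: iso value {iso_hu} is not crossed (data range [{lo}, {hi}])"
        )
    dx, dy, dz = volume.spacing
    verts_zyx, faces, _, _ = measure.marching_cubes(
        volume.data, level=iso_hu, spacing=(dz, dy, dx)
    )
    verts = verts_zyx[:, ::-1] + np.asarray(volume.origin)

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if mesh.volume < 0:  # make winding outward
        mesh.invert()
    return SurfaceMesh(
        vertices=np.asarray(mesh.vertices),
        triangles=np.asarray(mesh.faces),
        provenance={
            "iso_hu": float(iso_hu),
            "source_tag": volume.series_meta.get("derivation_tag"),
        },
    )


def largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    """Keep the connected component with the largest enclosed |volume|.

    Discarded components are logged with their volumes.  An exact volume
    tie is broken toward the component containing the smallest vertex
    index, with a warning.
    """
    tm = mesh.to_trimesh()
    if len(tm.faces) == 0:
        raise ValueError("empty mesh")
    labels = trimesh.graph.connected_component_labels(tm.face_adjacency, node_count=len(tm.faces))
    n_comp = int(labels.max()) + 1 if len(labels) else 0
    if n_comp <= 1:
        return mesh

    stats = []
    for c in range(n_comp):
        face_idx = np.flatnonzero(labels == c)
        sub = tm.submesh([face_idx], append=True)
        min_vertex = int(tm.faces[face_idx].min())
        stats.append((abs(float(sub.volume)), min_vertex, face_idx, sub))
    stats.sort(key=lambda s: (-s[0], s[1]))
    best_vol = stats[0][0]
    if len(stats) > 1 and any(abs(s[0] - best_vol) == 0 for s in stats[1:]):
        logger.warning("volume tie between components; keeping the one with the "
                       "smallest vertex index")
    for vol, _, face_idx, _ in stats[1:]:
        logger.info("discarding component: %d faces, enclosed volume %.3f mm^3",
                    len(face_idx), vol)
    keep = stats[0][3]
    if keep.volume < 0:
        keep.invert()
    return SurfaceMesh(
        vertices=np.asarray(keep.vertices),
        triangles=np.asarray(keep.faces),
        provenance={**mesh.provenance, "largest_component_of": n_comp},
    )


def write_stl(mesh: SurfaceMesh, path, tag: str | None = None) -> Path:
    """Write binary STL (little-endian); the 80-byte header carries the
    provenance tag.  File size is exactly ``80 + 4 + 50 * n_triangles``.
    """
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValueError("refusing to write non-finite vertex coordinates")
    path = Path(path)
    tag = tag if tag is not None else str(mesh.provenance.get("source_tag") or "speleoclean")
    header = tag.encode("ascii", "replace")[:80].ljust(80, b"\x00")

    tris = mesh.vertices[mesh.triangles].astype("<f4")  # (m, 3, 3)
    a = tris[:, 1] - tris[:, 0]
    b = tris[:, 2] - tris[:, 0]
    normals = np.cross(a, b)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals = (normals / norms).astype("<f4")

    record = np.zeros(len(tris), dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    record["n"] = normals
    record["v"] = tris
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", len(tris)))
        fh.write(record.tobytes())
    return path


def read_stl(path) -> SurfaceMesh:
    """Read a binary STL written by :func:`write_stl` (or any binary STL).

    Duplicate vertices are merged; the header tag is recovered into the
    provenance.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(80)
        (n,) = struct.unpack("<I", fh.read(4))
        record = np.frombuffer(
            fh.read(50 * n), dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        )
    tris = record["v"].astype(np.float64)
    flat = tris.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    tag = header.rstrip(b"\x00").decode("ascii", "replace")
    return SurfaceMesh(vertices=verts, triangles=faces, provenance={"source_tag": tag})


def write_ply(mesh: SurfaceMesh, path, vertex_scalars: np.ndarray | None = None,
              scalar_name: str = "quality") -> Path:
    """ASCII PLY export, optionally with one float scalar per vertex
    (used for deviation heat maps)."""
    path = Path(path)
    n_v, n_f = len(mesh.vertices), len(mesh.triangles)
    if vertex_scalars is not None and len(vertex_scalars) != n_v:
        raise ValueError("vertex_scalars length must equal the vertex count")
    lines = [
        "ply", "format ascii 1.0",
        f"comment {mesh.provenance.get('source_tag') or 'speleoclean'}",
        f"element vertex {n_v}",
        "property float x", "property float y", "property float z",
    ]
    if vertex_scalars is not None:
        lines.append(f"property float {scalar_name}")
    lines += [f"element face {n_f}", "property list uchar int vertex_indices", "end_header"]
    for i, v in enumerate(mesh.vertices):
        row = f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}"
        if vertex_scalars is not None:
            row += f" {float(vertex_scalars[i]):.6f}"
        lines.append(row)
    for f in mesh.triangles:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path
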