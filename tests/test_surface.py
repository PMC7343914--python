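"""Isosurface extraction, component filtering and STL/PLY round trips."""

import math

import numpy as np
import pytest

from speleoclean.phantom import sphere_phantom
from speleoclean.surface import (
    SurfaceMesh,
    default_iso_hu,
    extract_isosurface,
    largest_component,
    read_stl,
    write_ply,
    write_stl,
)
from speleoclean.volume import CTVolume


@pytest.fixture(scope="module")
def sphere_mesh():
    return extract_isosurface(sphere_phantom(radius=10.0, spacing=(0.5, 0.5, 0.5)), 500.0)


def test_sphere_area_within_2_percent(sphere_mesh):
    truth = 4 * math.pi * 10.0**2
    assert abs(sphere_mesh.area - truth) / truth < 0.02


def test_sphere_volume_within_1_percent(sphere_mesh):
    truth = 4.0 / 3.0 * math.pi * 10.0**3
    assert abs(sphere_mesh.enclosed_volume - truth) / truth < 0.01


def test_anisotropic_sampling_preserves_isotropy():
    vol = sphere_phantom(radius=10.0, spacing=(0.33, 0.33, 0.67))
    mesh = extract_isosurface(vol, 500.0)
    ext = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    assert abs(ext[2] - ext[0]) <= 0.67  # within one z voxel


def test_world_origin_shift_commutes(sphere_mesh):
    vol = sphere_phantom(radius=6.0, spacing=(0.5, 0.5, 0.5))
    shifted = CTVolume(vol.data, vol.spacing,
                       (vol.origin[0] + 5.0, vol.origin[1] - 2.0, vol.origin[2] + 11.0))
    m0 = extract_isosurface(vol, 500.0)
    m1 = extract_isosurface(shifted, 500.0)
    np.testing.assert_allclose(m1.vertices - m0.vertices,
                               np.broadcast_to([5.0, -2.0, 11.0], m0.vertices.shape),
                               atol=1e-9)


def test_outward_normals_positive_enclosed_volume(sphere_mesh):
    assert sphere_mesh.enclosed_volume > 0


def test_no_iso_crossing_is_an_error():
    vol = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1))
    with pytest.raises(ValueError, match="empty surface"):
        extract_isosurface(vol, 500.0)


def test_default_iso_between_background_and_object():
    vol = sphere_phantom(radius=8.0, spacing=(0.5, 0.5, 0.5))
    iso = default_iso_hu(vol, background_hu=0.0)
    assert 0.0 < iso < 1000.0


def test_mesh_volume_agrees_with_voxel_count(small_truth):
    """Enclosed mesh volume of the thresholded truth mask within 3 % of
    the voxel-count volume."""
    truth = small_truth
    vol = CTVolume(truth.bone_mask.data.astype(float), truth.volume.spacing,
                   truth.volume.origin)
    mesh = extract_isosurface(vol, 0.5)
    voxel_volume = truth.bone_mask.voxel_count() * np.prod(truth.volume.spacing)
    assert abs(mesh.enclosed_volume - voxel_volume) / voxel_volume < 0.03


# ------------------------------------------------------------- components
def _cube_mesh(centre, size):
    c = np.asarray(centre, float)
    s = size / 2.0
    verts = c + s * np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                              [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])
    faces = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                      [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
                      [1, 2, 6], [1, 6, 5], [0, 4, 7], [0, 7, 3]])
    return verts, faces


def _merge(meshes):
    verts, faces = [], []
    offset = 0
    for v, f in meshes:
        verts.append(v)
        faces.append(f + offset)
        offset += len(v)
    return SurfaceMesh(np.vstack(verts), np.vstack(faces))


def test_largest_component_keeps_single_component(sphere_mesh):
    out = largest_component(sphere_mesh)
    assert len(out.triangles) == len(sphere_mesh.triangles)


def test_sphere_plus_tiny_cube_keeps_sphere(sphere_mesh):
    combined = _merge([
        (sphere_mesh.vertices, sphere_mesh.triangles),
        _cube_mesh((40, 40, 40), 1.0),
    ])
    out = largest_component(combined)
    assert len(out.triangles) == len(sphere_mesh.triangles)
    assert abs(out.enclosed_volume - sphere_mesh.enclosed_volume) < 1e-6


def test_equal_volume_tie_keeps_smallest_vertex_index(caplog):
    combined = _merge([_cube_mesh((0, 0, 0), 2.0), _cube_mesh((10, 0, 0), 2.0)])
    with caplog.at_level("WARNING"):
        out = largest_component(combined)
    assert out.vertices[:, 0].max() < 5.0  # the first cube survived
    assert any("tie" in r.getMessage() for r in caplog.records)


# ---------------------------------------------------------------- STL, PLY
def test_stl_round_trip_preserves_triangles_and_volume(tmp_path, sphere_mesh):
    path = tmp_path / "sphere.stl"
    write_stl(sphere_mesh, path, tag="unit-sphere-test")
    back = read_stl(path)
    assert len(back.triangles) == len(sphere_mesh.triangles)
    assert back.provenance["source_tag"] == "unit-sphere-test"
    # volume re-measured after single-precision storage
    assert back.enclosed_volume == pytest.approx(sphere_mesh.enclosed_volume, rel=1e-4)


def test_stl_file_size_record_arithmetic(tmp_path):
    mesh = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
                       np.array([[0, 1, 2], [0, 1, 3]]))
    path = write_stl(mesh, tmp_path / "two.stl")
    assert path.stat().st_size == 80 + 4 + 2 * 50


def test_nonfinite_vertices_refused(tmp_path):
    with pytest.raises(ValueError):
        SurfaceMesh(np.array([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]]))


def test_ply_with_scalar_channel(tmp_path, sphere_mesh):
    scalars = np.linspace(0, 1, len(sphere_mesh.vertices))
    path = write_ply(sphere_mesh, tmp_path / "m.ply", vertex_scalars=scalars)
    text = path.read_text().splitlines()
    assert "property float quality" in text[:12]
    n_v = len(sphere_mesh.vertices)
    first_vertex = text[text.index("end_header") + 1].split()
    assert len(first_vertex) == 4  # x y z quality
    with pytest.raises(ValueError, match="length"):
        write_ply(sphere_mesh, tmp_path / "bad.ply", vertex_scalars=scalars[:-1])
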