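"""Contour normalisation, rasterisation, and shape-based interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speleoclean.contours import (
    BinaryMask,
    Contour,
    ContourSet,
    build_dense_mask,
    edit_mask,
    interpolate_masks,
    normalize_contour,
    rasterize_contour,
    read_contours,
    write_contours,
)


# ---------------------------------------------------------------- normalise
def test_normalize_flips_counterclockwise_square():
    # both traversal directions of the unit square must come out with
    # negative shoelace area (the clockwise convention, y down) and the
    # same start vertex
    ccw = Contour(0, ((0, 0), (1, 0), (1, 1), (0, 1)))
    cw = Contour(0, ((0, 0), (0, 1), (1, 1), (1, 0)))
    for square in (ccw, cw):
        out = normalize_contour(square)
        assert set(out.vertices) == set(square.vertices)  # geometry unchanged
        assert out.vertices[0] == (0.0, 0.0)  # top-left: smallest y, then smallest x
        # clockwise = negative signed area in image coords
        v = out.array
        area = 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert area < 0


def test_normalize_is_idempotent():
    c = normalize_contour(Contour(3, ((2, 5), (4, 1), (6, 5), (4, 8))))
    again = normalize_contour(c)
    assert again.vertices == c.vertices


def test_twelve_oclock_tie_breaks_to_smaller_x():
    # hexagon with a flat top: two equally-high vertices
    hexagon = Contour(0, ((1, 0), (3, 0), (4, 2), (3, 4), (1, 4), (0, 2)))
    out = normalize_contour(hexagon)
    assert out.vertices[0] == (1.0, 0.0)


def test_degenerate_contours_rejected():
    with pytest.raises(ValueError, match=">=3"):
        normalize_contour(Contour(0, ((0, 0), (1, 1))))
    bowtie = Contour(0, ((0, 0), (1, 1), (1, 0), (0, 1)))
    with pytest.raises(ValueError, match="self-intersect"):
        normalize_contour(bowtie)


# ---------------------------------------------------------------- rasterise
def test_square_covering_2x2_pixel_centers():
    # pixel centres at integer mm (spacing 1): square [-0.25, 1.25]^2
    square = Contour(0, ((-0.25, -0.25), (-0.25, 1.25), (1.25, 1.25), (1.25, -0.25)))
    out = rasterize_contour(square, (1.0, 1.0, 1.0), (1, 5, 5))
    assert out.sum() == 4
    assert out[:2, :2].all()


def _brute_force_even_odd(vertices, nx, ny, dx, dy):
    """Independent point-in-polygon oracle: angle-free crossing count per pixel."""
    out = np.zeros((ny, nx), dtype=bool)
    v = np.asarray(vertices, float)
    n = len(v)
    for j in range(ny):
        for i in range(nx):
            px, py = i * dx, j * dy
            crossings = 0
            for a in range(n):
                x0, y0 = v[a]
                x1, y1 = v[(a + 1) % n]
                if y0 == y1:
                    continue
                if (y0 <= py) != (y1 <= py):
                    xi = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
                    if px < xi:
                        crossings += 1
            out[j, i] = crossings % 2 == 1
    return out


@pytest.mark.parametrize("shift", [0.0, 0.5, 0.49, 0.51])
def test_rasterisation_matches_brute_force_oracle(shift):
    poly = [(0.7 + shift, 0.2), (3.4 + shift, 0.9), (3.9 + shift, 3.4),
            (1.2 + shift, 3.9), (0.2 + shift, 2.0)]
    got = rasterize_contour(Contour(0, tuple(poly)), (1.0, 1.0, 1.0), (1, 6, 6))
    want = _brute_force_even_odd(poly, 6, 6, 1.0, 1.0)
    np.testing.assert_array_equal(got, want)


def test_two_disjoint_contours_union():
    a = Contour(0, ((-0.25, -0.25), (-0.25, 1.25), (1.25, 1.25), (1.25, -0.25)))
    b = Contour(0, ((3.75, 3.75), (3.75, 5.25), (5.25, 5.25), (5.25, 3.75)))
    grid = ((1.0, 1.0, 1.0), (1, 7, 7))
    union = rasterize_contour(a, *grid) | rasterize_contour(b, *grid)
    assert union.sum() == rasterize_contour(a, *grid).sum() + rasterize_contour(b, *grid).sum()


def test_out_of_grid_contour_clipped_with_warning(caplog):
    big = Contour(0, ((-5, -5), (-5, 10), (10, 10), (10, -5)))
    with caplog.at_level("WARNING"):
        out = rasterize_contour(big, (1.0, 1.0, 1.0), (1, 4, 4))
    assert out.all()  # everything inside the grid is covered
    assert any("clip" in r.getMessage() for r in caplog.records)


# -------------------------------------------------------------- interpolate
def _disc(radius, shape=(64, 64), centre=(32, 32)):
    jj, ii = np.mgrid[: shape[0], : shape[1]]
    return (ii - centre[1]) ** 2 + (jj - centre[0]) ** 2 <= radius**2


def test_interpolation_identity_for_equal_masks():
    m = _disc(12)
    for t in (0.0, 0.3, 0.5, 0.77, 1.0):
        np.testing.assert_array_equal(interpolate_masks(m, m, t), m)


def test_concentric_discs_blend_to_intermediate_radius():
    inner, outer = _disc(10), _disc(20)
    mid = interpolate_masks(inner, outer, 0.5)
    # SDF blend of concentric discs: disc of linearly interpolated radius
    expect_inner, expect_outer = _disc(14), _disc(16)
    assert not (mid & ~expect_outer).any()  # nothing outside radius 16
    assert (expect_inner & ~mid).sum() == 0  # radius-14 disc fully covered


def test_endpoints_bit_exact():
    a, b = _disc(7, centre=(20, 20)), _disc(11, centre=(40, 44))
    np.testing.assert_array_equal(interpolate_masks(a, b, 0.0), a)
    np.testing.assert_array_equal(interpolate_masks(a, b, 1.0), b)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    r_a=st.integers(4, 14), r_b=st.integers(4, 14),
    cx=st.integers(20, 44), t=st.floats(0.05, 0.95),
)
def test_interpolation_symmetry(r_a, r_b, cx, t):
    a = _disc(r_a, centre=(32, 24))
    b = _disc(r_b, centre=(30, cx))
    ab = interpolate_masks(a, b, t)
    ba = interpolate_masks(b, a, 1.0 - t)
    np.testing.assert_array_equal(ab, ba)


def test_one_empty_mask_shrinks_shape():
    # with the capped distance field of the empty side, the shape erodes
    # toward its skeleton as t moves toward the empty keyframe
    a = _disc(12)
    empty = np.zeros_like(a)
    near = interpolate_masks(a, empty, 0.02)
    far = interpolate_masks(a, empty, 0.08)
    assert 0 < far.sum() < near.sum() < a.sum()
    assert not (near & ~a).any()  # shrinks within the original shape
    assert not (far & ~near).any()  # nested erosion
    with pytest.raises(ValueError, match="empty"):
        interpolate_masks(empty, empty, 0.5)


def test_anisotropic_pixels_use_mm_distances():
    # with dx=2, dy=1 a circle in pixel units is an ellipse in mm; the
    # interpolant of a shape with itself must still be the identity, and
    # the blend between two discs must stay between them
    a, b = _disc(8), _disc(16)
    mid = interpolate_masks(a, b, 0.5, spacing=(2.0, 1.0))
    assert (a & ~mid).sum() == 0 and (mid & ~b).sum() == 0


# ----------------------------------------------------------- dense building
def _contour_set_from_discs(keyframes, radii, shape=(12, 48, 48), spacing=(1.0, 1.0, 1.0)):
    contours = []
    for k, r in zip(keyframes, radii):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        verts = tuple(
            (24 + r * np.cos(t), 24 + r * np.sin(t)) for t in theta
        )
        contours.append(Contour(k, verts))
    return ContourSet("R1", contours, spacing, shape)


def test_keyframe_slices_are_bit_exact():
    cs = _contour_set_from_discs([2, 8], [10, 15])
    mask = build_dense_mask(cs)
    for k in (2, 8):
        expected = rasterize_contour(cs.on_slice(k)[0], cs.grid_spacing, cs.grid_shape)
        np.testing.assert_array_equal(mask.data[k], expected)


def test_support_contract_outside_keyframes_empty():
    cs = _contour_set_from_discs([0, 9], [10, 10], shape=(10, 48, 48))
    mask = build_dense_mask(cs)
    assert all(mask.data[k].any() for k in range(10))
    cs2 = _contour_set_from_discs([3, 7], [10, 10], shape=(12, 48, 48))
    mask2 = build_dense_mask(cs2)
    assert not mask2.data[:3].any() and not mask2.data[8:].any()
    assert all(mask2.data[k].any() for k in range(3, 8))


def test_single_keyframe_is_an_error():
    cs = _contour_set_from_discs([4], [10])
    with pytest.raises(ValueError, match="at least 2 keyframe"):
        build_dense_mask(cs)


def test_dense_mask_equals_truth_when_contoured_on_every_slice(small_truth):
    from speleoclean.phantom import simulate_reader

    cs = simulate_reader(small_truth, every_k=1, vertex_noise_sd=0.0, seed=0)
    mask = build_dense_mask(cs, small_truth.volume)
    np.testing.assert_array_equal(mask.data, small_truth.bone_mask.data)


def test_contour_file_format_round_trip(tmp_path):
    cs = _contour_set_from_discs([2, 8], [10, 15])
    path = write_contours(cs, tmp_path / "r1.contours.json")
    back = read_contours(path)
    assert back.reader_id == cs.reader_id
    assert back.grid_shape == cs.grid_shape
    assert back.keyframes == cs.keyframes
    np.testing.assert_allclose(back.contours[0].array, cs.contours[0].array)


# ------------------------------------------------------------------- edits
def test_edit_mask_replace_and_audit_trail():
    base = BinaryMask(np.zeros((4, 8, 8), bool), provenance=["init"])
    full = np.ones((8, 8), bool)
    m1 = edit_mask(base, 1, full)
    assert m1.voxel_count() == 64
    m2 = edit_mask(m1, 1, m1.data[1])  # replace a slice with itself
    np.testing.assert_array_equal(m2.data, m1.data)
    m3 = edit_mask(m2, 1, np.zeros((8, 8), bool))
    assert m3.voxel_count() == 0  # conservation: drop by that slice's count
    assert m3.provenance == ["init", "edit_mask(slice=1)", "edit_mask(slice=1)",
                             "edit_mask(slice=1)"]
    with pytest.raises(IndexError):
        edit_mask(base, 9, full)
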