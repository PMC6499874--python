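"""Mesh primitives: normals, bounding boxes, poles, rigid maps, mirroring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from braintorque import (TriMesh, bounding_box, extract_pole, mirror_x,
                         rigid_transform, vertex_normals)

finite_coord = st.floats(-100, 100, allow_nan=False, allow_infinity=False)


def naive_vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Independent per-face accumulation oracle (plain Python loop)."""
    acc = np.zeros_like(mesh.vertices)
    for tri in mesh.faces:
        a, b, c = mesh.vertices[tri]
        cross = np.cross(b - a, c - a)       # |cross| = 2 * area
        for idx in tri:
            acc[idx] += 0.5 * cross
    return acc / np.linalg.norm(acc, axis=1)[:, None]


class TestVertexNormals:
    def test_sphere_normals_are_radial(self, icosphere):
        normals = vertex_normals(icosphere)
        radial = icosphere.vertices / np.linalg.norm(
            icosphere.vertices, axis=1)[:, None]
        assert np.allclose(normals, radial, atol=1e-2)

    def test_cube_face_interior_normals_are_axis_aligned(self, subdivided_cube):
        normals = vertex_normals(subdivided_cube)
        v = subdivided_cube.vertices
        on_boundary = np.isclose(np.abs(v), 0.5)
        interior = on_boundary.sum(axis=1) == 1  # on exactly one face
        assert interior.any()
        for idx in np.nonzero(interior)[0]:
            axis = int(np.argmax(on_boundary[idx]))
            expected = np.zeros(3)
            expected[axis] = np.sign(v[idx, axis])
            assert np.allclose(normals[idx], expected, atol=1e-9)

    def test_matches_naive_oracle_on_random_hull(self, rng):
        import trimesh
        pts = rng.normal(size=(100, 3))
        hull = trimesh.Trimesh(vertices=pts).convex_hull
        mesh = TriMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
        assert np.allclose(vertex_normals(mesh), naive_vertex_normals(mesh),
                           atol=1e-9)

    def test_convex_mesh_normals_point_outward(self, icosphere):
        normals = vertex_normals(icosphere)
        outward = np.einsum("ij,ij->i", normals,
                            icosphere.vertices - icosphere.centroid)
        assert (outward > 0).all()

    def test_inward_winding_is_corrected(self, icosphere):
        flipped = TriMesh(icosphere.vertices, icosphere.faces[:, ::-1])
        assert np.allclose(vertex_normals(flipped), vertex_normals(icosphere))

    def test_isolated_vertex_is_an_error(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5.0, 5, 5]])
        mesh = TriMesh(v, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="isolated"):
            vertex_normals(mesh)


class TestBoundingBox:
    def test_unit_cube_extents(self, subdivided_cube):
        box = bounding_box(subdivided_cube)
        assert np.allclose(box.extents, [1, 1, 1])
        assert box.width == box.length == box.height == pytest.approx(1.0)

    def test_scale_factor_is_linear(self, subdivided_cube):
        assert np.allclose(bounding_box(subdivided_cube, scale=2.0).extents,
                           [2, 2, 2])

    def test_matches_naive_min_max_scan(self, rng):
        pts = rng.uniform(-50, 50, size=(500, 3))
        mesh = TriMesh(pts, np.array([[0, 1, 2]]))
        box = bounding_box(mesh)
        lo = [min(p[k] for p in pts) for k in range(3)]
        hi = [max(p[k] for p in pts) for k in range(3)]
        assert np.allclose(box.min_corner, lo)
        assert np.allclose(box.max_corner, hi)

    def test_rejects_nonpositive_scale(self, subdivided_cube):
        with pytest.raises(ValueError):
            bounding_box(subdivided_cube, scale=0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(t=st.tuples(finite_coord, finite_coord, finite_coord),
           s=st.floats(0.01, 10))
    def test_translation_invariant_and_scale_equivariant(self, icosphere, t, s):
        moved = icosphere.with_vertices(icosphere.vertices + np.array(t))
        assert np.allclose(bounding_box(moved).extents,
                           bounding_box(icosphere).extents, atol=1e-9)
        scaled = icosphere.with_vertices(icosphere.vertices * s)
        assert np.allclose(bounding_box(scaled).extents,
                           bounding_box(icosphere).extents * s, rtol=1e-9)


@pytest.fixture(scope="module")
def ellipsoid(icosphere):
    return icosphere.with_vertices(icosphere.vertices * [30, 60, 40])


class TestExtractPole:
    def test_anterior_pole_of_ellipsoid(self, ellipsoid):
        pole = extract_pole(ellipsoid, "anterior")
        assert pole[1] == pytest.approx(60, abs=0.5)
        assert np.allclose(pole[[0, 2]], 0, atol=6)

    def test_translation_equivariance(self, ellipsoid):
        moved = ellipsoid.with_vertices(ellipsoid.vertices + [0, 5, 0])
        assert extract_pole(moved, "anterior")[1] == pytest.approx(
            extract_pole(ellipsoid, "anterior")[1] + 5)

    def test_tie_breaks_to_lowest_index(self):
        v = np.array([[0, 1.0, 0], [1, 1.0, 5], [0, 0, 1], [1, 0, 0]])
        mesh = TriMesh(v, np.array([[0, 1, 2], [1, 2, 3]]))
        assert np.allclose(extract_pole(mesh, "anterior"), v[0])

    def test_unknown_direction(self, ellipsoid):
        with pytest.raises(ValueError):
            extract_pole(ellipsoid, "sideways")


class TestRigidTransform:
    def test_identity(self, icosphere):
        out = rigid_transform(icosphere, np.eye(3), np.zeros(3))
        assert np.allclose(out.vertices, icosphere.vertices)

    def test_group_property(self, icosphere):
        r90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        r180_inv = Rotation.from_euler("z", -180, degrees=True).as_matrix()
        out = rigid_transform(
            rigid_transform(rigid_transform(icosphere, r90, np.zeros(3)),
                            r90, np.zeros(3)),
            r180_inv, np.zeros(3))
        assert np.allclose(out.vertices, icosphere.vertices, atol=1e-9)

    def test_axis_permutation_permutes_extents(self, rng):
        pts = rng.uniform(size=(50, 3)) * [3, 5, 7]
        mesh = TriMesh(pts, np.array([[0, 1, 2]]))
        # x->y->z->x cyclic permutation, determinant +1
        perm = np.array([[0., 0., 1.], [1., 0., 0.], [0., 1., 0.]])
        rotated = rigid_transform(mesh, perm, np.zeros(3))
        assert np.allclose(bounding_box(rotated).extents,
                           bounding_box(mesh).extents[[2, 0, 1]])

    def test_rejects_non_orthonormal(self, icosphere):
        with pytest.raises(ValueError):
            rigid_transform(icosphere, np.eye(3) * 2, np.zeros(3))
        with pytest.raises(ValueError):  # reflection (det -1)
            rigid_transform(icosphere, np.diag([-1.0, 1, 1]), np.zeros(3))


class TestMirrorX:
    def test_involution(self, icosphere):
        twice = mirror_x(mirror_x(icosphere))
        assert np.allclose(twice.vertices, icosphere.vertices)
        assert np.array_equal(twice.faces, icosphere.faces)

    def test_side_label_swaps(self, icosphere):
        left = TriMesh(icosphere.vertices - [50, 0, 0], icosphere.faces,
                       side="left")
        assert mirror_x(left).side == "right"

    def test_normals_commute_with_mirroring(self, icosphere):
        mirrored = vertex_normals(mirror_x(icosphere))
        expected = vertex_normals(icosphere) * [-1, 1, 1]
        assert np.allclose(mirrored, expected, atol=1e-9)
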