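import numpy as np
import pytest

import phasebasket as pb
from phasebasket.errors import GeometryError, LocationError, UsageError
from phasebasket.geometry import BarycentricCoord, subdivide
from phasebasket.io_formats import SPLINES, TriMesh


def node(spline, electrode):
    return spline * 8 + electrode


class TestTriangulateBasket:
    def test_level0_counts_and_euler(self, basket):
        m = basket.level0
        assert m.n_vertices == 64
        assert m.n_edges == 186
        assert m.n_faces == 124
        assert m.euler_characteristic() == 2

    def test_subsquare_diagonal_triangulation(self, basket):
        """Sub-square A1B1B2A2 carries triangles {A1,B1,B2} and {A1,B2,A2}."""
        a1, b1 = node(0, 0), node(1, 0)
        b2, a2 = node(1, 1), node(0, 1)
        face_sets = {frozenset(f) for f in basket.level0.faces.tolist()}
        assert frozenset([a1, b1, b2]) in face_sets
        assert frozenset([a1, b2, a2]) in face_sets

    def test_outward_normals(self, basket):
        m = basket.level0
        center = m.vertices.mean(axis=0)
        align = np.einsum(
            "ij,ij->i", m.face_normals(), m.face_centroids() - center
        )
        assert np.all(align > 0)

    def test_swapped_splines_detected(self, sphere_geometry):
        coords = dict(sphere_geometry.coords)
        for e in range(1, 9):  # swap spline columns B and D
            coords[("B", e)], coords[("D", e)] = coords[("D", e)], coords[("B", e)]
        bad = pb.ElectrodeGeometry(coords)
        with pytest.raises(GeometryError, match="crossed-spline"):
            pb.triangulate_basket(bad)

    def test_watertight_by_trimesh(self, basket):
        trimesh = pytest.importorskip("trimesh")
        tm = trimesh.Trimesh(
            vertices=basket.refined.vertices,
            faces=basket.refined.faces,
            process=False,
        )
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.euler_number == 2


class TestSubdivide:
    def test_refined_counts_after_three_rounds(self, basket):
        assert basket.refined.n_vertices == 3970
        assert basket.refined.n_faces == 7936

    def test_single_triangle_one_round(self):
        tri = TriMesh(vertices=np.eye(3), faces=[[0, 1, 2]])
        refined, ancestry, weights, _ = subdivide(tri, 1)
        assert refined.n_vertices == 6
        assert refined.n_faces == 4
        assert list(ancestry) == [0, 0, 0, 0]
        np.testing.assert_allclose(weights.sum(axis=1), 1.0)

    def test_zero_rounds_identity(self, basket):
        refined, _, _, _ = subdivide(basket.level0, 0)
        np.testing.assert_array_equal(refined.faces, basket.level0.faces)
        np.testing.assert_allclose(refined.vertices, basket.level0.vertices)

    def test_negative_rounds_rejected(self, basket):
        with pytest.raises(UsageError):
            subdivide(basket.level0, -1)

    @pytest.mark.parametrize("rounds", [1, 2, 3])
    def test_count_recurrences(self, basket, rounds):
        """V' = V + E, E' = 2E + 3F, F' = 4F per round, chi preserved."""
        v, e, f = 64, 186, 124
        for _ in range(rounds):
            v, e, f = v + e, 2 * e + 3 * f, 4 * f
        refined, _, _, _ = subdivide(basket.level0, rounds)
        assert refined.n_vertices == v
        assert refined.n_edges == e
        assert refined.n_faces == f
        assert refined.euler_characteristic() == 2

    def test_refined_vertices_on_ancestor_faces(self, basket):
        """Flat subdivision: weights are supported on the 3 electrodes of
        one level-0 face, and reproduce the vertex position exactly."""
        pos = basket.vertex_weights @ basket.level0.vertices
        np.testing.assert_allclose(pos, basket.refined.vertices, atol=1e-9)
        assert np.all((basket.vertex_weights > 1e-12).sum(axis=1) <= 3)


class TestInterpolation:
    def test_constant_field(self, basket):
        out = basket.interpolate(np.full(64, 3.25))
        np.testing.assert_allclose(out, 3.25, atol=1e-12)

    def test_affine_field_exact(self, basket):
        f = lambda p: 2.0 * p[:, 0] - 3.0 * p[:, 1] + 0.5 * p[:, 2] + 1.0
        out = basket.interpolate(f(basket.level0.vertices))
        np.testing.assert_allclose(out, f(basket.refined.vertices), atol=1e-9)

    def test_monotone_within_ancestor_range(self, basket):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-1, 1, 64)
        out = basket.interpolate(vals)
        for fi in [0, 100, 5000, 7935]:
            anc = basket.face_ancestry[fi]
            corners = basket.level0.faces[anc]
            for vi in basket.refined.faces[fi]:
                assert vals[corners].min() - 1e-12 <= out[vi]
                assert out[vi] <= vals[corners].max() + 1e-12

    def test_matches_locate_and_combine_oracle(self, basket):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=64)
        out = basket.interpolate(vals)
        # independent oracle: geometric barycentric solve per vertex
        for vi in rng.integers(0, 3970, size=50):
            anc = int(basket.vertex_ancestor_face[vi])
            corners = basket.level0.faces[anc]
            coord = pb.locate_barycentric(
                basket.level0, anc, basket.refined.vertices[vi]
            )
            expected = np.dot(coord.lambdas, vals[corners])
            assert out[vi] == pytest.approx(expected, abs=1e-9)

    def test_wrong_count_rejected(self, basket):
        with pytest.raises(UsageError):
            basket.interpolate(np.zeros(63))


class TestBarycentric:
    def test_centroid(self, basket):
        c = basket.level0.face_centroids()[5]
        coord = pb.locate_barycentric(basket.level0, 5, c)
        np.testing.assert_allclose(coord.lambdas, [1 / 3] * 3, atol=1e-9)

    def test_vertex(self, basket):
        v2 = basket.level0.vertices[basket.level0.faces[10][1]]
        coord = pb.locate_barycentric(basket.level0, 10, v2)
        np.testing.assert_allclose(coord.lambdas, [0, 1, 0], atol=1e-9)

    def test_random_interior_roundtrip(self, basket):
        rng = np.random.default_rng(5)
        for face in rng.integers(0, 124, size=20):
            lam = rng.dirichlet([1, 1, 1])
            p = lam @ basket.level0.vertices[basket.level0.faces[face]]
            coord = pb.locate_barycentric(basket.level0, int(face), p)
            np.testing.assert_allclose(
                pb.barycentric_position(basket.level0, coord), p, atol=1e-9
            )

    def test_point_off_face_rejected(self, basket):
        center = basket.level0.vertices.mean(axis=0)
        with pytest.raises(LocationError):
            pb.locate_barycentric(basket.level0, 0, center)

    def test_transfer_roundtrip_grid_basket(self, basket, grid):
        coord = BarycentricCoord(face=40, lambdas=(0.2, 0.5, 0.3))
        p3d = pb.transfer_point(grid.mesh, basket.level0, coord)
        back = pb.locate_barycentric(basket.level0, 40, p3d)
        p2d = pb.transfer_point(basket.level0, grid.mesh, back)
        np.testing.assert_allclose(
            p2d, pb.barycentric_position(grid.mesh, coord), atol=1e-9
        )

    def test_electrode_node_correspondence(self, basket, grid):
        """Grid node (spline j, electrode i) transfers to electrode (j, i)."""
        coord = grid.locate(np.array([2.0, 3.0]))  # node C4
        p3d = pb.transfer_point(grid.mesh, basket.level0, coord)
        np.testing.assert_allclose(
            p3d, basket.geometry.coords[("C", 4)], atol=1e-9
        )


class TestCurvature:
    def test_sphere(self, basket):
        """Refined basket connectivity with vertices projected onto a
        10 mm sphere: H = 0.1/mm (3%), K = 0.01/mm^2 (6%)."""
        v = basket.refined.vertices
        v10 = 10.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        mesh = TriMesh(vertices=v10, faces=basket.refined.faces)
        curv = pb.vertex_curvatures(mesh)
        ok = curv.reliable
        assert ok.mean() > 0.99
        np.testing.assert_allclose(curv.mean[ok], 0.1, rtol=0.03)
        np.testing.assert_allclose(curv.gaussian[ok], 0.01, rtol=0.06)

    def test_plane(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        verts = np.column_stack(
            [xs.ravel(), ys.ravel(), np.zeros(64)]
        )
        faces = []
        for j in range(7):
            for i in range(7):
                a = j * 8 + i
                faces.append([a, a + 8, a + 9])
                faces.append([a, a + 9, a + 1])
        curv = pb.vertex_curvatures(TriMesh(vertices=verts, faces=faces))
        ok = curv.reliable
        assert np.abs(curv.mean[ok]).max() < 1e-6
        assert np.abs(curv.gaussian[ok]).max() < 1e-6

    def test_cylinder(self):
        r, n_a, n_z = 10.0, 24, 15
        angles = 2 * np.pi * np.arange(n_a) / n_a
        zs = np.linspace(0, 40, n_z)
        verts = [
            [r * np.cos(a), r * np.sin(a), z] for z in zs for a in angles
        ]
        faces = []
        for iz in range(n_z - 1):
            for ia in range(n_a):
                a0 = iz * n_a + ia
                a1 = iz * n_a + (ia + 1) % n_a
                b0, b1 = a0 + n_a, a1 + n_a
                faces.append([a0, a1, b1])
                faces.append([a0, b1, b0])
        curv = pb.vertex_curvatures(TriMesh(vertices=np.array(verts), faces=faces))
        interior = np.zeros(len(verts), dtype=bool)
        interior[3 * n_a : -3 * n_a] = True
        interior &= curv.reliable
        np.testing.assert_allclose(curv.mean[interior], 1 / (2 * r), rtol=0.10)
        assert np.abs(curv.gaussian[interior]).max() < 0.1 * (1 / (2 * r)) ** 2

    def test_h_squared_bounds_k(self, basket):
        curv = pb.vertex_curvatures(basket.refined)
        ok = curv.reliable
        assert np.all(curv.mean[ok] ** 2 >= curv.gaussian[ok] - 1e-12)


class TestShellProjection:
    def test_scaled_shell_radial_correspondence(self, sphere_geometry):
        basket = pb.BasketMesh.build(sphere_geometry, rounds=1)
        center = sphere_geometry.as_array().mean(axis=0)
        shell = TriMesh(
            vertices=center + 1.5 * (basket.refined.vertices - center),
            faces=basket.refined.faces,
        )
        rng = np.random.default_rng(6)
        vals = rng.normal(size=basket.refined.n_faces)
        out, fallback = pb.project_to_shell(basket, vals, shell)
        assert not fallback.any()
        # each shell vertex is radially aligned with its basket vertex, so
        # it inherits the value of one of that vertex's incident faces
        for vi in rng.integers(0, shell.n_vertices, size=40):
            incident = set(np.flatnonzero(
                (basket.refined.faces == vi).any(axis=1)
            ))
            assert out[vi] in {vals[f] for f in incident}

    def test_constant_field(self, sphere_geometry):
        basket = pb.BasketMesh.build(sphere_geometry, rounds=1)
        center = sphere_geometry.as_array().mean(axis=0)
        shell = TriMesh(
            vertices=center + 2.0 * (basket.refined.vertices - center),
            faces=basket.refined.faces,
        )
        out, _ = pb.project_to_shell(
            basket, np.full(basket.refined.n_faces, 4.5), shell
        )
        np.testing.assert_allclose(out, 4.5)

    def test_matches_scalar_raycast_oracle(self, sphere_geometry):
        """Cross-check the vectorized ray caster against a plain
        one-ray-one-triangle plane-intersection oracle."""

        def hit_face(origin, direction, tri):
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            denom = n @ direction
            if abs(denom) < 1e-12:
                return None
            t = (n @ (tri[0] - origin)) / denom
            if t <= 1e-12:
                return None
            p = origin + t * direction
            # inside test via barycentric areas
            area = np.linalg.norm(n)
            for a, b in [(0, 1), (1, 2), (2, 0)]:
                sub = np.cross(tri[b] - tri[a], p - tri[a])
                if (sub @ n) / area < -1e-9 * area:
                    return None
            return t

        basket = pb.BasketMesh.build(sphere_geometry, rounds=0)
        center = sphere_geometry.as_array().mean(axis=0)
        rng = np.random.default_rng(7)
        shell_v = center + (1.4 + 0.1 * rng.uniform(size=(64, 1))) * (
            basket.level0.vertices - center
        )
        shell = TriMesh(vertices=shell_v, faces=basket.level0.faces)
        vals = rng.normal(size=basket.level0.n_faces)
        out, fallback = pb.project_to_shell(basket, vals, shell)
        tris = basket.level0.vertices[basket.level0.faces]
        dirs = shell.vertices - center
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for vi in range(0, 64, 7):
            if fallback[vi]:
                continue
            best_t, best_f = np.inf, None
            for fi in range(len(tris)):
                t = hit_face(center, dirs[vi], tris[fi])
                if t is not None and t < best_t - 1e-12:
                    best_t, best_f = t, fi
            assert best_f is not None
            assert out[vi] == vals[best_f]
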