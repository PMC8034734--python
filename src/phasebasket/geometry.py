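"""Basket and grid geometry.

The 64 basket electrodes live on an 8x8 lattice: splines A..H around the
catheter, electrodes 1..8 along each spline.  Two meshes are built from
them:

* a flat **2D grid** with unit electrode spacing, each of the 49
  sub-squares split into two triangles — sub-square A1B1B2A2 carries
  triangles (A1,B1,B2) and (A1,B2,A2);
* a **closed 3D basket shell** applying the same connectivity to the 3-D
  electrode coordinates, adding the wraparound spline column (H back to A)
  and capping each pole octagon with a 6-triangle fan, for 124 level-0
  faces and Euler characteristic 2.  Each face is then split four ways
  ("flat": edge midpoints, no smoothing) three times, giving 3970 vertices
  and 7936 faces, with every refined face mapped back to its level-0
  ancestor and every refined vertex carrying barycentric weights over the
  64 electrodes so that scalar interpolation is exact.

Because the side faces of the basket are built in the same order as the
grid faces, face index f < 98 means "the same sub-triangle" on both
surfaces, which is what makes 2D<->3D barycentric transfer a lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorrespondenceError, GeometryError, LocationError, UsageError
from .io_formats import ELECTRODES, SPLINES, ElectrodeGeometry, TriMesh

N_SIDE_FACES = 112  # 8 spline pairs x 7 electrode pairs x 2 triangles
N_GRID_FACES = 98  # 7 spline pairs (no wraparound)
N_LEVEL0_FACES = 124  # side + two 6-triangle pole fans


def _node(spline: int, electrode: int) -> int:
    """Vertex index of (spline, electrode), spline-major like
    :meth:`ElectrodeGeometry.as_array`."""
    return spline * 8 + electrode


def _side_faces(wrap: bool) -> np.ndarray:
    """Sub-square triangles in (spline-pair major, electrode-pair minor)
    order; two triangles per sub-square split along the A1-B2 diagonal:
    (A1,B1,B2) and (A1,B2,A2)."""
    faces = []
    n_pairs = 8 if wrap else 7
    for j in range(n_pairs):
        j2 = (j + 1) % 8
        for i in range(7):
            a1, b1 = _node(j, i), _node(j2, i)
            b2, a2 = _node(j2, i + 1), _node(j, i + 1)
            faces.append([a1, b1, b2])
            faces.append([a1, b2, a2])
    return np.array(faces, dtype=int)


def _pole_fans() -> np.ndarray:
    """Six-triangle fans closing the two pole octagons (electrode rows 1
    and 8), fanned from the spline-A vertex, wound consistently with the
    side faces."""
    row0 = [_node(j, 0) for j in range(8)]
    row7 = [_node(j, 7) for j in range(8)]
    faces = []
    for k in range(1, 7):  # bottom cap: reverse orientation
        faces.append([row0[0], row0[k + 1], row0[k]])
    for k in range(1, 7):  # top cap
        faces.append([row7[0], row7[k], row7[k + 1]])
    return np.array(faces, dtype=int)


@dataclass
class GridMesh2D:
    """Flat 8x8 electrode grid with unit spacing.

    Node (spline j, electrode i) sits at (x=j, y=i); distances are in
    electrode-spacing units.  Face ordering matches the non-wrap side
    faces of :class:`BasketMesh`, so face index f < 98 refers to the same
    sub-triangle on both surfaces.
    """

    mesh: TriMesh

    @classmethod
    def build(cls) -> "GridMesh2D":
        xy = np.array([[j, i, 0.0] for j in range(8) for i in range(8)])
        return cls(TriMesh(vertices=xy, faces=_side_faces(wrap=False)))

    def locate(self, point: np.ndarray) -> "BarycentricCoord":
        """Containing face and barycentric coordinates of a 2D point
        (x in [0,7] spline axis, y in [0,7] electrode axis)."""
        x, y = float(point[0]), float(point[1])
        if not (0 <= x <= 7 and 0 <= y <= 7):
            raise LocationError(f"point ({x}, {y}) outside the 8x8 grid")
        j = min(int(np.floor(x)), 6)
        i = min(int(np.floor(y)), 6)
        lx, ly = x - j, y - i
        # diagonal A1->B2 splits the sub-square; ly<=lx is triangle (A1,B1,B2)
        face = 2 * (j * 7 + i) + (0 if ly <= lx else 1)
        return locate_barycentric(self.mesh, face, np.array([x, y, 0.0]))


@dataclass
class BasketMesh:
    """Closed basket shell with its refinement and ancestry maps."""

    geometry: ElectrodeGeometry
    level0: TriMesh
    refined: TriMesh
    rounds: int
    face_ancestry: np.ndarray  # refined face -> level-0 face
    vertex_weights: np.ndarray  # (n_refined_vertices, 64) electrode weights
    vertex_ancestor_face: np.ndarray  # refined vertex -> a level-0 face
    flipped: bool = False  # whether winding was globally reversed to point outward

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, geometry: ElectrodeGeometry, rounds: int = 3) -> "BasketMesh":
        basket = triangulate_basket(geometry)
        return basket.refine(rounds)

    def refine(self, rounds: int) -> "BasketMesh":
        refined, ancestry, weights, vanc = subdivide(self.level0, rounds)
        return BasketMesh(
            geometry=self.geometry,
            level0=self.level0,
            refined=refined,
            rounds=rounds,
            face_ancestry=ancestry,
            vertex_weights=weights,
            vertex_ancestor_face=vanc,
            flipped=self.flipped,
        )

    # -- region bookkeeping ------------------------------------------------

    def region_of_level0_face(self, face: int) -> tuple[str, int, int]:
        """Region tag of a level-0 face: ('sub', i, j) with 1-based
        (electrode-pair, spline-pair) indices, ('wrap', i, 8) for the H->A
        column, or ('pole', 0|1, -1) for the caps."""
        if face < N_SIDE_FACES:
            j, i = divmod(face // 2, 7)
            if j < 7:
                return ("sub", i + 1, j + 1)
            return ("wrap", i + 1, 8)
        return ("pole", 0 if face < N_SIDE_FACES + 6 else 1, -1)

    def region_of_refined_face(self, face: int) -> tuple[str, int, int]:
        return self.region_of_level0_face(int(self.face_ancestry[face]))

    # -- interpolation -----------------------------------------------------

    def interpolate(self, electrode_values: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of 64 per-electrode scalars (or a
        (64, n) block) onto every refined vertex; electrode vertices keep
        their own values exactly."""
        electrode_values = np.asarray(electrode_values)
        if electrode_values.shape[0] != 64:
            raise UsageError("expected one value per electrode (64 rows)")
        return self.vertex_weights @ electrode_values

    def refined_face_barycentric_in_ancestor(self, face: int) -> "BarycentricCoord":
        """Centroid of a refined face expressed in its level-0 ancestor's
        barycentric coordinates."""
        anc = int(self.face_ancestry[face])
        corners = self.level0.faces[anc]  # electrode vertex ids
        w = self.vertex_weights[self.refined.faces[face]].mean(axis=0)
        lam = w[corners]
        if not np.isclose(lam.sum(), 1.0, atol=1e-9):
            raise GeometryError("refined face weights not supported on ancestor")
        return BarycentricCoord(face=anc, lambdas=tuple(lam))


@dataclass(frozen=True)
class BarycentricCoord:
    """A point inside a triangle face as weights over its three vertices."""

    face: int
    lambdas: tuple[float, float, float]

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if abs(lam.sum() - 1.0) > 1e-8:
            raise UsageError(f"barycentric weights must sum to 1; got {lam.sum()}")
        if lam.min() < -1e-9:
            raise UsageError(f"negative barycentric weight {lam.min()}")


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures with mean H=(k1+k2)/2 (1/mm) and
    Gaussian K=k1*k2 (1/mm^2); ``reliable`` flags vertices whose 2-ring
    supported a well-posed quadric fit."""

    k1: np.ndarray
    k2: np.ndarray
    reliable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reliable is None:
            self.reliable = np.ones(len(self.k1), dtype=bool)

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.k1 + self.k2)

    @property
    def gaussian(self) -> np.ndarray:
        return self.k1 * self.k2


# ---------------------------------------------------------------------------
# construction


def triangulate_basket(geometry: ElectrodeGeometry) -> BasketMesh:
    """Apply the grid connectivity to the 64 electrode coordinates,
    wrapping spline H back to A and capping the pole octagons.

    The result is a closed, consistently oriented manifold with V=64,
    E=186, F=124 and Euler characteristic 2.  Winding is normalised so
    face normals point away from the mesh centroid; any face whose normal
    still points inward afterwards indicates crossed splines and raises a
    :class:`GeometryError` (the automated form of plotting each surface
    and inspecting it).
    """
    vertices = geometry.as_array()
    faces = np.vstack([_side_faces(wrap=True), _pole_fans()])
    mesh = TriMesh(vertices=vertices, faces=faces.copy())
    center = vertices.mean(axis=0)
    radial = mesh.face_centroids() - center
    align = np.einsum("ij,ij->i", mesh.face_normals(), radial)
    flipped = False
    if np.median(align) < 0:  # left-handed electrode labelling; flip globally
        mesh = TriMesh(vertices=vertices, faces=faces[:, [0, 2, 1]])
        align = -align
        flipped = True
    bad = np.flatnonzero(align <= 0)
    if bad.size:
        raise GeometryError(
            f"crossed-spline diagnostic: {bad.size} faces with inward "
            f"normals (face indices {bad[:10].tolist()}...)"
        )
    if mesh.euler_characteristic() != 2:
        raise GeometryError("basket mesh is not a topological sphere")
    identity = np.eye(64)
    return BasketMesh(
        geometry=geometry,
        level0=mesh,
        refined=mesh,
        rounds=0,
        face_ancestry=np.arange(len(mesh.faces)),
        vertex_weights=identity,
        vertex_ancestor_face=_vertex_first_face(mesh),
        flipped=flipped,
    )


def _vertex_first_face(mesh: TriMesh) -> np.ndarray:
    anc = np.full(mesh.n_vertices, -1, dtype=int)
    for fi, f in enumerate(mesh.faces):
        for v in f:
            if anc[v] < 0:
                anc[v] = fi
    return anc


def subdivide(
    mesh: TriMesh, rounds: int
) -> tuple[TriMesh, np.ndarray, np.ndarray, np.ndarray]:
    """Flat 4-way subdivision with ancestry tracking.

    Each round inserts the midpoint of every edge and replaces each face
    by its three corner triangles plus the central one; counts follow
    V' = V + E, F' = 4F, E' = 2E + 3F.  Midpoints sit on the straight
    edge (no smoothing), so every refined vertex stays on its ancestral
    face and barycentric interpolation from the original vertices is
    exact.

    Returns ``(refined, face_ancestry, vertex_weights, vertex_ancestor)``
    where *face_ancestry* maps refined faces to input faces,
    *vertex_weights* expresses each refined vertex as a convex combination
    of the input vertices, and *vertex_ancestor* assigns each refined
    vertex one input face it lies on (the lowest-index face that created
    it).
    """
    if rounds < 0:
        raise UsageError("subdivision rounds must be >= 0")
    vertices = mesh.vertices.copy()
    faces = mesh.faces.copy()
    ancestry = np.arange(len(faces))
    weights = np.eye(mesh.n_vertices)
    vanc = _vertex_first_face(mesh)
    vanc0 = vanc.copy()

    for _ in range(rounds):
        midpoint_of: dict[tuple[int, int], int] = {}
        new_vertices = [vertices]
        new_weights = [weights]
        new_vanc = list(vanc)
        next_index = len(vertices)

        def midpoint(a: int, b: int, face_anc: int) -> int:
            nonlocal next_index
            key = (a, b) if a < b else (b, a)
            if key not in midpoint_of:
                midpoint_of[key] = next_index
                new_vertices.append(
                    0.5 * (vertices[a] + vertices[b]).reshape(1, 3)
                )
                new_weights.append(
                    0.5 * (weights[a] + weights[b]).reshape(1, -1)
                )
                new_vanc.append(face_anc)
                next_index += 1
            return midpoint_of[key]

        new_faces = []
        new_ancestry = []
        for fi, (a, b, c) in enumerate(faces):
            anc = int(ancestry[fi])
            mab = midpoint(a, b, anc)
            mbc = midpoint(b, c, anc)
            mca = midpoint(c, a, anc)
            new_faces.extend(
                [[a, mab, mca], [b, mbc, mab], [c, mca, mbc], [mab, mbc, mca]]
            )
            new_ancestry.extend([anc] * 4)
        vertices = np.vstack(new_vertices)
        weights = np.vstack(new_weights)
        faces = np.array(new_faces, dtype=int)
        ancestry = np.array(new_ancestry, dtype=int)
        vanc = np.array(new_vanc, dtype=int)

    refined = TriMesh(vertices=vertices, faces=faces)
    # original vertices keep their original ancestor faces
    vanc[: len(vanc0)] = vanc0
    return refined, ancestry, weights, vanc


# ---------------------------------------------------------------------------
# barycentric machinery


def locate_barycentric(
    mesh: TriMesh, face: int, point: np.ndarray, tol: float = 1e-6
) -> BarycentricCoord:
    """Barycentric coordinates of *point* on the given face.

    The point must lie on (or numerically near) the face plane and inside
    the triangle to within ``-1e-9`` in each weight.
    """
    tri = mesh.vertices[mesh.faces[face]]
    point = np.asarray(point, dtype=float)
    a = np.vstack([tri.T, np.ones(3)])
    b = np.concatenate([point, [1.0]])
    lam, *_ = np.linalg.lstsq(a, b, rcond=None)
    recon = lam @ tri
    scale = max(1.0, np.abs(tri).max())
    if np.linalg.norm(recon - point) > tol * scale:
        raise LocationError(
            f"point {point} is {np.linalg.norm(recon - point):.3g} away "
            f"from face {face}"
        )
    if lam.min() < -1e-9:
        raise LocationError(f"point {point} outside face {face} (lambda={lam})")
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.sum()
    return BarycentricCoord(face=face, lambdas=tuple(lam))


def barycentric_position(mesh: TriMesh, coord: BarycentricCoord) -> np.ndarray:
    return np.asarray(coord.lambdas) @ mesh.vertices[mesh.faces[coord.face]]


def transfer_point(src: TriMesh, dst: TriMesh, coord: BarycentricCoord) -> np.ndarray:
    """Carry a barycentric point from one mesh to the corresponding face
    of another mesh sharing its face indexing."""
    if coord.face >= len(dst.faces):
        raise CorrespondenceError(
            f"face {coord.face} of source has no counterpart in destination "
            f"({len(dst.faces)} faces)"
        )
    return barycentric_position(dst, coord)


# ---------------------------------------------------------------------------
# curvature


def vertex_curvatures(mesh: TriMesh) -> CurvatureField:
    """Principal curvatures per vertex from a quadratic-patch fit.

    For each vertex the 2-ring neighbourhood is expressed in a local frame
    whose z-axis is the (area-weighted, outward) vertex normal; a full
    quadric ``h = a x^2 + b x y + c y^2 + d x + e y`` is fitted by least
    squares and the principal curvatures are the eigenvalues of the
    Weingarten map, signed so that a sphere with outward normals has
    positive mean curvature.  Vertices with fewer than 5 points in the
    2-ring are flagged unreliable (curvatures set to 0).
    """
    n_v = mesh.n_vertices
    # vertex normals: area-weighted face normals
    v = mesh.vertices[mesh.faces]
    fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # 2x area * unit normal
    normals = np.zeros((n_v, 3))
    for k in range(3):
        np.add.at(normals, mesh.faces[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    normals /= norm

    neighbors: list[set[int]] = [set() for _ in range(n_v)]
    for a, b in mesh.edges():
        neighbors[a].add(b)
        neighbors[b].add(a)

    k1 = np.zeros(n_v)
    k2 = np.zeros(n_v)
    reliable = np.zeros(n_v, dtype=bool)
    for vi in range(n_v):
        ring = set(neighbors[vi])
        for nb in list(ring):
            ring |= neighbors[nb]
        ring.discard(vi)
        pts = mesh.vertices[sorted(ring)] - mesh.vertices[vi]
        if len(pts) < 5:
            continue
        nz = normals[vi]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(nz @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        ex = np.cross(nz, ref)
        ex /= np.linalg.norm(ex)
        ey = np.cross(nz, ex)
        x, y, h = pts @ ex, pts @ ey, pts @ nz
        design = np.column_stack([x * x, x * y, y * y, x, y])
        try:
            coef, *_ = np.linalg.lstsq(design, h, rcond=None)
        except np.linalg.LinAlgError:
            continue
        a, b, c, d, e = coef
        denom = np.sqrt(1.0 + d * d + e * e)
        first = np.array([[1 + d * d, d * e], [d * e, 1 + e * e]])
        second = np.array([[2 * a, b], [b, 2 * c]]) / denom
        shape = np.linalg.solve(first, second)
        eig = np.linalg.eigvals(shape).real
        # height measured along the outward normal: convex surfaces have
        # negative hessian, so negate to make a sphere's curvature positive
        kk = -np.sort(eig)[::-1]
        k1[vi], k2[vi] = max(kk), min(kk)
        reliable[vi] = True
    return CurvatureField(k1=k1, k2=k2, reliable=reliable)


# ---------------------------------------------------------------------------
# shell projection


def project_to_shell(
    basket: BasketMesh, face_values: np.ndarray, shell: TriMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Carry per-face basket values onto the vertices of an anatomical shell.

    From the basket centre (mean of the 64 electrode coordinates) a ray is
    cast through every shell vertex; the value of the first basket face it
    hits (smallest positive ray parameter, ties broken by smallest face
    index) is assigned to that vertex.  Vertices whose ray misses every
    face fall back to the face whose centroid direction is angularly
    nearest and are flagged.

    Returns ``(values_per_shell_vertex, fallback_flags)``.
    """
    face_values = np.asarray(face_values, dtype=float)
    mesh = basket.refined
    if face_values.shape[0] != mesh.n_faces:
        raise UsageError("one value per refined basket face required")
    center = basket.geometry.as_array().mean(axis=0)
    directions = shell.vertices - center
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise GeometryError("shell vertex coincides with the basket centre")
    directions = directions / norms

    tri = mesh.vertices[mesh.faces]
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = np.empty(len(shell.vertices))
    fallback = np.zeros(len(shell.vertices), dtype=bool)
    centroid_dirs = mesh.face_centroids() - center
    centroid_dirs /= np.linalg.norm(centroid_dirs, axis=1, keepdims=True)

    chunk = 256
    eps = 1e-12
    for start in range(0, len(shell.vertices), chunk):
        d = directions[start : start + chunk]  # (m, 3)
        # Moller-Trumbore, broadcast rays x faces
        p = np.cross(d[:, None, :], e2[None, :, :])  # (m, f, 3)
        det = np.einsum("fk,mfk->mf", e1, p)
        valid = np.abs(det) > eps
        inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
        t_vec = center - v0  # (f, 3)
        u = np.einsum("fk,mfk->mf", t_vec, p) * inv_det
        q = np.cross(t_vec[None, :, :], e1[None, :, :])  # (1, f, 3)
        vv = np.einsum("mk,mfk->mf", d, np.broadcast_to(q, p.shape)) * inv_det
        t = np.einsum("fk,mfk->mf", e2, np.broadcast_to(q, p.shape)) * inv_det
        tol = 1e-9
        hit = valid & (u >= -tol) & (vv >= -tol) & (u + vv <= 1 + tol) & (t > eps)
        t_masked = np.where(hit, t, np.inf)
        # smallest positive t; ties (within 1e-12) broken by face index
        best = np.argmin(np.round(t_masked / 1e-12) * 1e-12, axis=1)
        has_hit = np.isfinite(t_masked[np.arange(len(d)), best])
        for m in range(len(d)):
            gi = start + m
            if has_hit[m]:
                out[gi] = face_values[best[m]]
            else:
                near = int(np.argmax(centroid_dirs @ d[m]))
                out[gi] = face_values[near]
                fallback[gi] = True
    return out, fallback
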