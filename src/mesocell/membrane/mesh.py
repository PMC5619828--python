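"""Closed triangulated surfaces with worm-like-chain reference state.

Sphere meshing targets an *arbitrary* vertex count (icosphere subdivision
cannot): a Fibonacci lattice is relaxed by point repulsion on the sphere
("spring relaxation") and triangulated with a convex hull.  All reference
quantities (edge lengths, triangle areas, dihedral angles, total area and
volume) are taken from the constructed state, which is therefore the
stress-free configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree


class GeometryError(ValueError):
    pass


@dataclass
class TriMesh:
    """Closed orientable genus-0 triangle mesh plus membrane parameters.

    Vertex coordinates live in a ParticleSystem; ``offset`` is the index of
    the first mesh vertex there.  Force routines take the (N_v, 3) vertex
    position block directly.
    """

    faces: np.ndarray           # (F, 3) outward-oriented
    edges: np.ndarray           # (E, 2)
    edge_l0: np.ndarray         # (E,)
    edge_lmax: np.ndarray       # (E,)
    face_a0: np.ndarray         # (F,)
    dihedrals: np.ndarray       # (D, 4) quadruples (k, i, j, l), shared edge (i, j)
    dihedral_phi0: np.ndarray   # (D,)
    area0: float
    volume0: float
    persistence: float = 0.00141
    c1: float = 0.0
    kb: float = 65.0
    ka: float = 10000.0
    kv: float = 15000.0
    gamma_c: float = 30.0
    kbt: float = 1.0
    offset: int = 0
    l0: float = field(default=0.0)  # mean reference edge length

    def __post_init__(self) -> None:
        if self.l0 == 0.0:
            self.l0 = float(np.mean(self.edge_l0))
        self.validate_topology()

    @property
    def gamma_t(self) -> float:
        """Tangential dissipative parameter, fixed at 3 gamma_C."""
        return 3.0 * self.gamma_c

    @property
    def n_vertices(self) -> int:
        return int(self.faces.max()) + 1

    @property
    def vertex_slice(self) -> slice:
        return slice(self.offset, self.offset + self.n_vertices)

    def validate_topology(self) -> None:
        nv = self.n_vertices
        nf = self.faces.shape[0]
        ne = self.edges.shape[0]
        if nf != 2 * nv - 4 or ne != 3 * nv - 6:
            raise GeometryError(
                f"not a closed genus-0 surface: V={nv}, E={ne}, F={nf}"
            )
        if np.any(self.edge_l0 >= self.edge_lmax):
            raise GeometryError("every edge requires l_0 < l_max")

    # -- geometry --------------------------------------------------------
    def area_volume(self, positions: np.ndarray) -> tuple[float, float]:
        """Total area and signed volume from oriented triangles."""
        a = positions[self.faces[:, 0]]
        b = positions[self.faces[:, 1]]
        c = positions[self.faces[:, 2]]
        cr = np.cross(b - a, c - a)
        area = 0.5 * float(np.linalg.norm(cr, axis=1).sum())
        volume = float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0
        return area, volume

    def edge_lengths(self, positions: np.ndarray) -> np.ndarray:
        d = positions[self.edges[:, 0]] - positions[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def contains(self, positions: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Point-in-closed-mesh test via the generalized winding number.

        Points outside the vertex bounding box (padded) are rejected without
        evaluating the winding sum.
        """
        points = np.atleast_2d(points)
        inside = np.zeros(points.shape[0], dtype=bool)
        verts = positions
        lo = verts.min(axis=0) - 1e-9
        hi = verts.max(axis=0) + 1e-9
        cand = np.flatnonzero(
            np.all((points >= lo) & (points <= hi), axis=1)
        )
        if cand.size == 0:
            return inside
        fa = verts[self.faces[:, 0]]
        fb = verts[self.faces[:, 1]]
        fc = verts[self.faces[:, 2]]
        chunk = max(1, int(4e6 / max(1, self.faces.shape[0])))
        for s in range(0, cand.size, chunk):
            idx = cand[s : s + chunk]
            p = points[idx]
            a = fa[None, :, :] - p[:, None, :]
            b = fb[None, :, :] - p[:, None, :]
            c = fc[None, :, :] - p[:, None, :]
            la = np.sqrt(np.einsum("pfi,pfi->pf", a, a))
            lb = np.sqrt(np.einsum("pfi,pfi->pf", b, b))
            lc = np.sqrt(np.einsum("pfi,pfi->pf", c, c))
            bxc = np.empty_like(a)
            bxc[..., 0] = b[..., 1] * c[..., 2] - b[..., 2] * c[..., 1]
            bxc[..., 1] = b[..., 2] * c[..., 0] - b[..., 0] * c[..., 2]
            bxc[..., 2] = b[..., 0] * c[..., 1] - b[..., 1] * c[..., 0]
            num = np.einsum("pfi,pfi->pf", a, bxc)
            den = (
                la * lb * lc
                + np.einsum("pfi,pfi->pf", a, b) * lc
                + np.einsum("pfi,pfi->pf", b, c) * la
                + np.einsum("pfi,pfi->pf", c, a) * lb
            )
            omega = 2.0 * np.arctan2(num, den)
            inside[idx] = omega.sum(axis=1) / (4.0 * np.pi) > 0.5
        return inside


def nucleus_diameter_from_nc(cell_diameter: float, nc_ratio: float) -> float:
    """Nucleus diameter from the projected-area nuclear-cytoplasmic ratio."""
    if nc_ratio < 0:
        raise ValueError("NC ratio must be nonnegative")
    return cell_diameter * float(np.sqrt(nc_ratio))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _relax_on_sphere(pts: np.ndarray, n_iter: int, k: int = 8) -> np.ndarray:
    """Short-range point repulsion constrained to the unit sphere."""
    n = pts.shape[0]
    target = np.sqrt(8.0 * np.pi / (np.sqrt(3.0) * (2 * n - 4)))
    for _ in range(n_iter):
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=k + 1)
        dist, idx = dist[:, 1:], idx[:, 1:]
        dr = pts[:, None, :] - pts[idx]
        d = np.maximum(dist, 1e-9)[:, :, None]
        w = np.maximum(0.0, target * 1.4 - dist)[:, :, None]
        step = (dr / d * w).sum(axis=1)
        pts = pts + 0.35 * step
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _hull_topology(points: np.ndarray) -> np.ndarray:
    """Outward-oriented convex-hull faces of points on a sphere."""
    hull = ConvexHull(points)
    faces = hull.simplices.copy()
    a = points[faces[:, 0]]
    b = points[faces[:, 1]]
    c = points[faces[:, 2]]
    normals = np.cross(b - a, c - a)
    centroids = (a + b + c) / 3.0
    flip = np.einsum("ij,ij->i", normals, centroids) < 0.0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def _edges_and_dihedrals(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edge_opp: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for f in faces:
        for e in range(3):
            i, j, k = int(f[e]), int(f[(e + 1) % 3]), int(f[(e + 2) % 3])
            key = (min(i, j), max(i, j))
            edge_opp.setdefault(key, []).append((i, j, k))
    edges = []
    dihedrals = []
    for (u, v), adj in sorted(edge_opp.items()):
        if len(adj) != 2:
            raise GeometryError(f"edge ({u},{v}) shared by {len(adj)} faces")
        edges.append((u, v))
        (i1, j1, k1), (_, _, k2) = adj
        # quadruple (k, i, j, l): opposite vertices around the shared edge,
        # winding taken from the first face so the torsion sign is consistent
        dihedrals.append((k1, i1, j1, k2))
    return np.array(edges, dtype=np.int64), np.array(dihedrals, dtype=np.int64)


def _dihedral_angles(quads: np.ndarray, positions: np.ndarray) -> np.ndarray:
    from mesocell.membrane.forces import dihedral_angles

    return dihedral_angles(quads, positions)


def c1_closed_form(l0: float, lmax: float, p: float, kbt: float) -> float:
    """Per-triangle repulsion coefficient balancing the WLC pull at l = l_0.

    From force balance on an equilateral triangulation: the WLC edge tension
    kbt x (6 - 9x + 4x^2) / (4 p (1-x)^2) at x = l0/lmax equals the area-term
    push 8 sqrt(3) C1 / (3 l0^3) from the two adjacent triangles (per-edge
    area derivative sqrt(3) l / 4 with the opposite vertex held fixed).
    """
    x0 = l0 / lmax
    if not 0.0 < x0 < 1.0:
        raise ValueError("l0/lmax must lie in (0, 1)")
    f_wlc = kbt * x0 * (6.0 - 9.0 * x0 + 4.0 * x0 * x0) / (4.0 * p * (1.0 - x0) ** 2)
    return f_wlc * 3.0 * l0**3 / (8.0 * np.sqrt(3.0))


def calibrate_c1(mesh: TriMesh, positions: np.ndarray) -> float:
    """Least-squares C1 minimizing net vertex forces at the reference state.

    The POW force is linear in C1, so the optimum is found in closed form.
    On symmetric meshes (regular icosahedron) the residual vanishes exactly.
    """
    from mesocell.membrane.forces import _wlc_forces, _pow_forces

    f_wlc = _wlc_forces(mesh, positions)
    saved = mesh.c1
    mesh.c1 = 1.0
    f_pow_unit = _pow_forces(mesh, positions)
    mesh.c1 = saved
    denom = float(np.sum(f_pow_unit * f_pow_unit))
    if denom == 0.0:
        raise GeometryError("degenerate mesh: zero POW force response")
    return -float(np.sum(f_wlc * f_pow_unit)) / denom


def _finalize_mesh(points: np.ndarray, faces: np.ndarray, lmax: float, **params) -> TriMesh:
    edges, dihedrals = _edges_and_dihedrals(faces)
    el = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    a = points[faces[:, 0]]
    b = points[faces[:, 1]]
    c = points[faces[:, 2]]
    cr = np.cross(b - a, c - a)
    face_a0 = 0.5 * np.linalg.norm(cr, axis=1)
    area0 = float(face_a0.sum())
    volume0 = float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0
    if volume0 <= 0:
        raise GeometryError("inconsistent orientation: nonpositive volume")
    mesh = TriMesh(
        faces=faces,
        edges=edges,
        edge_l0=el,
        edge_lmax=np.full(el.shape, float(lmax)),
        face_a0=face_a0,
        dihedrals=dihedrals,
        dihedral_phi0=np.zeros(dihedrals.shape[0]),
        area0=area0,
        volume0=volume0,
        **params,
    )
    mesh.dihedral_phi0 = _dihedral_angles(dihedrals, points)
    mesh.c1 = calibrate_c1(mesh, points)
    return mesh


def make_sphere_mesh(
    n_vertices: int,
    diameter: float,
    lmax: float = 3.0,
    n_relax: int = 120,
    **params,
) -> tuple[TriMesh, np.ndarray]:
    """Near-uniform closed triangulation of a sphere with exactly
    ``n_vertices`` vertices.  Returns (mesh, vertex positions).

    Extra keyword arguments set membrane parameters (kb, ka, kv, gamma_c,
    persistence, kbt).
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices")
    pts = _fibonacci_sphere(n_vertices)
    pts = _relax_on_sphere(pts, n_iter=n_relax)
    pts = pts * (diameter / 2.0)
    faces = _hull_topology(pts)
    mesh = _finalize_mesh(pts, faces, lmax, **params)
    return mesh, pts


def make_icosahedron_mesh(
    diameter: float = 2.0, lmax_factor: float = 3.0, **params
) -> tuple[TriMesh, np.ndarray]:
    """Regular icosahedron (12 vertices); exactly force-free reference state
    for the WLC/POW energy by symmetry."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    pts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= diameter / 2.0
    faces = _hull_topology(pts)
    edge_len = float(np.min(np.linalg.norm(pts[0] - pts[1:], axis=1)))
    mesh = _finalize_mesh(pts, faces, lmax_factor * edge_len, **params)
    return mesh, pts
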