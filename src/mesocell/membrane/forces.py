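"""Membrane force routines: WLC/POW elasticity, bending, constraints, viscosity.

Each conservative routine is the exact negative gradient of its energy
(checked against central differences in the test suite).
"""

from __future__ import annotations

import numpy as np

from mesocell.membrane.mesh import TriMesh, GeometryError


class OverstretchError(RuntimeError):
    def __init__(self, edge: int, x: float):
        super().__init__(f"edge {edge} overstretched: l/lmax = {x:.4f} >= 1")
        self.edge = edge


# ---------------------------------------------------------------------------
# WLC + POW in-plane elasticity
# ---------------------------------------------------------------------------

def _edge_geometry(mesh: TriMesh, positions: np.ndarray):
    d = positions[mesh.edges[:, 0]] - positions[mesh.edges[:, 1]]
    l = np.linalg.norm(d, axis=1)
    return d, l


def _check_stretch(mesh: TriMesh, l: np.ndarray) -> np.ndarray:
    x = l / mesh.edge_lmax
    if np.any(x >= 1.0):
        e = int(np.argmax(x))
        raise OverstretchError(e, float(x[e]))
    return x


def _wlc_forces(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    d, l = _edge_geometry(mesh, positions)
    x = _check_stretch(mesh, l)
    # dU/dl = kbt/(4p) * x (6 - 9x + 4x^2) / (1-x)^2
    tension = (
        mesh.kbt
        / (4.0 * mesh.persistence)
        * x
        * (6.0 - 9.0 * x + 4.0 * x * x)
        / (1.0 - x) ** 2
    )
    f_edge = -(tension / l)[:, None] * d  # on edge vertex 0
    forces = np.zeros_like(positions)
    np.add.at(forces, mesh.edges[:, 0], f_edge)
    np.add.at(forces, mesh.edges[:, 1], -f_edge)
    return forces


def _triangle_area_grads(positions: np.ndarray, faces: np.ndarray):
    a = positions[faces[:, 0]]
    b = positions[faces[:, 1]]
    c = positions[faces[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    if np.any(nn < 1e-14):
        raise GeometryError("degenerate (zero-area) triangle")
    nhat = n / nn[:, None]
    area = 0.5 * nn
    ga = 0.5 * np.cross(b - c, nhat)
    gb = 0.5 * np.cross(c - a, nhat)
    gc = 0.5 * np.cross(a - b, nhat)
    return area, ga, gb, gc


def _pow_forces(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    area, ga, gb, gc = _triangle_area_grads(positions, mesh.faces)
    coef = (mesh.c1 / area**2)[:, None]  # -d(C1/A)/dA = C1/A^2
    forces = np.zeros_like(positions)
    np.add.at(forces, mesh.faces[:, 0], coef * ga)
    np.add.at(forces, mesh.faces[:, 1], coef * gb)
    np.add.at(forces, mesh.faces[:, 2], coef * gc)
    return forces


def wlc_pow_forces(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    """Negative gradient of the in-plane elastic energy."""
    return _wlc_forces(mesh, positions) + _pow_forces(mesh, positions)


def wlc_pow_energy(mesh: TriMesh, positions: np.ndarray) -> float:
    _, l = _edge_geometry(mesh, positions)
    x = _check_stretch(mesh, l)
    u_wlc = (
        mesh.kbt
        * mesh.edge_lmax
        / (4.0 * mesh.persistence)
        * (3.0 * x * x - 2.0 * x**3)
        / (1.0 - x)
    ).sum()
    area, _, _, _ = _triangle_area_grads(positions, mesh.faces)
    return float(u_wlc + (mesh.c1 / area).sum())


# ---------------------------------------------------------------------------
# dihedral bending
# ---------------------------------------------------------------------------

def _dihedral_geometry(quads: np.ndarray, positions: np.ndarray):
    p0 = positions[quads[:, 0]]
    p1 = positions[quads[:, 1]]
    p2 = positions[quads[:, 2]]
    p3 = positions[quads[:, 3]]
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(n1sq < 1e-20) or np.any(n2sq < 1e-20) or np.any(lb2 < 1e-12):
        raise GeometryError("degenerate dihedral (collinear triple)")
    return b1, b2, b3, n1, n2, lb2, n1sq, n2sq


def dihedral_angles(quads: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Torsion angle of each (p0, p1, p2, p3) quadruple, in (-pi, pi]."""
    b1, b2, b3, n1, n2, lb2, _, _ = _dihedral_geometry(quads, positions)
    m = np.cross(n1, n2)
    y = np.einsum("ij,ij->i", m, b2) / lb2
    x = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, x)


def dihedral_angle_gradients(quads: np.ndarray, positions: np.ndarray):
    """phi and d(phi)/d(p0..p3) for each quadruple (standard closed form)."""
    b1, b2, b3, n1, n2, lb2, n1sq, n2sq = _dihedral_geometry(quads, positions)
    m = np.cross(n1, n2)
    y = np.einsum("ij,ij->i", m, b2) / lb2
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)
    g0 = -(lb2 / n1sq)[:, None] * n1
    g3 = (lb2 / n2sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / lb2**2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / lb2**2)[:, None]
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = c12 * g0 - (1.0 + c32) * g3
    return phi, g0, g1, g2, g3


def bending_forces(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    """Negative gradient of U_b = sum kb [1 - cos(phi - phi0)]."""
    phi, g0, g1, g2, g3 = dihedral_angle_gradients(mesh.dihedrals, positions)
    coef = (-mesh.kb * np.sin(phi - mesh.dihedral_phi0))[:, None]
    forces = np.zeros_like(positions)
    np.add.at(forces, mesh.dihedrals[:, 0], coef * g0)
    np.add.at(forces, mesh.dihedrals[:, 1], coef * g1)
    np.add.at(forces, mesh.dihedrals[:, 2], coef * g2)
    np.add.at(forces, mesh.dihedrals[:, 3], coef * g3)
    return forces


def bending_energy(mesh: TriMesh, positions: np.ndarray) -> float:
    phi = dihedral_angles(mesh.dihedrals, positions)
    return float(mesh.kb * (1.0 - np.cos(phi - mesh.dihedral_phi0)).sum())


# ---------------------------------------------------------------------------
# global area / volume constraints
# ---------------------------------------------------------------------------

def area_volume_forces(mesh: TriMesh, positions: np.ndarray) -> np.ndarray:
    """Negative gradient of the quadratic area and volume penalties."""
    area, ga, gb, gc = _triangle_area_grads(positions, mesh.faces)
    a_tot = float(area.sum())
    fa = positions[mesh.faces[:, 0]]
    fb = positions[mesh.faces[:, 1]]
    fc = positions[mesh.faces[:, 2]]
    v_tot = float(np.einsum("ij,ij->i", fa, np.cross(fb, fc)).sum()) / 6.0
    if v_tot <= 0.0:
        raise GeometryError("inconsistent orientation: nonpositive volume")
    dua = mesh.ka * mesh.kbt * (a_tot - mesh.area0) / (mesh.l0**2 * mesh.area0)
    duv = mesh.kv * mesh.kbt * (v_tot - mesh.volume0) / (mesh.l0**3 * mesh.volume0)
    forces = np.zeros_like(positions)
    np.add.at(forces, mesh.faces[:, 0], -dua * ga - duv * np.cross(fb, fc) / 6.0)
    np.add.at(forces, mesh.faces[:, 1], -dua * gb - duv * np.cross(fc, fa) / 6.0)
    np.add.at(forces, mesh.faces[:, 2], -dua * gc - duv * np.cross(fa, fb) / 6.0)
    return forces


def area_volume_energy(mesh: TriMesh, positions: np.ndarray) -> float:
    a_tot, v_tot = mesh.area_volume(positions)
    if v_tot <= 0.0:
        raise GeometryError("inconsistent orientation: nonpositive volume")
    ua = mesh.ka * mesh.kbt * (a_tot - mesh.area0) ** 2 / (2.0 * mesh.l0**2 * mesh.area0)
    uv = mesh.kv * mesh.kbt * (v_tot - mesh.volume0) ** 2 / (2.0 * mesh.l0**3 * mesh.volume0)
    return float(ua + uv)


# ---------------------------------------------------------------------------
# membrane viscosity (per-edge dissipative + random pair)
# ---------------------------------------------------------------------------

def membrane_viscous_forces(
    mesh: TriMesh,
    positions: np.ndarray,
    velocities: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-edge dissipative force plus its fluctuation-matched random force.

    F_D = -gamma_T v_ij - gamma_C (v_ij . rhat) rhat.  The random force is
    built from the traceless-symmetric part of a per-edge Wiener-increment
    matrix so an isolated membrane equilibrates to kbt.
    """
    if mesh.gamma_c < 0:
        raise ValueError("gamma_c must be nonnegative")
    gt, gc = mesh.gamma_t, mesh.gamma_c
    d, l = _edge_geometry(mesh, positions)
    rhat = d / l[:, None]
    vij = velocities[mesh.edges[:, 0]] - velocities[mesh.edges[:, 1]]
    f_d = -gt * vij - gc * np.einsum("ij,ij->i", vij, rhat)[:, None] * rhat

    ne = mesh.edges.shape[0]
    dw = rng.standard_normal((ne, 3, 3)) * np.sqrt(dt)
    dws = 0.5 * (dw + np.transpose(dw, (0, 2, 1)))
    tr = np.trace(dw, axis1=1, axis2=2)
    dws_bar = dws - (np.trace(dws, axis1=1, axis2=2) / 3.0)[:, None, None] * np.eye(3)
    amp_t = np.sqrt(2.0 * gt)
    amp_c = np.sqrt(max(3.0 * gc - gt, 0.0))
    mat = amp_t * dws_bar + (amp_c / 3.0) * tr[:, None, None] * np.eye(3)
    f_r = np.sqrt(2.0 * mesh.kbt) * np.einsum("eij,ej->ei", mat, rhat) / dt

    forces = np.zeros_like(positions)
    np.add.at(forces, mesh.edges[:, 0], f_d + f_r)
    np.add.at(forces, mesh.edges[:, 1], -(f_d + f_r))
    return forces


# ---------------------------------------------------------------------------
# bundle callback for the integrator
# ---------------------------------------------------------------------------

def membrane_callback(mesh: TriMesh, viscosity: bool = True):
    """Bonded-force callback adding all membrane terms for one mesh."""

    def cb(positions, velocities, forces, rng, dt):
        sl = mesh.vertex_slice
        p = positions[sl]
        f = wlc_pow_forces(mesh, p)
        f += bending_forces(mesh, p)
        f += area_volume_forces(mesh, p)
        if viscosity:
            f += membrane_viscous_forces(mesh, p, velocities[sl], dt, rng)
        forces[sl] += f

    return cb
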