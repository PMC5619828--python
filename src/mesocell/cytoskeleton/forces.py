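"""Bonded forces for the filament network: harmonic stretch/bend, torsion.

E_bond = k (r - r0)^2, E_angle = k (theta - theta0)^2 (no 1/2 factor),
E_torsion = k [1 - cos(phi - phi0)].  All forces are exact negative
gradients (central-difference checked in tests).
"""

from __future__ import annotations

import numpy as np

from mesocell.cytoskeleton.network import FilamentNetwork
from mesocell.membrane.forces import dihedral_angles, dihedral_angle_gradients
from mesocell.membrane.mesh import GeometryError


def _bond_forces(
    bonds: np.ndarray, k: np.ndarray, r0: np.ndarray, positions: np.ndarray, forces: np.ndarray
) -> None:
    if bonds.shape[0] == 0:
        return
    d = positions[bonds[:, 0]] - positions[bonds[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise GeometryError("zero-length bond")
    f = (-2.0 * k * (r - r0) / r)[:, None] * d
    np.add.at(forces, bonds[:, 0], f)
    np.add.at(forces, bonds[:, 1], -f)


def bond_tensions(network: FilamentNetwork, positions: np.ndarray) -> np.ndarray:
    """Spring-force magnitude |2 k (r - r0)| per bond (Bell-law input)."""
    d = positions[network.bonds[:, 0]] - positions[network.bonds[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return np.abs(2.0 * network.bond_k * (r - network.bond_r0))


def _angle_terms(angles: np.ndarray, positions: np.ndarray):
    u = positions[angles[:, 0]] - positions[angles[:, 1]]
    v = positions[angles[:, 2]] - positions[angles[:, 1]]
    lu = np.linalg.norm(u, axis=1)
    lv = np.linalg.norm(v, axis=1)
    if np.any(lu < 1e-12) or np.any(lv < 1e-12):
        raise GeometryError("zero-length bond in angle computation")
    uh = u / lu[:, None]
    vh = v / lv[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 0.0))
    return uh, vh, lu, lv, cos_t, sin_t, theta


def _angle_forces(
    angles: np.ndarray,
    k: np.ndarray,
    theta0: np.ndarray,
    positions: np.ndarray,
    forces: np.ndarray,
) -> None:
    if angles.shape[0] == 0:
        return
    uh, vh, lu, lv, cos_t, sin_t, theta = _angle_terms(angles, positions)
    # coefficient 2 k (theta - theta0) / sin(theta); finite limit -2k at
    # theta -> pi when theta0 = pi (collinear equilibrium)
    dev = theta - theta0
    near = sin_t < 1e-8
    ratio = np.where(near & (np.abs(dev) < 1e-6), -np.ones_like(dev), dev / np.maximum(sin_t, 1e-8))
    coef = 2.0 * k * ratio
    gi = (vh - cos_t[:, None] * uh) / lu[:, None]
    gk = (uh - cos_t[:, None] * vh) / lv[:, None]
    np.add.at(forces, angles[:, 0], coef[:, None] * gi)
    np.add.at(forces, angles[:, 2], coef[:, None] * gk)
    np.add.at(forces, angles[:, 1], -coef[:, None] * (gi + gk))


def bond_angle_forces(network: FilamentNetwork, positions: np.ndarray) -> np.ndarray:
    """Negative gradient of all harmonic bond + angle terms (incl. membrane links)."""
    forces = np.zeros_like(positions)
    _bond_forces(network.bonds, network.bond_k, network.bond_r0, positions, forces)
    if network.membrane_links.shape[0]:
        _bond_forces(
            network.membrane_links, network.link_k, network.link_r0, positions, forces
        )
    _angle_forces(
        network.angles, network.angle_k, network.angle_theta0, positions, forces
    )
    return forces


def bond_angle_energy(network: FilamentNetwork, positions: np.ndarray) -> float:
    e = 0.0
    for bonds, k, r0 in (
        (network.bonds, network.bond_k, network.bond_r0),
        (network.membrane_links, network.link_k, network.link_r0),
    ):
        if bonds.shape[0]:
            d = positions[bonds[:, 0]] - positions[bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            e += float((k * (r - r0) ** 2).sum())
    if network.angles.shape[0]:
        _, _, _, _, _, _, theta = _angle_terms(network.angles, positions)
        e += float((network.angle_k * (theta - network.angle_theta0) ** 2).sum())
    return e


def torsion_forces(network: FilamentNetwork, positions: np.ndarray) -> np.ndarray:
    """Negative gradient of k_tor [1 - cos(phi - phi0)] over CL dihedrals."""
    forces = np.zeros_like(positions)
    if network.torsions.shape[0] == 0:
        return forces
    phi, g0, g1, g2, g3 = dihedral_angle_gradients(network.torsions, positions)
    coef = (-network.torsion_k * np.sin(phi - network.torsion_phi0))[:, None]
    np.add.at(forces, network.torsions[:, 0], coef * g0)
    np.add.at(forces, network.torsions[:, 1], coef * g1)
    np.add.at(forces, network.torsions[:, 2], coef * g2)
    np.add.at(forces, network.torsions[:, 3], coef * g3)
    return forces


def torsion_energy(network: FilamentNetwork, positions: np.ndarray) -> float:
    if network.torsions.shape[0] == 0:
        return 0.0
    phi = dihedral_angles(network.torsions, positions)
    return float((network.torsion_k * (1.0 - np.cos(phi - network.torsion_phi0))).sum())


def network_callback(network: FilamentNetwork):
    """Bonded-force callback adding every network term."""

    def cb(positions, velocities, forces, rng, dt):
        forces += bond_angle_forces(network, positions)
        forces += torsion_forces(network, positions)

    return cb
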