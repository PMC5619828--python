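"""Topology container for the cross-linked filament network.

Default stiffness parameters (simulation units):

    kappa_fil     8e4    filament spring constant      (0.092 N/m)
    kappa_bend    350    filament bending stiffness    (4.025e-16 J)
    kappa_cl      8e3    cross-link spring constant    (0.0092 N/m)
    kappa_cl_fil  550    CL-filament bending stiffness (6.325e-16 J)
    k_tor         470    CL-filament torsion stiffness (4.7e-16 J)

Filament bonds/angles use theta_0 = pi (straight chains); the CL anchor
angle uses theta_0 = pi/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

KAPPA_FIL = 8.0e4
KAPPA_BEND = 350.0
KAPPA_CL = 8.0e3
KAPPA_CL_FIL = 550.0
K_TOR = 470.0
FILAMENT_R0 = 0.5
FILAMENT_LENGTH = 4.0


@dataclass
class FilamentNetwork:
    """Chains, bonds, angle triples, torsion quadruples and membrane links.

    All indices address particles in the owning ParticleSystem.  Bonds are
    E = k (r - r0)^2, angles E = k (theta - theta0)^2, torsions
    E = k [1 - cos(phi - phi0)].
    """

    chains: list = field(default_factory=list)  # list of int arrays
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsions: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), np.int64))
    torsion_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsion_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # merged filament-filament cross-link bonds also appear in `bonds`;
    # cl_pairs records which filament *chains* each merged CL joins,
    # cl_bond_particles the two filament *particles* it connects
    cl_pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    cl_bond_particles: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    # membrane links: (filament particle, membrane vertex particle)
    membrane_links: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), np.int64))
    link_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    link_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_filaments(self) -> int:
        return len(self.chains)

    def chain_of(self) -> dict[int, int]:
        """Map particle index -> chain index."""
        out: dict[int, int] = {}
        for ci, ch in enumerate(self.chains):
            for p in ch:
                out[int(p)] = ci
        return out

    def crosslinks_per_filament(self) -> np.ndarray:
        """Number of merged CL bonds touching each filament chain."""
        counts = np.zeros(self.n_filaments, dtype=np.int64)
        for a, b in self.cl_pairs:
            counts[a] += 1
            counts[b] += 1
        return counts

    def validate(self) -> None:
        seen: set[int] = set()
        for ch in self.chains:
            for p in ch:
                if int(p) in seen:
                    raise ValueError("particle belongs to more than one chain")
                seen.add(int(p))
        if self.membrane_links.shape[0]:
            fil = self.membrane_links[:, 0]
            if np.unique(fil).size != fil.size:
                raise ValueError("a filament particle carries two membrane links")
        if np.any(self.cl_pairs[:, 0] == self.cl_pairs[:, 1]):
            raise ValueError("CL connects a filament to itself")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "chains": [c.tolist() if isinstance(c, np.ndarray) else list(c) for c in self.chains],
            "bonds": self.bonds.tolist(),
            "bond_k": self.bond_k.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "angles": self.angles.tolist(),
            "angle_k": self.angle_k.tolist(),
            "angle_theta0": self.angle_theta0.tolist(),
            "torsions": self.torsions.tolist(),
            "torsion_k": self.torsion_k.tolist(),
            "torsion_phi0": self.torsion_phi0.tolist(),
            "cl_pairs": self.cl_pairs.tolist(),
            "cl_bond_particles": self.cl_bond_particles.tolist(),
            "membrane_links": self.membrane_links.tolist(),
            "link_k": self.link_k.tolist(),
            "link_r0": self.link_r0.tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "FilamentNetwork":
        doc = json.loads(text)
        return cls(
            chains=[np.asarray(c, dtype=np.int64) for c in doc["chains"]],
            bonds=np.asarray(doc["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_k=np.asarray(doc["bond_k"], dtype=float),
            bond_r0=np.asarray(doc["bond_r0"], dtype=float),
            angles=np.asarray(doc["angles"], dtype=np.int64).reshape(-1, 3),
            angle_k=np.asarray(doc["angle_k"], dtype=float),
            angle_theta0=np.asarray(doc["angle_theta0"], dtype=float),
            torsions=np.asarray(doc["torsions"], dtype=np.int64).reshape(-1, 4),
            torsion_k=np.asarray(doc["torsion_k"], dtype=float),
            torsion_phi0=np.asarray(doc["torsion_phi0"], dtype=float),
            cl_pairs=np.asarray(doc["cl_pairs"], dtype=np.int64).reshape(-1, 2),
            cl_bond_particles=np.asarray(doc["cl_bond_particles"], dtype=np.int64).reshape(-1, 2),
            membrane_links=np.asarray(doc["membrane_links"], dtype=np.int64).reshape(-1, 2),
            link_k=np.asarray(doc["link_k"], dtype=float),
            link_r0=np.asarray(doc["link_r0"], dtype=float),
        )

    def add_bond(self, i: int, j: int, k: float, r0: float) -> None:
        self.bonds = np.vstack([self.bonds, [[i, j]]]).astype(np.int64)
        self.bond_k = np.append(self.bond_k, k)
        self.bond_r0 = np.append(self.bond_r0, r0)

    def add_angle(self, i: int, j: int, k: int, kk: float, theta0: float) -> None:
        self.angles = np.vstack([self.angles, [[i, j, k]]]).astype(np.int64)
        self.angle_k = np.append(self.angle_k, kk)
        self.angle_theta0 = np.append(self.angle_theta0, theta0)
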