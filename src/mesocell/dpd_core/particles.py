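"""Particle container and thermodynamic state."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# particle type ids
FLUID = 1
FILAMENT = 2
MEMBRANE = 3
NUCLEUS = 4
WALL = 5

N_TYPES = 5


@dataclass
class ThermoState:
    """Thermostat target and integration step.

    Identical seeds on a single thread reproduce trajectories bit-for-bit.
    """

    kbt: float = 1.0
    dt: float = 1.0e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kbt <= 0:
            raise ValueError("kbt must be positive")


@dataclass
class ParticleSystem:
    """Positions, velocities, forces and type ids of all DPD particles.

    Lengths are in simulation units (1 sim length = 1 um).  Wall particles
    (type 5) are frozen: zero velocity at all times, never integrated.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    mass: float = 1.0
    forces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.forces is None:
            self.forces = np.zeros_like(self.positions)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shape mismatch")
        self.velocities[self.types == WALL] = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def mobile(self) -> np.ndarray:
        """Boolean mask of non-wall particles."""
        return self.types != WALL

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature of mobile particles."""
        m = self.mobile
        v = self.velocities[m]
        if v.shape[0] == 0:
            return 0.0
        return self.mass * float(np.sum(v * v)) / (3.0 * v.shape[0])

    def momentum(self) -> np.ndarray:
        """Total momentum of mobile particles."""
        return self.mass * self.velocities[self.mobile].sum(axis=0)

    def wrap(self) -> None:
        """Wrap positions into the primary box in periodic dimensions."""
        for d in range(3):
            if self.periodic[d]:
                self.positions[:, d] %= self.box[d]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            mass=self.mass,
            forces=self.forces.copy(),
        )


def concatenate(systems: list[ParticleSystem]) -> ParticleSystem:
    """Merge particle systems sharing the same box."""
    first = systems[0]
    return ParticleSystem(
        positions=np.concatenate([s.positions for s in systems]),
        velocities=np.concatenate([s.velocities for s in systems]),
        types=np.concatenate([s.types for s in systems]),
        box=first.box.copy(),
        periodic=first.periodic.copy(),
        mass=first.mass,
    )


def minimum_image(dr: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors."""
    dr = np.array(dr, dtype=np.float64, copy=True)
    for d in range(3):
        if periodic[d]:
            dr[..., d] -= box[d] * np.round(dr[..., d] / box[d])
    return dr
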