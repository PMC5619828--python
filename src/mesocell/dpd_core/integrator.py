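"""Modified velocity-Verlet time integration (DPD-VV, lambda = 1/2).

Per step:

    r(t+dt) = r(t) + dt v(t) + dt^2/2 f(t)
    v~      = v(t) + dt/2 f(t)
    f(t+dt) = f(r(t+dt), v~)                # pair + bonded + body forces
    v(t+dt) = v(t) + dt/2 [f(t) + f(t+dt)]

Wall particles are frozen (never integrated, velocity pinned to zero).
A signed-distance geometry may be attached; particles crossing into the
solid are bounce-back reflected (position mirrored along the trajectory,
velocity negated).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from mesocell.dpd_core.particles import ParticleSystem, ThermoState, WALL
from mesocell.dpd_core.interactions import InteractionTable
from mesocell.dpd_core.neighbors import build_neighbor_lists
from mesocell.dpd_core.forces import pair_forces_kernel

BondedCallback = Callable[[np.ndarray, np.ndarray, np.ndarray, np.random.Generator, float], None]


class InstabilityError(RuntimeError):
    def __init__(self, particle: int, message: str):
        super().__init__(f"particle {particle}: {message}")
        self.particle = particle


class Simulation:
    """Drives a ParticleSystem forward in time.

    Parameters
    ----------
    system, table, thermo :
        Particle container, type-pair interaction table, thermostat state.
    bonded_callbacks :
        Callables ``cb(positions, velocities, forces_out, rng, dt)`` adding
        bonded (membrane / cytoskeleton) forces in place.
    body_force :
        Optional uniform force vector applied to every particle selected by
        ``body_force_mask`` (defaults to all mobile particles).
    geometry :
        Optional object with ``sdf(points) -> signed distances`` (positive
        inside the solid) used for bounce-back reflection.
    """

    def __init__(
        self,
        system: ParticleSystem,
        table: InteractionTable,
        thermo: ThermoState,
        bonded_callbacks: Sequence[BondedCallback] = (),
        body_force: Optional[np.ndarray] = None,
        body_force_mask: Optional[np.ndarray] = None,
        geometry=None,
        skin: float = 0.3,
        check_stability: bool = True,
        frozen_mask: Optional[np.ndarray] = None,
        wrap_positions: bool = True,
    ):
        table.validate()
        self.system = system
        self.frozen_mask = frozen_mask
        self.table = table
        self.thermo = thermo
        self.bonded_callbacks = list(bonded_callbacks)
        self.body_force = None if body_force is None else np.asarray(body_force, float)
        self.body_force_mask = body_force_mask
        self.geometry = geometry
        self.wrap_positions = wrap_positions
        self.skin = float(skin)
        self.check_stability = check_stability
        self.rng = np.random.default_rng(thermo.seed)
        self.cutoff = table.max_cutoff()
        self.step_count = 0
        self._pairs = None
        self._ref_positions = None
        self._forces = None

    # -- neighbor bookkeeping -------------------------------------------
    def _pairs_current(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.system.positions
        if self._pairs is not None:
            disp = pos - self._ref_positions
            box, periodic = self.system.box, self.system.periodic
            for d in range(3):  # wrapping must not look like displacement
                if periodic[d]:
                    disp[:, d] -= box[d] * np.round(disp[:, d] / box[d])
            if float(np.abs(disp).max(initial=0.0)) < 0.5 * self.skin:
                return self._pairs
        self._pairs = build_neighbor_lists(self.system, self.cutoff + self.skin)
        self._ref_positions = pos.copy()
        return self._pairs

    # -- forces ----------------------------------------------------------
    def compute_forces(self, velocities: np.ndarray) -> np.ndarray:
        sys_ = self.system
        pi, pj = self._pairs_current()
        forces = np.zeros_like(sys_.positions)
        theta = self.rng.standard_normal(pi.shape[0])
        t = self.table
        pair_forces_kernel(
            sys_.positions,
            velocities,
            sys_.types,
            pi,
            pj,
            t.a,
            t.gamma,
            t.sigma,
            t.rc_rep,
            t.rc_th,
            t.excluded,
            t.weight_exponent,
            sys_.box,
            sys_.periodic,
            1.0 / np.sqrt(self.thermo.dt),
            theta,
            forces,
        )
        for cb in self.bonded_callbacks:
            cb(sys_.positions, velocities, forces, self.rng, self.thermo.dt)
        if self.body_force is not None:
            mask = (
                sys_.mobile if self.body_force_mask is None else self.body_force_mask
            )
            forces[mask] += self.body_force
        return forces

    # -- wall reflection -------------------------------------------------
    def _bounce_back(self, old_pos: np.ndarray, v_half: np.ndarray) -> None:
        sys_ = self.system
        mobile = sys_.mobile
        d = self.geometry.sdf(sys_.positions)
        crossed = np.flatnonzero((d > 0.0) & mobile)
        if crossed.size == 0:
            return
        # vectorized bisection for the crossing points along old -> new
        a = old_pos[crossed].copy()
        b = sys_.positions[crossed].copy()
        started_inside = self.geometry.sdf(a) > 0.0
        for _ in range(20):
            mid = 0.5 * (a + b)
            in_solid = self.geometry.sdf(mid) > 0.0
            b[in_solid] = mid[in_solid]
            a[~in_solid] = mid[~in_solid]
        cross = 0.5 * (a + b)
        cross[started_inside] = old_pos[crossed][started_inside]
        sys_.positions[crossed] = 2.0 * cross - sys_.positions[crossed]
        sys_.velocities[crossed] = -sys_.velocities[crossed]
        v_half[crossed] = -v_half[crossed]
        if crossed.size:
            depth = self.geometry.sdf(sys_.positions[crossed])
            worst = int(np.argmax(depth))
            if depth[worst] > self.cutoff:
                raise InstabilityError(
                    int(crossed[worst]),
                    f"inside solid by {depth[worst]:.3f} after reflection",
                )

    # -- stepping --------------------------------------------------------
    def step(self, n_steps: int = 1) -> ParticleSystem:
        sys_ = self.system
        dt = self.thermo.dt
        inv_m = 1.0 / sys_.mass
        mobile = sys_.mobile
        if self.frozen_mask is not None:
            mobile = mobile & ~self.frozen_mask
        if self._forces is None:
            self._forces = self.compute_forces(sys_.velocities)
        for _ in range(n_steps):
            f = self._forces
            v_half = sys_.velocities.copy()
            v_half[mobile] += 0.5 * dt * inv_m * f[mobile]
            disp = dt * v_half[mobile]
            if self.check_stability and disp.size:
                worst = int(np.argmax(np.abs(disp).max(axis=1)))
                if np.abs(disp[worst]).max() > self.cutoff:
                    idx = np.flatnonzero(mobile)[worst]
                    raise InstabilityError(
                        int(idx), f"displacement {np.abs(disp[worst]).max():.3f} > cutoff per step"
                    )
            old_pos = sys_.positions.copy()
            sys_.positions[mobile] += disp
            if self.geometry is not None:
                self._bounce_back(old_pos, v_half)
            if self.wrap_positions:
                sys_.wrap()
            f_new = self.compute_forces(v_half)
            sys_.velocities[mobile] = v_half[mobile] + 0.5 * dt * inv_m * f_new[mobile]
            sys_.velocities[~mobile] = 0.0
            self._forces = f_new
            self.step_count += 1
        return sys_

    def invalidate_neighbors(self) -> None:
        """Force a neighbor rebuild (after topology or position edits)."""
        self._pairs = None
        self._forces = None
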