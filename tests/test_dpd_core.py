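"""DPD core: pair forces, neighbor search, integrator, thermostat."""

import numpy as np
import pytest

from mesocell.dpd_core import (
    ParticleSystem,
    ThermoState,
    Simulation,
    InteractionTable,
    default_interactions,
    build_neighbor_lists,
    brute_force_pairs,
    conservative_force,
    dissipative_random_forces,
    DegeneratePairError,
    InstabilityError,
)
from mesocell.dpd_core.particles import FLUID, WALL
from mesocell.dpd_core.neighbors import ConfigurationError

from conftest import fluid_box_system


# ---------------------------------------------------------------------------
# conservative force
# ---------------------------------------------------------------------------

class TestConservativeForce:
    def test_zero_at_cutoff(self):
        f = conservative_force(np.array([1.0, 0.0, 0.0]), a=10.0, rc=1.0)
        assert np.allclose(f, 0.0)

    def test_linear_form_half_cutoff(self):
        f = conservative_force(np.array([0.5, 0.0, 0.0]), a=10.0, rc=1.0)
        assert np.linalg.norm(f) == pytest.approx(5.0)

    def test_filament_row_magnitude(self):
        # a = 100, R_c = 0.5, r = 0.25 -> magnitude 50
        f = conservative_force(np.array([0.25, 0.0, 0.0]), a=100.0, rc=0.5)
        assert np.linalg.norm(f) == pytest.approx(50.0)

    def test_repulsive_direction(self):
        r_ij = np.array([0.0, 0.3, 0.0])  # r_i - r_j
        f = conservative_force(r_ij, a=10.0, rc=1.0)
        assert np.dot(f, r_ij) > 0  # pushes i away from j

    def test_coincident_raises(self):
        with pytest.raises(DegeneratePairError):
            conservative_force(np.zeros(3), a=10.0, rc=1.0)


# ---------------------------------------------------------------------------
# dissipative / random forces
# ---------------------------------------------------------------------------

class TestThermostatPair:
    def test_perpendicular_velocity_zero_dissipative(self):
        r = np.array([0.5, 0.0, 0.0])
        v = np.array([0.0, 1.3, 0.0])
        f_d, _ = dissipative_random_forces(r, v, 30.0, np.sqrt(60.0), 1.0, 1.0, 0.7)
        assert np.allclose(f_d, 0.0)

    def test_weight_value(self):
        # w_R(R_c/2) = 0.5^0.25
        r = np.array([0.5, 0.0, 0.0])
        v = np.zeros(3)
        _, f_r = dissipative_random_forces(r, v, 30.0, np.sqrt(60.0), 1.0, 1.0, 1.0)
        w = np.linalg.norm(f_r) / np.sqrt(60.0)
        assert w == pytest.approx(0.5**0.25, rel=1e-12)

    def test_random_force_zero_mean(self):
        rng = np.random.default_rng(0)
        r = np.array([0.4, 0.0, 0.0])
        v = np.zeros(3)
        samples = np.empty(100_000)
        thetas = rng.standard_normal(samples.size)
        for k, th in enumerate(thetas):
            _, f_r = dissipative_random_forces(
                r, v, 30.0, np.sqrt(60.0), 1.0, 1.0, th
            )
            samples[k] = f_r[0]
        se = samples.std() / np.sqrt(samples.size)
        assert abs(samples.mean()) < 4.0 * se

    def test_sigma_consistency_enforced(self):
        with pytest.raises(ValueError):
            dissipative_random_forces(
                np.array([0.4, 0, 0]), np.zeros(3), 30.0, 1.0, 1.0, 1.0, 0.3
            )

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            dissipative_random_forces(
                np.array([0.4, 0, 0]), np.zeros(3), -1.0, 0.0, 1.0, 1.0, 0.3
            )


# ---------------------------------------------------------------------------
# interaction table
# ---------------------------------------------------------------------------

class TestInteractionTable:
    def test_symmetry_and_fdt(self, table):
        table.validate()
        assert np.allclose(table.sigma**2, 2.0 * table.gamma * table.kbt)

    def test_wall_wall_excluded(self, table):
        assert table.excluded[WALL, WALL]

    def test_dual_cutoffs_filament(self, table):
        assert table.rc_rep[2, 2] == 0.5
        assert table.rc_th[2, 2] == 1.0
        assert table.a[2, 2] == 100.0

    def test_asymmetric_rejected(self):
        t = default_interactions()
        t.a[1, 2] = 99.0  # break symmetry by hand
        with pytest.raises(ValueError):
            t.validate()


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

class TestNeighborLists:
    def _pair_set(self, pi, pj):
        return set(map(tuple, np.sort(np.column_stack([pi, pj]), axis=1)))

    def test_two_particles_within(self):
        s = ParticleSystem(
            np.array([[1.0, 1.0, 1.0], [1.9, 1.0, 1.0]]),
            np.zeros((2, 3)), np.full(2, FLUID),
            np.array([4.0, 4.0, 4.0]), [True] * 3,
        )
        pi, pj = build_neighbor_lists(s, 1.0)
        assert len(pi) == 1

    def test_two_particles_outside(self):
        s = ParticleSystem(
            np.array([[1.0, 1.0, 1.0], [2.1, 1.0, 1.0]]),
            np.zeros((2, 3)), np.full(2, FLUID),
            np.array([4.0, 4.0, 4.0]), [True] * 3,
        )
        pi, _ = build_neighbor_lists(s, 1.0)
        assert len(pi) == 0

    def test_against_brute_force(self):
        s = fluid_box_system(box_side=5.0, density=1.0, seed=3)
        pi, pj = build_neighbor_lists(s, 1.0)
        bi, bj = brute_force_pairs(s, 1.0)
        assert self._pair_set(pi, pj) == self._pair_set(bi, bj)

    def test_box_too_small(self):
        s = fluid_box_system(box_side=2.5, density=1.0, seed=0)
        with pytest.raises(ConfigurationError):
            build_neighbor_lists(s, 1.0)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

class TestIntegrator:
    def test_free_streaming(self):
        s = ParticleSystem(
            np.array([[2.0, 2.0, 2.0]]), np.array([[0.5, -0.25, 0.1]]),
            np.full(1, FLUID), np.array([5.0, 5.0, 5.0]), [True] * 3,
        )
        t = InteractionTable()  # all-zero forces
        sim = Simulation(s, t, ThermoState(seed=0))
        sim.step(1)
        assert np.allclose(
            s.positions[0], [2.0 + 0.5e-3, 2.0 - 0.25e-3, 2.0 + 0.1e-3]
        )

    def test_momentum_conservation_1000_steps(self, table):
        s = fluid_box_system(seed=4)
        sim = Simulation(s, table, ThermoState(seed=4))
        sim.step(200)
        p0 = s.momentum()
        sim.step(1000)
        assert np.abs(s.momentum() - p0).max() / s.n < 1e-10

    def test_determinism_bit_identical(self, table):
        def run():
            s = fluid_box_system(seed=5)
            Simulation(s, default_interactions(), ThermoState(seed=5)).step(150)
            return s.positions.copy(), s.velocities.copy()

        p1, v1 = run()
        p2, v2 = run()
        assert np.array_equal(p1, p2)
        assert np.array_equal(v1, v2)

    def test_wall_particles_never_move(self, table):
        rng = np.random.default_rng(6)
        box = np.full(3, 5.0)
        n = 300
        types = np.full(n, FLUID)
        types[:50] = WALL
        s = ParticleSystem(
            rng.uniform(0, 5, (n, 3)), np.zeros((n, 3)), types, box, [True] * 3
        )
        wall_pos = s.positions[:50].copy()
        sim = Simulation(s, table, ThermoState(seed=6))
        sim.step(300)
        assert np.array_equal(s.positions[:50], wall_pos)
        assert np.all(s.velocities[:50] == 0.0)

    def test_instability_detected(self):
        s = ParticleSystem(
            np.array([[2.0, 2.0, 2.0]]), np.array([[2000.0, 0.0, 0.0]]),
            np.full(1, FLUID), np.array([5.0, 5.0, 5.0]), [True] * 3,
        )
        sim = Simulation(s, InteractionTable(), ThermoState(seed=0))
        with pytest.raises(InstabilityError):
            sim.step(1)

    def test_particle_count_and_density_preserved(self, table):
        s = fluid_box_system(seed=7)
        n0 = s.n
        sim = Simulation(s, table, ThermoState(seed=7))
        sim.step(500)
        s.wrap()
        assert s.n == n0
        assert np.all(s.positions >= 0) and np.all(s.positions < s.box)


class TestThermostat:
    @pytest.mark.parametrize("gamma", [30.0, 45.0, 65.0])
    def test_equilibrium_temperature(self, gamma):
        t = default_interactions()
        t.set_pair(1, 1, 10.0, gamma)
        s = fluid_box_system(seed=11)
        sim = Simulation(s, t, ThermoState(seed=11))
        sim.step(1000)
        temps = []
        for _ in range(40):
            sim.step(50)
            temps.append(s.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(1.0, abs=0.03)

    def test_pair_antisymmetry_exact(self, table):
        # total pair force on an isolated pair must vanish component-wise
        from mesocell.dpd_core.forces import pair_forces_kernel

        s = ParticleSystem(
            np.array([[2.0, 2.0, 2.0], [2.4, 2.3, 2.1]]),
            np.array([[0.1, 0.0, 0.0], [0.0, -0.2, 0.3]]),
            np.full(2, FLUID), np.array([5.0, 5.0, 5.0]), [True] * 3,
        )
        forces = np.zeros((2, 3))
        pair_forces_kernel(
            s.positions, s.velocities, s.types,
            np.array([0]), np.array([1]),
            table.a, table.gamma, table.sigma, table.rc_rep, table.rc_th,
            table.excluded, table.weight_exponent, s.box, s.periodic,
            1.0 / np.sqrt(1e-3), np.array([0.83]), forces,
        )
        assert np.all(forces[0] == -forces[1])
        assert np.linalg.norm(forces[0]) > 0
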