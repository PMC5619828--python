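"""Cytoskeleton bonded forces and unbinding kinetics."""

import numpy as np
import pytest
from scipy import stats as sps

from mesocell.cytoskeleton import (
    FilamentNetwork,
    BellParameters,
    bell_rate,
    bell_unbind_probability,
    bond_angle_forces,
    bond_angle_energy,
    torsion_forces,
    torsion_energy,
)
from mesocell.cytoskeleton.network import KAPPA_FIL, KAPPA_CL
from mesocell.cytoskeleton.bell import CL_BELL
from mesocell.membrane.mesh import GeometryError
from mesocell.units import UnitSystem

from conftest import central_difference_check


def _toy_network():
    return FilamentNetwork(
        chains=[np.arange(5)],
        bonds=np.array([[0, 1], [1, 2], [2, 3], [3, 4], [1, 5]]),
        bond_k=np.array([KAPPA_FIL] * 4 + [KAPPA_CL]),
        bond_r0=np.array([0.5] * 4 + [0.25]),
        angles=np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4], [5, 1, 0]]),
        angle_k=np.array([350.0, 350.0, 350.0, 550.0]),
        angle_theta0=np.array([np.pi, np.pi, np.pi, np.pi / 2.0]),
        torsions=np.array([[0, 1, 5, 4]]),
        torsion_k=np.array([470.0]),
        torsion_phi0=np.array([0.3]),
    )


class TestBondAngle:
    def test_harmonic_minimum(self):
        net = FilamentNetwork(
            chains=[np.array([0, 1])],
            bonds=np.array([[0, 1]]),
            bond_k=np.array([KAPPA_FIL]),
            bond_r0=np.array([0.5]),
        )
        p = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        assert np.abs(bond_angle_forces(net, p)).max() == 0.0
        delta = 1e-3
        p2 = np.array([[0.0, 0.0, 0.0], [0.5 + delta, 0.0, 0.0]])
        assert bond_angle_energy(net, p2) == pytest.approx(
            KAPPA_FIL * delta**2, rel=1e-9
        )

    def test_collinear_triple_zero_force(self):
        net = FilamentNetwork(
            chains=[np.array([0, 1, 2])],
            bonds=np.array([[0, 1], [1, 2]]),
            bond_k=np.full(2, KAPPA_FIL),
            bond_r0=np.full(2, 0.5),
            angles=np.array([[0, 1, 2]]),
            angle_k=np.array([350.0]),
            angle_theta0=np.array([np.pi]),
        )
        p = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert np.abs(bond_angle_forces(net, p)).max() < 1e-9

    def test_gradient_consistency(self):
        net = _toy_network()
        rng = np.random.default_rng(1)
        p = rng.normal(0.0, 1.0, (6, 3))
        assert (
            central_difference_check(bond_angle_forces, bond_angle_energy, net, p)
            < 1e-4
        )

    def test_zero_length_bond_rejected(self):
        net = FilamentNetwork(
            chains=[np.array([0, 1, 2])],
            bonds=np.array([[0, 1]]),
            bond_k=np.array([1.0]),
            bond_r0=np.array([0.5]),
            angles=np.array([[0, 1, 2]]),
            angle_k=np.array([1.0]),
            angle_theta0=np.array([np.pi]),
        )
        p = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
        with pytest.raises(GeometryError):
            bond_angle_forces(net, p)


class TestTorsion:
    def test_zero_at_equilibrium(self):
        net = _toy_network()
        rng = np.random.default_rng(2)
        p = rng.normal(0.0, 1.0, (6, 3))
        from mesocell.membrane.forces import dihedral_angles

        net.torsion_phi0 = dihedral_angles(net.torsions, p)
        f = torsion_forces(net, p)
        assert np.abs(f).max() < 1e-9

    def test_energy_at_pi_offset(self):
        net = _toy_network()
        rng = np.random.default_rng(3)
        p = rng.normal(0.0, 1.0, (6, 3))
        from mesocell.membrane.forces import dihedral_angles

        net.torsion_phi0 = dihedral_angles(net.torsions, p) + np.pi
        assert torsion_energy(net, p) == pytest.approx(2.0 * 470.0)

    def test_gradient_consistency(self):
        net = _toy_network()
        rng = np.random.default_rng(4)
        p = rng.normal(0.0, 1.0, (6, 3))
        assert central_difference_check(torsion_forces, torsion_energy, net, p) < 1e-4

    def test_degenerate_dihedral_rejected(self):
        net = _toy_network()
        p = np.zeros((6, 3))
        p[1] = [1, 0, 0]
        p[5] = [2, 0, 0]  # collinear 0-1-5
        p[4] = [3, 1, 0]
        with pytest.raises(GeometryError):
            torsion_forces(net, p)


class TestBell:
    def test_contact_branch_ignores_force(self):
        # r < r0 -> rate kappa0 = 78/s regardless of load
        assert bell_rate(1.0e6, 0.1, CL_BELL) == pytest.approx(78.0)

    def test_unit_exponent(self):
        # lambda F = kbt -> rate = kappa0 e ~ 212/s
        f = 1.0 / CL_BELL.lam
        assert bell_rate(f, 0.3, CL_BELL) == pytest.approx(78.0 * np.e, rel=1e-12)

    def test_continuity_at_zero_force(self):
        below = bell_rate(0.0, 0.1, CL_BELL)
        above = bell_rate(0.0, 0.3, CL_BELL)
        assert below == above == pytest.approx(78.0)

    def test_monotone_in_force(self):
        forces = np.linspace(0.0, 1e5, 50)
        rates = bell_rate(forces, 0.3, CL_BELL)
        assert np.all(np.diff(rates) >= 0)

    def test_overflow_clamps_to_one(self):
        p = bell_unbind_probability(1e12, 0.3, CL_BELL, dt_phys=1e-3)
        assert p == pytest.approx(1.0)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            bell_rate(-1.0, 0.3, CL_BELL)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BellParameters(kappa0=-1.0, lam=0.0, r0=0.1)
        with pytest.raises(ValueError):
            BellParameters(kappa0=1.0, lam=-1.0, r0=0.1)

    def test_unloaded_survival_exponential(self):
        """KS test: survival sampled through the per-step probability is
        exponential with mean 1/kappa0."""
        rng = np.random.default_rng(8)
        units = UnitSystem()
        dt_sim = 50 * 1e-3  # one event sweep
        p = float(
            bell_unbind_probability(0.0, 0.3, CL_BELL, dt_sim=dt_sim, units=units)
        )
        dt_phys = dt_sim * units.time_si
        steps = rng.geometric(p, size=10_000)
        times = steps * dt_phys
        res = sps.kstest(times, "expon", args=(0.0, 1.0 / CL_BELL.kappa0))
        assert res.pvalue > 1e-3

    def test_dt_scaling(self):
        p1 = bell_unbind_probability(0.0, 0.3, CL_BELL, dt_phys=1e-6)
        p2 = bell_unbind_probability(0.0, 0.3, CL_BELL, dt_phys=2e-6)
        assert p2 == pytest.approx(2.0 * p1, rel=1e-4)


class TestNetworkContainer:
    def test_validate_duplicate_particle(self):
        net = FilamentNetwork(chains=[np.array([0, 1]), np.array([1, 2])])
        with pytest.raises(ValueError):
            net.validate()

    def test_validate_double_membrane_link(self):
        net = FilamentNetwork(
            chains=[np.array([0, 1])],
            membrane_links=np.array([[0, 5], [0, 6]]),
            link_k=np.ones(2),
            link_r0=np.full(2, 0.4),
        )
        with pytest.raises(ValueError):
            net.validate()

    def test_self_link_rejected(self):
        net = FilamentNetwork(
            chains=[np.array([0, 1])], cl_pairs=np.array([[0, 0]])
        )
        with pytest.raises(ValueError):
            net.validate()

    def test_json_round_trip(self):
        net = _toy_network()
        net2 = FilamentNetwork.from_json(net.to_json())
        assert np.array_equal(net.bonds, net2.bonds)
        assert np.allclose(net.angle_theta0, net2.angle_theta0)
        assert np.array_equal(net.torsions, net2.torsions)
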