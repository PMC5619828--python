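"""Shared fixtures.  Heavy objects are session-scoped and deterministic."""

from __future__ import annotations

import numpy as np
import pytest

from mesocell.dpd_core.particles import ParticleSystem, ThermoState, FLUID
from mesocell.dpd_core.interactions import default_interactions
from mesocell.membrane.mesh import make_sphere_mesh, make_icosahedron_mesh


def fluid_box_system(box_side: float = 5.0, density: float = 3.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    box = np.full(3, box_side)
    n = int(density * box.prod())
    return ParticleSystem(
        positions=rng.uniform(0.0, box, (n, 3)),
        velocities=np.zeros((n, 3)),
        types=np.full(n, FLUID),
        box=box,
        periodic=np.array([True, True, True]),
    )


@pytest.fixture()
def fluid_box():
    return fluid_box_system()


@pytest.fixture()
def table():
    return default_interactions()


@pytest.fixture()
def thermo():
    return ThermoState(seed=1)


@pytest.fixture(scope="session")
def icosa():
    return make_icosahedron_mesh(diameter=2.0)


@pytest.fixture(scope="session")
def small_sphere():
    return make_sphere_mesh(200, 6.0)


@pytest.fixture(scope="session")
def sphere_3500():
    """The full-resolution cell-surface mesh (built once; ~30 s)."""
    return make_sphere_mesh(3500, 16.0)


@pytest.fixture(scope="session")
def mini_cell():
    """Reduced-scale assembled cell (built once; ~2-3 min)."""
    from mesocell.cli_io.fixtures import make_fixture

    return make_fixture("mini-cell", seed=7)


def central_difference_check(force_fn, energy_fn, obj, positions, h=1e-6):
    """Max relative deviation between analytic forces and -grad(energy)."""
    f = force_fn(obj, positions)
    g = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            pp = positions.copy()
            pp[i, d] += h
            pm = positions.copy()
            pm[i, d] -= h
            g[i, d] = -(energy_fn(obj, pp) - energy_fn(obj, pm)) / (2.0 * h)
    scale = max(float(np.abs(g).max()), 1e-12)
    return float(np.abs(f - g).max()) / scale
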