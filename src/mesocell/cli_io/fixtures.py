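"""Named reduced-scale presets for desk-scale testing.

Every preset builds deterministically from its seed and runs end-to-end on
one CPU well inside the desk-scale budget.
"""

from __future__ import annotations

import numpy as np

from mesocell.dpd_core.particles import ParticleSystem, ThermoState, FLUID
from mesocell.dpd_core.interactions import default_interactions
from mesocell.membrane.mesh import make_sphere_mesh
from mesocell.cell_assembly.config import AssemblyConfig
from mesocell.cell_assembly.generate import (
    assemble_cell,
    seed_filaments,
    polymerize,
    form_crosslinks,
)
from mesocell.geometry_flow import DeviceGeometry

FIXTURE_NAMES = (
    "fluid-box",
    "membrane-only",
    "mini-cell",
    "mini-device",
    "network-box",
)


def _reduced_assembly(seed: int) -> AssemblyConfig:
    return AssemblyConfig(
        polymerize_steps=1_000,
        cl_max_steps=10_000,
        link_max_steps=10_000,
        convergence_window=4_000,
        check_every=50,
        seed=seed,
    )


def make_fixture(name: str, seed: int = 0):
    """Deterministic reduced-scale object for tests.

    fluid-box     -> (ParticleSystem, InteractionTable, ThermoState):
                     periodic 5x5x5 box, number density 3, a=10, gamma=30.
    membrane-only -> (TriMesh, positions): D = 6 um sphere, ~400 vertices.
    mini-cell     -> CellBundle: D = 6 um, NC = 0.29, reduced assembly.
    mini-device   -> DeviceGeometry: one constriction period, shrunk.
    network-box   -> (AssemblyState, TopologyStats): cross-linked periodic
                     box network at the default densities (6 um box).
    """
    if name == "fluid-box":
        rng = np.random.default_rng(seed)
        box = np.array([5.0, 5.0, 5.0])
        n = int(3.0 * box.prod())
        system = ParticleSystem(
            positions=rng.uniform(0.0, box, (n, 3)),
            velocities=np.zeros((n, 3)),
            types=np.full(n, FLUID),
            box=box,
            periodic=np.array([True, True, True]),
        )
        return system, default_interactions(), ThermoState(seed=seed)
    if name == "membrane-only":
        return make_sphere_mesh(400, 6.0)
    if name == "mini-cell":
        return assemble_cell(
            diameter=6.0,
            nc_ratio=0.29,
            n_vertices=400,
            config=_reduced_assembly(seed),
            seed=seed,
        )
    if name == "mini-device":
        return DeviceGeometry(
            gap=6.0,
            side=8.0,
            depth=8.0,
            row_spacing=24.0,
            n_rows=1,
            first_row_y=12.0,
            wall_pad=1.5,
        )
    if name == "network-box":
        cfg = _reduced_assembly(seed)
        rng = np.random.default_rng(seed)
        state = seed_filaments(np.array([6.0, 6.0, 6.0]), cfg, rng)
        polymerize(state, rng=rng)
        state, stats = form_crosslinks(state, rng=rng)
        return state, stats
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
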