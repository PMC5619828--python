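"""Virtual experiments: micropipette aspiration and obstacle-array transit.

Aspiration applies a suction ramp (experimental protocol: 0 -> 117.72 Pa at
3.27 Pa/s) to the cell at a pipette mouth and records the normalized
aspiration length L_n = (L_p - L_p0) / R_p, where L_p is the deepest
penetration of any cell-membrane vertex past the mouth plane and L_p0 the
baseline at tiny pressure.  The wall-clock of the physical ramp is far
beyond particle-resolved reach, so the ramp is applied over a configurable
number of steps (quasi-static protocol); pressures are reported in Pa.

Transit drives a cell through rows of triangular constrictions with a
uniform body force equivalent to the device pressure gradient; transit
velocity is traveled distance over elapsed time.

Aspiration runs solvent-free (membrane viscosity and the cytoskeleton
thermostat provide dissipation); transit runs with explicit DPD fluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from mesocell.dpd_core.particles import (
    ParticleSystem,
    ThermoState,
    FLUID,
    WALL,
)
from mesocell.dpd_core.interactions import default_interactions
from mesocell.dpd_core.integrator import Simulation
from mesocell.membrane.forces import membrane_callback
from mesocell.cytoskeleton.forces import network_callback
from mesocell.cell_assembly.generate import CellBundle
from mesocell.geometry_flow import (
    PipetteGeometry,
    DeviceGeometry,
    build_walls,
    drive_flow,
)
from mesocell.units import UnitSystem, DEFAULT_UNITS


class ProtocolError(RuntimeError):
    pass


@dataclass
class AspirationProtocol:
    """Pressure ramp of the aspiration experiment (pressures in Pa)."""

    rate_pa_s: float = 3.27
    max_pressure_pa: float = 117.72
    baseline_pa: float = 2.0          # "tiny pressure" defining L_p0
    hold_pressure_pa: float | None = None  # constant-pressure (creep) mode
    ramp_steps: int = 20_000
    equilibration_steps: int = 5_000
    sample_every: int = 200

    def __post_init__(self) -> None:
        if self.rate_pa_s <= 0:
            raise ValueError("pressure rate must be positive")
        if self.max_pressure_pa < self.baseline_pa:
            raise ValueError("max pressure must be >= baseline")

    def pressure_at(self, frac: float) -> float:
        """Suction pressure at ramp fraction in [0, 1]."""
        if self.hold_pressure_pa is not None:
            return self.hold_pressure_pa
        return self.baseline_pa + frac * (self.max_pressure_pa - self.baseline_pa)


@dataclass
class ExperimentRecord:
    """Time series of measured observables plus run metadata."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data.get("t_sim")
        if t is not None and len(t) > 1 and not np.all(np.diff(t) >= 0):
            raise ValueError("time stamps must be monotone")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "ExperimentRecord":
        return cls(data=pd.read_csv(path), meta=meta)


def _cell_system(
    bundle: CellBundle, box: np.ndarray, periodic, center: np.ndarray
) -> tuple[ParticleSystem, CellBundle]:
    moved = bundle.translated(np.asarray(center) - bundle.centroid)
    system = ParticleSystem(
        positions=moved.positions.copy(),
        velocities=np.zeros_like(moved.positions),
        types=moved.types.copy(),
        box=np.asarray(box, float),
        periodic=np.asarray(periodic, bool),
    )
    return system, moved


def _bundle_callbacks(bundle: CellBundle):
    cbs = [membrane_callback(bundle.cell_mesh)]
    if bundle.nucleus_mesh is not None:
        cbs.append(membrane_callback(bundle.nucleus_mesh))
    cbs.append(network_callback(bundle.network))
    return cbs


# ---------------------------------------------------------------------------
# micropipette aspiration
# ---------------------------------------------------------------------------

def run_aspiration(
    bundle: CellBundle,
    pipette: PipetteGeometry | None = None,
    protocol: AspirationProtocol | None = None,
    thermo: ThermoState | None = None,
    seed: int = 0,
    units: UnitSystem = DEFAULT_UNITS,
    with_wall_particles: bool = True,
) -> ExperimentRecord:
    """Pressure-ramp aspiration of one cell; returns the L_n(dP) record.

    The suction is a body force along +x applied to cell particles inside
    the capture region (within the bore radius of the pipette axis, past
    one diameter upstream of the mouth); its total equals dP * pi * R_p^2.
    """
    pipette = pipette or PipetteGeometry(radius=max(1.5, bundle.diameter / 5.0))
    protocol = protocol or AspirationProtocol()
    thermo = thermo or ThermoState(seed=seed)
    d = bundle.diameter
    rp = pipette.radius

    box = np.array([2.0 * d + pipette.wall_length + 4.0, d + 6.0, d + 6.0])
    mouth_x = d + 2.0
    axis_yz = (box[1] / 2.0, box[2] / 2.0)
    geom = PipetteGeometry(
        radius=rp,
        mouth=mouth_x,
        wall_length=pipette.wall_length,
        rounding=pipette.rounding,
        center=axis_yz,
    )
    system, cell = _cell_system(
        bundle,
        box,
        [False, False, False],
        np.array([mouth_x - d / 2.0, axis_yz[0], axis_yz[1]]),
    )
    if with_wall_particles:
        wall_pos = build_walls(geom, box, cutoff=1.0, rng=np.random.default_rng(seed + 1))
        system = ParticleSystem(
            positions=np.vstack([system.positions, wall_pos]),
            velocities=np.zeros((system.n + wall_pos.shape[0], 3)),
            types=np.concatenate([system.types, np.full(wall_pos.shape[0], WALL)]),
            box=box,
            periodic=system.periodic,
        )
    sim = Simulation(
        system,
        default_interactions(thermo.kbt),
        thermo,
        bonded_callbacks=_bundle_callbacks(cell),
        geometry=geom,
        wrap_positions=False,
    )

    n_cell = cell.n
    mem_sl = cell.cell_mesh.vertex_slice
    suction_area = np.pi * rp**2

    def suction_callback_factory():
        state = {"dp_pa": 0.0}

        def cb(positions, velocities, forces, rng, dt):
            dp_sim = units.pressure_to_sim(state["dp_pa"])
            if dp_sim == 0.0:
                return
            p = positions[:n_cell]
            rho = np.hypot(p[:, 1] - axis_yz[0], p[:, 2] - axis_yz[1])
            eligible = (rho < rp) & (p[:, 0] > mouth_x - d)
            n_el = int(eligible.sum())
            if n_el:
                forces[:n_cell][eligible, 0] += dp_sim * suction_area / n_el

        return state, cb

    suction_state, suction_cb = suction_callback_factory()
    sim.bonded_callbacks.append(suction_cb)

    def l_p() -> float:
        return float(system.positions[mem_sl][:, 0].max() - mouth_x)

    rows = []
    # baseline at tiny pressure
    suction_state["dp_pa"] = protocol.baseline_pa
    sim.step(protocol.equilibration_steps)
    l_p0 = l_p()

    total = protocol.ramp_steps
    done = 0
    aborted = False
    while done < total:
        chunk = min(protocol.sample_every, total - done)
        dp = protocol.pressure_at((done + chunk) / total)
        suction_state["dp_pa"] = dp
        sim.step(chunk)
        done += chunk
        ln = max(0.0, (l_p() - l_p0) / rp)
        rows.append(
            {
                "step": done,
                "t_sim": done * thermo.dt,
                "t_s": done * thermo.dt * units.time_si,
                "dp_pa": dp,
                "l_p": l_p(),
                "l_n": ln,
                "temperature": system.kinetic_temperature(),
            }
        )
        if l_p() > geom.wall_length:
            aborted = True
            break

    return ExperimentRecord(
        data=pd.DataFrame(rows),
        meta={
            "experiment": "aspiration",
            "pipette_radius": rp,
            "l_p0": l_p0,
            "seed": seed,
            "cell_seed": bundle.seed,
            "diameter": bundle.diameter,
            "nc_ratio": bundle.nc_ratio,
            "aborted_fully_aspirated": aborted,
        },
    )


# ---------------------------------------------------------------------------
# microfluidic transit
# ---------------------------------------------------------------------------

def run_transit(
    bundle: CellBundle,
    device: DeviceGeometry,
    pressure_gradient_pa_um: float = 0.67,
    thermo: ThermoState | None = None,
    seed: int = 0,
    steps: int = 40_000,
    sample_every: int = 200,
    fluid_density: float = 3.0,
    equilibration_steps: int = 2_000,
    stuck_window: int = 20,
    stuck_tol: float = 0.05,
    units: UnitSystem = DEFAULT_UNITS,
) -> ExperimentRecord:
    """Drive one cell through the obstacle array; record the centroid track.

    Outcome is "transit" with velocity = traveled distance / elapsed time,
    or "stuck" when the centroid stalls for ``stuck_window`` samples.
    """
    thermo = thermo or ThermoState(seed=seed)
    box = device.box
    rng = np.random.default_rng(seed)

    start = np.array([box[0] / 2.0, max(bundle.diameter / 2.0 + 1.0, 2.0), box[2] / 2.0])
    system, cell = _cell_system(bundle, box, device.periodic, start)
    n_cell = cell.n

    # fluid fill: random at target density, outside walls and cell
    n_fluid = int(fluid_density * box.prod())
    pts = rng.uniform(0.0, box, size=(int(n_fluid * 1.6), 3))
    ok = device.sdf(pts) < -0.15
    pts = pts[ok]
    inside_cell = cell.cell_mesh.contains(
        system.positions[cell.cell_mesh.vertex_slice], pts
    )
    pts = pts[~inside_cell][: n_fluid]
    wall_pos = build_walls(device, box, fluid_density, cutoff=1.0, rng=rng)

    system = ParticleSystem(
        positions=np.vstack([system.positions, pts, wall_pos]),
        velocities=np.zeros((n_cell + pts.shape[0] + wall_pos.shape[0], 3)),
        types=np.concatenate(
            [
                system.types,
                np.full(pts.shape[0], FLUID),
                np.full(wall_pos.shape[0], WALL),
            ]
        ),
        box=box,
        periodic=device.periodic,
    )
    body = drive_flow(system, pressure_gradient_pa_um, axis=1, density=fluid_density, units=units)
    sim = Simulation(
        system,
        default_interactions(thermo.kbt),
        thermo,
        bonded_callbacks=_bundle_callbacks(cell),
        body_force=body,
        geometry=device,
        wrap_positions=True,
    )

    sim.body_force = None
    sim.step(equilibration_steps)
    sim.body_force = body

    def centroid_y() -> float:
        return float(np.mean(system.positions[:n_cell, 1]))

    rows = []
    y_unwrapped = centroid_y()
    y_prev = y_unwrapped
    t0 = 0.0
    outcome = "transit"
    done = 0
    while done < steps:
        sim.step(sample_every)
        done += sample_every
        y_now = centroid_y()
        dy = y_now - y_prev
        dy -= box[1] * np.round(dy / box[1])
        y_unwrapped += dy
        y_prev = y_now
        rows.append(
            {
                "step": done,
                "t_sim": done * thermo.dt,
                "y": y_unwrapped,
                "temperature": system.kinetic_temperature(),
            }
        )
        if len(rows) > stuck_window:
            travel = rows[-1]["y"] - rows[-1 - stuck_window]["y"]
            if travel < stuck_tol:
                outcome = "stuck"
                break

    df = pd.DataFrame(rows)
    if len(df) >= 2 and outcome == "transit":
        dist = df["y"].iloc[-1] - df["y"].iloc[0]
        t_el = df["t_sim"].iloc[-1] - df["t_sim"].iloc[0]
        v_sim = dist / t_el
    else:
        v_sim = 0.0
    return ExperimentRecord(
        data=df,
        meta={
            "experiment": "transit",
            "outcome": outcome,
            "velocity_sim": v_sim,
            "velocity_mm_s": units.velocity_to_si(v_sim) * 1e3,
            "seed": seed,
            "cell_seed": bundle.seed,
            "gap": device.gap,
            "pressure_gradient_pa_um": pressure_gradient_pa_um,
        },
    )


def measure_tracer_speed(
    device: DeviceGeometry,
    pressure_gradient_pa_um: float = 0.67,
    thermo: ThermoState | None = None,
    seed: int = 0,
    steps: int = 20_000,
    fluid_density: float = 3.0,
    units: UnitSystem = DEFAULT_UNITS,
) -> float:
    """Mean streamwise fluid speed (mm/s) in the cell-free device
    (bead-calibration closure)."""
    thermo = thermo or ThermoState(seed=seed)
    box = device.box
    rng = np.random.default_rng(seed)
    n_fluid = int(fluid_density * box.prod())
    pts = rng.uniform(0.0, box, size=(int(n_fluid * 1.6), 3))
    pts = pts[device.sdf(pts) < -0.15][:n_fluid]
    wall_pos = build_walls(device, box, fluid_density, cutoff=1.0, rng=rng)
    system = ParticleSystem(
        positions=np.vstack([pts, wall_pos]),
        velocities=np.zeros((pts.shape[0] + wall_pos.shape[0], 3)),
        types=np.concatenate(
            [np.full(pts.shape[0], FLUID), np.full(wall_pos.shape[0], WALL)]
        ),
        box=box,
        periodic=device.periodic,
    )
    body = drive_flow(system, pressure_gradient_pa_um, axis=1, density=fluid_density, units=units)
    sim = Simulation(
        system, default_interactions(thermo.kbt), thermo,
        body_force=body, geometry=device,
    )
    sim.step(steps // 2)
    vs = []
    for _ in range(10):
        sim.step(steps // 20)
        vs.append(float(system.velocities[system.types == FLUID, 1].mean()))
    return units.velocity_to_si(float(np.mean(vs))) * 1e3


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def run_ensemble(
    cells: Sequence[CellBundle],
    run_fn: Callable[[CellBundle, int], ExperimentRecord],
    rotations: int = 4,
    rotation_axis: int = 2,
) -> tuple[list[ExperimentRecord], pd.DataFrame]:
    """Run every cell at ``rotations`` rigid orientations; aggregate.

    Aspiration records are summarized as mean +/- SD of L_n per pressure
    level; transit records as mean +/- SD of transit velocity.
    """
    if len(cells) == 0:
        raise ValueError("empty ensemble")
    records: list[ExperimentRecord] = []
    for ci, cell in enumerate(cells):
        for k in range(rotations):
            rotated = cell.rotated(2.0 * np.pi * k / rotations, axis=rotation_axis)
            rec = run_fn(rotated, ci * rotations + k)
            rec.meta.update({"cell_id": ci, "rotation": k})
            records.append(rec)

    kinds = {r.meta.get("experiment") for r in records}
    if len(kinds) != 1:
        raise ValueError(f"mixed experiment types in ensemble: {kinds}")
    kind = kinds.pop()
    if kind == "aspiration":
        frames = []
        for r in records:
            df = r.data[["dp_pa", "l_n"]].copy()
            df["cell_id"] = r.meta["cell_id"]
            df["rotation"] = r.meta["rotation"]
            frames.append(df)
        stacked = pd.concat(frames)
        summary = (
            stacked.groupby("dp_pa")["l_n"].agg(["mean", "std", "count"]).reset_index()
        )
        summary["std"] = summary["std"].fillna(0.0)
    else:
        vals = pd.DataFrame(
            {
                "cell_id": [r.meta["cell_id"] for r in records],
                "rotation": [r.meta["rotation"] for r in records],
                "velocity_mm_s": [r.meta["velocity_mm_s"] for r in records],
                "outcome": [r.meta["outcome"] for r in records],
            }
        )
        summary = vals
    return records, summary
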