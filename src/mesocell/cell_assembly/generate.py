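"""Network generation pipeline.

Phases (run as thermostatted DPD dynamics with binding/unbinding event
sweeps every ``check_every`` steps):

1. ``seed_filaments``  - fill a periodic box with straight 4 um chains.
2. ``polymerize``      - end depolymerization/repolymerization; the removal
   probability is controlled so the net added-minus-removed count stays
   near zero and total filament length is approximately conserved.
3. ``form_crosslinks`` - auxiliary CL particles bind filaments within
   0.25 um (one CL per filament particle, a CL joins two distinct
   filaments), unbind by the force-dependent law, run until the free-CL
   count converges; then single-bound CLs are pruned and each remaining CL
   is merged into one direct filament-filament bond.
4. ``carve_network`` / ``link_membranes`` - cut the network to the cell
   volume, generate chromatin inside the nucleus, stochastically link
   filament particles to membrane vertices, add torsion quadruples.

Auxiliary CL particles are coupled to the rest of the system through the
thermostat only (no conservative repulsion); with the full a = 100
filament repulsion they could never reach the 0.25 um binding radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from mesocell.dpd_core.particles import (
    ParticleSystem,
    ThermoState,
    FLUID,
    FILAMENT,
    MEMBRANE,
    NUCLEUS,
)
from mesocell.dpd_core.interactions import InteractionTable, default_interactions
from mesocell.dpd_core.integrator import Simulation
from mesocell.cytoskeleton.network import (
    FilamentNetwork,
    KAPPA_FIL,
    KAPPA_BEND,
    KAPPA_CL,
    KAPPA_CL_FIL,
    K_TOR,
)
from mesocell.cytoskeleton.bell import bell_unbind_probability
from mesocell.cytoskeleton.forces import network_callback
from mesocell.membrane.mesh import (
    TriMesh,
    make_sphere_mesh,
    nucleus_diameter_from_nc,
    GeometryError,
)
from mesocell.units import UnitSystem, DEFAULT_UNITS
from mesocell.cell_assembly.config import AssemblyConfig, TopologyStats


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# assembly state
# ---------------------------------------------------------------------------

@dataclass
class AssemblyState:
    """Mutable network-under-construction in a periodic box."""

    positions: np.ndarray
    box: np.ndarray
    config: AssemblyConfig
    chains: list = field(default_factory=list)       # list[list[int]]
    free_monomers: list = field(default_factory=list)
    cl_indices: list = field(default_factory=list)
    cl_bonds: dict = field(default_factory=dict)     # cl index -> [fil particles]
    cl_bond_r0: dict = field(default_factory=dict)   # (cl, fil) -> rest length
    velocities: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def chain_of(self) -> np.ndarray:
        out = np.full(self.n, -1, dtype=np.int64)
        for ci, ch in enumerate(self.chains):
            out[np.asarray(ch, dtype=np.int64)] = ci
        return out

    def types(self) -> np.ndarray:
        t = np.full(self.n, FILAMENT, dtype=np.int64)
        if self.cl_indices:
            t[np.asarray(self.cl_indices, dtype=np.int64)] = FLUID
        return t

    def wrapped(self) -> np.ndarray:
        p = self.positions % self.box
        return np.minimum(p, self.box * (1.0 - 1e-12))

    def network(self) -> FilamentNetwork:
        """Bonded topology of the current state (chains + CL-particle bonds)."""
        bonds, bond_k, bond_r0 = [], [], []
        angles, angle_k, angle_t0 = [], [], []
        r0 = self.config.fil_spacing
        for ch in self.chains:
            for a, b in zip(ch[:-1], ch[1:]):
                bonds.append((a, b))
                bond_k.append(KAPPA_FIL)
                bond_r0.append(r0)
            for a, b, c in zip(ch[:-2], ch[1:-1], ch[2:]):
                angles.append((a, b, c))
                angle_k.append(KAPPA_BEND)
                angle_t0.append(np.pi)
        chain_neighbor = _chain_neighbors(self.chains, self.n)
        for cl, fils in self.cl_bonds.items():
            for f in fils:
                bonds.append((cl, f))
                bond_k.append(KAPPA_CL)
                bond_r0.append(self.cl_bond_r0.get((cl, f), self.config.cl_bell.r0))
                nb = chain_neighbor[f]
                if nb >= 0:
                    angles.append((cl, f, nb))
                    angle_k.append(KAPPA_CL_FIL)
                    angle_t0.append(np.pi / 2.0)
        return FilamentNetwork(
            chains=[np.asarray(c, dtype=np.int64) for c in self.chains],
            bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
            bond_k=np.asarray(bond_k, dtype=float),
            bond_r0=np.asarray(bond_r0, dtype=float),
            angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
            angle_k=np.asarray(angle_k, dtype=float),
            angle_theta0=np.asarray(angle_t0, dtype=float),
        )


def _chain_neighbors(chains, n: int) -> np.ndarray:
    """For each chain particle, one bonded neighbor (next, else previous)."""
    nb = np.full(n, -1, dtype=np.int64)
    for ch in chains:
        for k, p in enumerate(ch):
            nb[p] = ch[k + 1] if k + 1 < len(ch) else ch[k - 1]
    return nb


def assembly_interactions(kbt: float = 1.0) -> InteractionTable:
    """Filament repulsion + thermostat; CL particles thermostat-only."""
    t = InteractionTable(kbt=kbt)
    t.set_pair(1, 1, 0.0, 30.0)                      # CL-CL
    t.set_pair(1, 2, 0.0, 45.0)                      # CL-filament
    t.set_pair(2, 2, 100.0, 65.0, rc_rep=0.5, rc_th=1.0)
    t.validate()
    return t


def _make_sim(state: AssemblyState, thermo: ThermoState, table=None) -> Simulation:
    system = ParticleSystem(
        positions=state.positions,
        velocities=state.velocities,
        types=state.types(),
        box=state.box,
        periodic=np.array([True, True, True]),
    )
    net = state.network()
    sim = Simulation(
        system,
        table if table is not None else assembly_interactions(thermo.kbt),
        thermo,
        bonded_callbacks=[network_callback(net)],
        wrap_positions=False,
    )
    sim._assembly_net = net  # refreshed in place after topology events
    return sim


def _soft_launch(state: AssemblyState, thermo: ThermoState, table=None) -> None:
    """Resolve seeding overlaps: short run at reduced dt with capped speeds."""
    gentle = ThermoState(kbt=thermo.kbt, dt=thermo.dt / 10.0, seed=thermo.seed + 9)
    sim = _make_sim(state, gentle, table)
    state.positions = sim.system.positions
    state.velocities = sim.system.velocities
    vcap = 3.0 * np.sqrt(thermo.kbt)
    for _ in range(20):
        sim.step(50)
        np.clip(state.velocities, -vcap, vcap, out=state.velocities)


def _refresh_topology(sim: Simulation, state: AssemblyState) -> None:
    new = state.network()
    old = sim._assembly_net
    for name in (
        "chains", "bonds", "bond_k", "bond_r0",
        "angles", "angle_k", "angle_theta0",
    ):
        setattr(old, name, getattr(new, name))
    sim._forces = None


# ---------------------------------------------------------------------------
# phase 1: seeding
# ---------------------------------------------------------------------------

def seed_filaments(
    box: np.ndarray, config: AssemblyConfig, rng: np.random.Generator
) -> AssemblyState:
    """Fill a periodic box with straight random chains at the target density."""
    box = np.asarray(box, dtype=float)
    if np.any(box < config.filament_length * 0.5):
        raise ConfigurationError("box too small for one filament")
    ppf = config.particles_per_filament
    n_target = config.fil_density * float(box.prod())
    n_fil = max(1, int(round(n_target / ppf)))
    positions = np.empty((n_fil * ppf, 3))
    chains = []
    k = 0
    for _ in range(n_fil):
        start = rng.uniform(0.0, box)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        idx = list(range(k, k + ppf))
        positions[k : k + ppf] = start + np.outer(
            np.arange(ppf) * config.fil_spacing, u
        )
        chains.append(idx)
        k += ppf
    return AssemblyState(positions=positions, box=box, config=config, chains=chains)


# ---------------------------------------------------------------------------
# phase 2: polymerization / depolymerization
# ---------------------------------------------------------------------------

def polymerize(
    state: AssemblyState,
    steps: int | None = None,
    rng: np.random.Generator | None = None,
    thermo: ThermoState | None = None,
) -> AssemblyState:
    """End-exchange dynamics keeping total filament length ~constant."""
    cfg = state.config
    steps = cfg.polymerize_steps if steps is None else steps
    if steps == 0:
        return state
    rng = rng or np.random.default_rng(cfg.seed + 1)
    thermo = thermo or ThermoState(seed=cfg.seed + 1)
    _soft_launch(state, thermo)
    sim = _make_sim(state, thermo)
    state.positions = sim.system.positions
    state.velocities = sim.system.velocities

    p_remove = 0.05
    added_tot = removed_tot = 0
    done = 0
    while done < steps:
        chunk = min(cfg.check_every, steps - done)
        sim.step(chunk)
        done += chunk
        changed = False
        added = removed = 0
        # depolymerize from the minus end
        for ch in state.chains:
            if len(ch) > cfg.min_chain_len and rng.random() < p_remove:
                state.free_monomers.append(ch.pop(0))
                removed += 1
                changed = True
        # repolymerize onto the plus end
        if state.free_monomers:
            wp = state.wrapped()
            ends = np.array([ch[-1] for ch in state.chains])
            tree = cKDTree(wp[ends], boxsize=state.box)
            used_ends: set[int] = set()
            still_free = []
            for m in state.free_monomers:
                d, j = tree.query(wp[m], k=1)
                if d < cfg.growth_radius and j not in used_ends:
                    ch = state.chains[int(j)]  # ends[j] ends chain j
                    end = ch[-1]
                    # place at rest distance along the approach direction to
                    # avoid shock-loading the stiff new bond
                    dr = wp[m] - wp[end]
                    dr -= state.box * np.round(dr / state.box)
                    nd = np.linalg.norm(dr)
                    u = dr / nd if nd > 1e-9 else rng.normal(size=3)
                    u = u / np.linalg.norm(u)
                    state.positions[m] = state.positions[end] + cfg.fil_spacing * u
                    state.velocities[m] = state.velocities[end]
                    ch.append(m)
                    used_ends.add(int(j))
                    added += 1
                    changed = True
                else:
                    still_free.append(m)
            state.free_monomers = still_free
        # removal probability proportional to the running added-removed excess
        added_tot += added
        removed_tot += removed
        p_remove = float(
            np.clip(0.05 + 0.2 * (added_tot - removed_tot) / len(state.chains), 0.0, 0.5)
        )
        if changed:
            _refresh_topology(sim, state)
    return state


# ---------------------------------------------------------------------------
# phase 3: cross-link formation, pruning and merging
# ---------------------------------------------------------------------------

def form_crosslinks(
    state: AssemblyState,
    rng: np.random.Generator | None = None,
    thermo: ThermoState | None = None,
    max_steps: int | None = None,
    units: UnitSystem = DEFAULT_UNITS,
) -> tuple[AssemblyState, TopologyStats]:
    """Bind/unbind auxiliary CL particles until the free-CL count converges,
    then prune single-bound CLs and merge the rest into direct bonds."""
    cfg = state.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    thermo = thermo or ThermoState(seed=cfg.seed + 2)
    max_steps = cfg.cl_max_steps if max_steps is None else max_steps

    n_cl = int(round(cfg.cl_density * float(state.box.prod())))
    if n_cl > 0:
        cl_pos = rng.uniform(0.0, state.box, size=(n_cl, 3))
        base = state.n
        state.positions = np.vstack([state.positions, cl_pos])
        state.velocities = np.vstack([state.velocities, np.zeros((n_cl, 3))])
        state.cl_indices = list(range(base, base + n_cl))

    free_trace: list[int] = []
    if n_cl > 0:
        sim = _make_sim(state, thermo)
        state.positions = sim.system.positions
        state.velocities = sim.system.velocities
        dt_window = cfg.check_every * thermo.dt * units.time_si
        chain_of = state.chain_of()
        occupied: set[int] = set()

        done = 0
        window_free: list[int] = []
        prev_free = None
        while done < max_steps:
            sim.step(cfg.check_every)
            done += cfg.check_every
            changed = False
            wp = state.wrapped()
            # unbinding (Bell)
            for cl in list(state.cl_bonds):
                for f in list(state.cl_bonds[cl]):
                    dr = wp[cl] - wp[f]
                    dr -= state.box * np.round(dr / state.box)
                    r = float(np.linalg.norm(dr))
                    r0b = state.cl_bond_r0.get((cl, f), cfg.cl_bell.r0)
                    force = abs(2.0 * KAPPA_CL * (r - r0b))
                    p = bell_unbind_probability(
                        force, r, cfg.cl_bell, thermo.kbt, dt_phys=dt_window
                    )
                    if rng.random() < p:
                        state.cl_bonds[cl].remove(f)
                        state.cl_bond_r0.pop((cl, f), None)
                        occupied.discard(f)
                        changed = True
                if not state.cl_bonds[cl]:
                    del state.cl_bonds[cl]
            # anneal fresh rest lengths toward the nominal binding radius
            for key, r0b in list(state.cl_bond_r0.items()):
                if abs(r0b - cfg.cl_bell.r0) > 1e-9:
                    state.cl_bond_r0[key] = r0b + np.clip(
                        cfg.cl_bell.r0 - r0b, -0.01, 0.01
                    )
                    changed = True
            # binding
            fil_mask = np.ones(state.n, dtype=bool)
            fil_mask[np.asarray(state.cl_indices, dtype=np.int64)] = False
            fil_idx = np.flatnonzero(fil_mask)
            tree = cKDTree(wp[fil_idx], boxsize=state.box)
            for cl in state.cl_indices:
                bound = state.cl_bonds.get(cl, [])
                if len(bound) >= 2:
                    continue
                bound_chains = {int(chain_of[f]) for f in bound}
                cand = tree.query_ball_point(wp[cl], cfg.cl_bell.r0)
                best, best_d = -1, np.inf
                for c in cand:
                    f = int(fil_idx[c])
                    if f in occupied or int(chain_of[f]) in bound_chains:
                        continue
                    dr = wp[cl] - wp[f]
                    dr -= state.box * np.round(dr / state.box)
                    d = float(np.linalg.norm(dr))
                    if d < best_d:
                        best, best_d = f, d
                if best >= 0:
                    first_bond = not bound
                    state.cl_bonds.setdefault(cl, []).append(best)
                    occupied.add(best)
                    if first_bond:
                        # free CL: snap to rest distance, inherit velocity
                        dr = wp[cl] - wp[best]
                        dr -= state.box * np.round(dr / state.box)
                        nd = float(np.linalg.norm(dr))
                        u = dr / nd if nd > 1e-9 else rng.normal(size=3)
                        u = u / np.linalg.norm(u)
                        state.positions[cl] = (
                            state.positions[best] + cfg.cl_bell.r0 * u
                        )
                        state.velocities[cl] = state.velocities[best]
                        state.cl_bond_r0[(cl, best)] = cfg.cl_bell.r0
                    else:
                        # tethered CL: start stress-free, anneal to nominal
                        state.cl_bond_r0[(cl, best)] = max(best_d, 0.05)
                    changed = True
            if changed:
                _refresh_topology(sim, state)
            # convergence on the free-CL count
            n_free = sum(
                1 for cl in state.cl_indices if not state.cl_bonds.get(cl)
            )
            window_free.append(n_free)
            if done % cfg.convergence_window < cfg.check_every:
                cur = float(np.mean(window_free))
                free_trace.append(int(round(cur)))
                window_free = []
                if prev_free is not None and abs(cur - prev_free) <= max(
                    1.0, cfg.convergence_rtol * max(prev_free, 1.0)
                ):
                    break
                prev_free = cur

    state, stats = _prune_and_merge(state)
    stats.free_cl_trace = free_trace
    return state, stats


def _prune_and_merge(state: AssemblyState) -> tuple[AssemblyState, TopologyStats]:
    """Drop single-bound CLs, replace double-bound CLs by direct bonds,
    remove all CL particles from the state."""
    chain_of = state.chain_of()
    merged: list[tuple[int, int]] = []
    for cl, fils in state.cl_bonds.items():
        if len(fils) == 2 and chain_of[fils[0]] != chain_of[fils[1]]:
            merged.append((int(fils[0]), int(fils[1])))
    # compact: remove CL particles
    keep = np.ones(state.n, dtype=bool)
    if state.cl_indices:
        keep[np.asarray(state.cl_indices, dtype=np.int64)] = False
    new_index = np.cumsum(keep) - 1
    state.positions = state.positions[keep]
    state.velocities = state.velocities[keep]
    state.chains = [[int(new_index[p]) for p in ch] for ch in state.chains]
    merged_new = np.array(
        [(int(new_index[a]), int(new_index[b])) for a, b in merged], dtype=np.int64
    ).reshape(-1, 2)
    state.cl_indices = []
    state.cl_bonds = {}
    state.cl_bond_r0 = {}
    state.free_monomers = [int(new_index[m]) for m in state.free_monomers if keep[m]]

    counts = np.zeros(len(state.chains), dtype=np.int64)
    chain_of2 = state.chain_of()
    for a, b in merged_new:
        counts[chain_of2[a]] += 1
        counts[chain_of2[b]] += 1
    stats = TopologyStats(
        mean_cls_per_filament=float(counts.mean()) if counts.size else 0.0,
        sd_cls_per_filament=float(counts.std()) if counts.size else 0.0,
        n_filaments=len(state.chains),
        n_cl_bonds=int(merged_new.shape[0]),
    )
    state.merged_pairs = merged_new  # type: ignore[attr-defined]
    return state, stats


def build_network(
    chains,
    merged_pairs: np.ndarray,
    positions: np.ndarray,
    config: AssemblyConfig,
) -> FilamentNetwork:
    """Final bonded topology: chain bonds/angles, merged CL bonds with
    anchor angles (theta_0 = pi/2).  Merged-bond rest lengths are the
    constructed separations (stress-free by construction)."""
    bonds, bond_k, bond_r0 = [], [], []
    angles, angle_k, angle_t0 = [], [], []
    for ch in chains:
        for a, b in zip(ch[:-1], ch[1:]):
            bonds.append((a, b))
            bond_k.append(KAPPA_FIL)
            bond_r0.append(config.fil_spacing)
        for a, b, c in zip(ch[:-2], ch[1:-1], ch[2:]):
            angles.append((a, b, c))
            angle_k.append(KAPPA_BEND)
            angle_t0.append(np.pi)
    n = positions.shape[0]
    neighbor = _chain_neighbors(chains, n)
    cl_rows = []
    for a, b in np.asarray(merged_pairs, dtype=np.int64).reshape(-1, 2):
        r = float(np.linalg.norm(positions[a] - positions[b]))
        cl_rows.append(len(bonds))
        bonds.append((int(a), int(b)))
        bond_k.append(KAPPA_CL)
        bond_r0.append(r)
        for anchor, other in ((a, b), (b, a)):
            nb = neighbor[anchor]
            if nb >= 0:
                angles.append((int(nb), int(anchor), int(other)))
                angle_k.append(KAPPA_CL_FIL)
                angle_t0.append(np.pi / 2.0)
    chain_of = np.full(n, -1, dtype=np.int64)
    for ci, ch in enumerate(chains):
        chain_of[np.asarray(ch, dtype=np.int64)] = ci
    pairs = np.asarray(merged_pairs, dtype=np.int64).reshape(-1, 2)
    net = FilamentNetwork(
        chains=[np.asarray(c, dtype=np.int64) for c in chains],
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_k=np.asarray(bond_k, dtype=float),
        bond_r0=np.asarray(bond_r0, dtype=float),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_k=np.asarray(angle_k, dtype=float),
        angle_theta0=np.asarray(angle_t0, dtype=float),
        cl_pairs=chain_of[pairs] if pairs.size else pairs,
        cl_bond_particles=pairs,
    )
    return net


def add_torsions(network: FilamentNetwork, positions: np.ndarray) -> None:
    """Four-body torsion across each merged CL bond; equilibrium angle is the
    constructed dihedral.  Quadruple: (neighbor on A, anchor A, anchor B,
    neighbor on B).  Degenerate (collinear) quadruples are skipped."""
    from mesocell.membrane.forces import dihedral_angles

    n = positions.shape[0]
    neighbor = _chain_neighbors(network.chains, n)
    quads = []
    for a, b in network.cl_bond_particles:
        na, nb = neighbor[a], neighbor[b]
        if na < 0 or nb < 0:
            continue
        q = (int(na), int(a), int(b), int(nb))
        b1 = positions[q[1]] - positions[q[0]]
        b2 = positions[q[2]] - positions[q[1]]
        b3 = positions[q[3]] - positions[q[2]]
        if (
            np.linalg.norm(np.cross(b1, b2)) < 1e-8
            or np.linalg.norm(np.cross(b2, b3)) < 1e-8
        ):
            continue
        quads.append(q)
    if not quads:
        return
    quads_arr = np.asarray(quads, dtype=np.int64)
    phi0 = dihedral_angles(quads_arr, positions)
    network.torsions = quads_arr
    network.torsion_k = np.full(quads_arr.shape[0], K_TOR)
    network.torsion_phi0 = phi0


# ---------------------------------------------------------------------------
# phase 4: carving and membrane linking
# ---------------------------------------------------------------------------

def coherent_chains(state: AssemblyState) -> np.ndarray:
    """Positions with each chain placed contiguously near its wrapped head."""
    pos = state.positions.copy()
    box = state.box
    for ch in state.chains:
        head = pos[ch[0]] % box
        shift = head - pos[ch[0]]
        for p in ch:
            pos[p] = pos[p] + shift
        for k in range(1, len(ch)):
            d = pos[ch[k]] - pos[ch[k - 1]]
            pos[ch[k]] -= box * np.round(d / box)
    return pos


def carve_network(
    state: AssemblyState,
    keep: np.ndarray,
    positions: np.ndarray,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Cut the merged network to a region: chains split into runs of kept
    particles (length >= 2); merged bonds survive when both ends survive.

    Returns (new positions, new chains, new merged pairs)."""
    cfg = state.config
    runs: list[list[int]] = []
    for ch in state.chains:
        cur: list[int] = []
        for p in ch:
            if keep[p]:
                cur.append(p)
            else:
                if len(cur) >= 2:
                    runs.append(cur)
                cur = []
        if len(cur) >= 2:
            runs.append(cur)
    kept_particles = sorted({p for run in runs for p in run})
    new_index = np.full(state.n, -1, dtype=np.int64)
    for ni, p in enumerate(kept_particles):
        new_index[p] = ni
    new_pos = positions[kept_particles]
    new_chains = [[int(new_index[p]) for p in run] for run in runs]
    merged = getattr(state, "merged_pairs", np.zeros((0, 2), np.int64))
    ok = (new_index[merged[:, 0]] >= 0) & (new_index[merged[:, 1]] >= 0) if merged.size else np.zeros(0, bool)
    new_merged = new_index[merged[ok]] if merged.size else merged
    return new_pos, new_chains, new_merged


# ---------------------------------------------------------------------------
# cell bundle
# ---------------------------------------------------------------------------

@dataclass
class CellBundle:
    """A fully assembled cell: membranes, cytoskeleton, chromatin, topology.

    Particle layout: [cell membrane vertices][nucleus vertices][filament and
    chromatin particles].  ``network`` indexes into ``positions``.
    """

    positions: np.ndarray
    types: np.ndarray
    cell_mesh: TriMesh
    nucleus_mesh: TriMesh | None
    network: FilamentNetwork
    stats: TopologyStats
    diameter: float
    nc_ratio: float
    seed: int

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, vec: np.ndarray) -> "CellBundle":
        out = self._clone()
        out.positions = self.positions + np.asarray(vec, float)
        return out

    def rotated(self, angle: float, axis: int = 2) -> "CellBundle":
        """Rigid rotation about the centroid (reference state is invariant)."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        rot[i, i] = c
        rot[j, j] = c
        rot[i, j] = -s
        rot[j, i] = s
        out = self._clone()
        ctr = self.centroid
        out.positions = (self.positions - ctr) @ rot.T + ctr
        return out

    def _clone(self) -> "CellBundle":
        return CellBundle(
            positions=self.positions.copy(),
            types=self.types.copy(),
            cell_mesh=self.cell_mesh,
            nucleus_mesh=self.nucleus_mesh,
            network=self.network,
            stats=self.stats,
            diameter=self.diameter,
            nc_ratio=self.nc_ratio,
            seed=self.seed,
        )


def _box_network(
    side: float, config: AssemblyConfig, seed: int, thermo_kbt: float = 1.0
) -> AssemblyState:
    """Seed + polymerize + cross-link a periodic box network."""
    rng = np.random.default_rng(seed)
    box = np.array([side, side, side])
    state = seed_filaments(box, config, rng)
    thermo = ThermoState(kbt=thermo_kbt, seed=seed)
    polymerize(state, rng=rng, thermo=thermo)
    state, _ = form_crosslinks(state, rng=rng, thermo=ThermoState(kbt=thermo_kbt, seed=seed + 1))
    return state


def nucleus_vertex_count(nucleus_diameter: float, target_edge: float = 0.5) -> int:
    """Vertex count giving ~target mean edge length on the nucleus sphere."""
    area = np.pi * nucleus_diameter**2
    n_faces = area / (np.sqrt(3.0) / 4.0 * target_edge**2)
    return max(12, int(round(n_faces / 2.0 + 2.0)))


def assemble_cell(
    diameter: float = 16.0,
    nc_ratio: float = 0.29,
    n_vertices: int = 3500,
    config: AssemblyConfig | None = None,
    seed: int = 0,
    link: bool = True,
    units: UnitSystem = DEFAULT_UNITS,
) -> CellBundle:
    """Build a complete cell: meshes, carved cytoskeleton, chromatin, links."""
    config = config or AssemblyConfig(seed=seed)
    cell_mesh, cell_pts = make_sphere_mesh(n_vertices, diameter)
    nucleus_mesh = None
    nucleus_pts = np.zeros((0, 3))
    if nc_ratio > 0:
        d_n = nucleus_diameter_from_nc(diameter, nc_ratio)
        nv_n = nucleus_vertex_count(d_n)
        nucleus_mesh, nucleus_pts = make_sphere_mesh(
            nv_n, d_n, lmax=1.2, kb=250.0, ka=5000.0, kv=15000.0
        )
        if not bool(np.all(cell_mesh.contains(cell_pts, nucleus_pts))):
            raise GeometryError("nucleus mesh intersects the cell mesh")

    # cytoskeleton network in a periodic box around the cell
    side = diameter + 2.0
    state = _box_network(side, config, seed)
    pos = coherent_chains(state) - side / 2.0  # cell frame, centered at origin
    inside_cell = cell_mesh.contains(cell_pts, pos)
    if nucleus_mesh is not None:
        inside_nucl = nucleus_mesh.contains(nucleus_pts, pos)
        keep = inside_cell & ~inside_nucl
    else:
        keep = inside_cell
    cy_pos, cy_chains, cy_merged = carve_network(state, keep, pos)

    # chromatin network inside the nucleus
    ch_pos = np.zeros((0, 3))
    ch_chains: list = []
    ch_merged = np.zeros((0, 2), np.int64)
    if nucleus_mesh is not None and config.chromatin_density > 0:
        ch_cfg = AssemblyConfig(
            **{
                **{k: getattr(config, k) for k in (
                    "filament_length", "fil_spacing", "cl_density",
                    "growth_radius", "cl_bell", "cell_link_bell",
                    "nucleus_link_bell", "polymerize_steps", "cl_max_steps",
                    "link_max_steps", "convergence_window", "convergence_rtol",
                    "check_every", "min_chain_len",
                )},
                "fil_density": config.chromatin_density,
                "seed": seed + 101,
            }
        )
        d_n = nucleus_diameter_from_nc(diameter, nc_ratio)
        side_n = d_n + 2.0
        st_n = _box_network(side_n, ch_cfg, seed + 101)
        pos_n = coherent_chains(st_n) - side_n / 2.0
        keep_n = nucleus_mesh.contains(nucleus_pts, pos_n)
        ch_pos, ch_chains, ch_merged = carve_network(st_n, keep_n, pos_n)

    # combine particle blocks
    nv_c = cell_mesh.n_vertices
    nv_n = 0 if nucleus_mesh is None else nucleus_mesh.n_vertices
    off_cy = nv_c + nv_n
    off_ch = off_cy + cy_pos.shape[0]
    positions = np.vstack([cell_pts, nucleus_pts, cy_pos, ch_pos])
    types = np.concatenate(
        [
            np.full(nv_c, MEMBRANE),
            np.full(nv_n, NUCLEUS),
            np.full(cy_pos.shape[0] + ch_pos.shape[0], FILAMENT),
        ]
    ).astype(np.int64)
    cell_mesh.offset = 0
    if nucleus_mesh is not None:
        nucleus_mesh.offset = nv_c
    chains = [[p + off_cy for p in ch] for ch in cy_chains] + [
        [p + off_ch for p in ch] for ch in ch_chains
    ]
    merged = np.vstack(
        [cy_merged + off_cy, ch_merged + off_ch]
    ) if (cy_merged.size or ch_merged.size) else np.zeros((0, 2), np.int64)
    network = build_network(chains, merged, positions, config)

    counts = network.crosslinks_per_filament()
    stats = TopologyStats(
        mean_cls_per_filament=float(counts.mean()) if counts.size else 0.0,
        sd_cls_per_filament=float(counts.std()) if counts.size else 0.0,
        n_filaments=network.n_filaments,
        n_cl_bonds=int(network.cl_bond_particles.shape[0]),
    )
    bundle = CellBundle(
        positions=positions,
        types=types,
        cell_mesh=cell_mesh,
        nucleus_mesh=nucleus_mesh,
        network=network,
        stats=stats,
        diameter=diameter,
        nc_ratio=nc_ratio,
        seed=seed,
    )
    if link:
        link_membranes(bundle, config, units=units)
    else:
        add_torsions(bundle.network, bundle.positions)
    return bundle


def link_membranes(
    bundle: CellBundle,
    config: AssemblyConfig,
    thermo: ThermoState | None = None,
    max_steps: int | None = None,
    units: UnitSystem = DEFAULT_UNITS,
) -> TopologyStats:
    """Stochastic filament-membrane linking with frozen membranes.

    One membrane vertex per filament particle and vice versa; cell links
    bind within 0.5 um, nucleus links within 0.4 um; unbinding follows the
    force-dependent law with per-class parameters.  Runs until the linked
    count converges, then adds torsion quadruples and updates positions.
    """
    cfg = config
    thermo = thermo or ThermoState(seed=bundle.seed + 7)
    max_steps = cfg.link_max_steps if max_steps is None else max_steps
    rng = np.random.default_rng(bundle.seed + 7)

    pad = 4.0
    box = np.full(3, bundle.diameter + 2 * pad)
    shift = box / 2.0 - bundle.centroid
    positions = bundle.positions + shift
    system = ParticleSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        types=bundle.types,
        box=box,
        periodic=np.array([False, False, False]),
    )
    frozen = (bundle.types == MEMBRANE) | (bundle.types == NUCLEUS)
    net = bundle.network
    sim = Simulation(
        system,
        default_interactions(thermo.kbt),
        thermo,
        bonded_callbacks=[network_callback(net)],
        frozen_mask=frozen,
        wrap_positions=False,
    )

    nv_c = bundle.cell_mesh.n_vertices
    cell_verts = np.arange(nv_c)
    nucl_verts = (
        np.arange(nv_c, nv_c + bundle.nucleus_mesh.n_vertices)
        if bundle.nucleus_mesh is not None
        else np.zeros(0, np.int64)
    )
    fil_idx = np.flatnonzero(bundle.types == FILAMENT)
    cell_tree = cKDTree(system.positions[cell_verts])
    nucl_tree = cKDTree(system.positions[nucl_verts]) if nucl_verts.size else None

    links: dict[int, int] = {}  # filament particle -> vertex particle
    link_r0: dict[int, float] = {}  # filament particle -> rest length
    vertex_used: set[int] = set()
    dt_window = cfg.check_every * thermo.dt * units.time_si

    def refresh() -> None:
        items = sorted(links.items())
        net.membrane_links = np.asarray(items, dtype=np.int64).reshape(-1, 2)
        net.link_k = np.full(len(items), KAPPA_CL)
        net.link_r0 = np.asarray([link_r0[f] for f, _ in items]) if items else np.zeros(0)
        sim._forces = None

    done = 0
    prev_count = None
    while done < max_steps:
        sim.step(cfg.check_every)
        done += cfg.check_every
        changed = False
        # unbinding
        for f, v in list(links.items()):
            is_cell = v < nv_c
            bell = cfg.cell_link_bell if is_cell else cfg.nucleus_link_bell
            r = float(np.linalg.norm(system.positions[f] - system.positions[v]))
            force = abs(2.0 * KAPPA_CL * (r - link_r0[f]))
            if rng.random() < bell_unbind_probability(
                force, r, bell, thermo.kbt, dt_phys=dt_window
            ):
                del links[f]
                del link_r0[f]
                vertex_used.discard(v)
                changed = True
        # binding
        unlinked = [int(f) for f in fil_idx if int(f) not in links]
        if unlinked:
            pf = system.positions[unlinked]
            for tree, verts, radius in (
                (cell_tree, cell_verts, cfg.cell_link_bell.r0),
                (nucl_tree, nucl_verts, cfg.nucleus_link_bell.r0),
            ):
                if tree is None:
                    continue
                d, j = tree.query(pf, k=1, distance_upper_bound=radius)
                for fi, (dd, jj) in enumerate(zip(d, j)):
                    f = unlinked[fi]
                    if not np.isfinite(dd) or f in links:
                        continue
                    v = int(verts[jj])
                    if v in vertex_used:
                        continue
                    links[f] = v
                    link_r0[f] = float(
                        np.linalg.norm(system.positions[f] - system.positions[v])
                    )
                    vertex_used.add(v)
                    changed = True
        if changed:
            refresh()
        if done % cfg.convergence_window < cfg.check_every:
            cur = len(links)
            if prev_count is not None and abs(cur - prev_count) <= max(
                1.0, cfg.convergence_rtol * max(prev_count, 1)
            ):
                break
            prev_count = cur

    refresh()
    add_torsions(net, system.positions)
    bundle.positions = system.positions - shift
    n_cell_links = sum(1 for v in links.values() if v < nv_c)
    n_nucl_links = len(links) - n_cell_links
    bundle.stats.cell_linked_fraction = n_cell_links / max(1, nv_c)
    bundle.stats.nucleus_linked_fraction = (
        n_nucl_links / max(1, nucl_verts.size) if nucl_verts.size else 0.0
    )
    return bundle.stats
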