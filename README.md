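# mesocell

A mesoscopic, particle-based model of a eukaryotic cell — triangulated
viscoelastic membrane, nucleus envelope, and a cross-linked filament
network — embedded in a Dissipative Particle Dynamics (DPD) solvent, with
two virtual experiments (micropipette aspiration and transit through a
microfluidic obstacle array) and the analysis used to extract whole-cell
elastic modulus and viscosity.

## Layout

| module | contents |
| --- | --- |
| `mesocell.dpd_core` | particle container, type-pair interaction table (dual cutoffs, fluctuation–dissipation-consistent random forces), cell-list neighbor search, modified velocity-Verlet integrator |
| `mesocell.membrane` | sphere meshing at arbitrary vertex count, worm-like-chain + area-repulsion elasticity, dihedral bending, global area/volume constraints, membrane viscosity (traceless-symmetric Wiener random forces) |
| `mesocell.cytoskeleton` | harmonic bond/angle forces, four-body torsion across cross-links, force-dependent (Bell-law) unbinding kinetics |
| `mesocell.cell_assembly` | stochastic network generation: filament seeding, polymerization/depolymerization, cross-link formation with prune-and-merge, carving to the cell volume, chromatin, membrane linking |
| `mesocell.geometry_flow` | signed-distance wall geometries (pipette, triangular pillar arrays), frozen-particle walls + bounce-back reflection, body-force flow driving |
| `mesocell.experiments` | aspiration pressure ramps (L_n = (L_p − L_p0)/R_p records), obstacle-array transit (velocity / stuck outcomes), ensembles over cells and rotations |
| `mesocell.analysis` | half-space punch modulus fit (E = 3Φ_p·ΔP/(2π·L_n)), creep viscosity from the plateau approach, sweep summaries |
| `mesocell.cli_io` | YAML run configuration, XYZ/VTK/OFF/HDF5 I/O, reduced-scale fixtures, CLI |

Units: 1 sim length = 1 µm; energy and time scales are configurable
constants in `mesocell.units.UnitSystem` (defaults 1.15e-18 J, 3.33e-5 s).

## CLI

```bash
mesocell fixture mini-cell --seed 1 --out cell.json   # reduced-scale cell bundle
mesocell build-cell --config run.yaml                  # full assembly from YAML
mesocell aspirate  --config run.yaml --cell cell.json  # aspiration ramp -> CSV
mesocell transit   --config run.yaml --cell cell.json  # obstacle-array transit
mesocell analyze   --record out/aspiration.csv --creep # E (and eta) fits
```

A minimal config (`mesocell.cli_io.config.RunConfig` schema; unknown keys
are rejected):

```yaml
cell: {diameter: 16.0, nc_ratio: 0.29, n_vertices: 3500}
thermo: {kbt: 1.0, dt: 1.0e-3, steps: 500000, seed: 1}
experiment: {kind: aspiration, pipette_radius: 3.0}
output: {directory: out}
```

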