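"""YAML run configuration with strict schema validation.

Unknown keys are rejected with the offending field named; every run echoes
its full configuration (including the seed) into the output directory for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    kwargs = {}
    for f in dc_fields(cls):
        if f.name in data:
            val = data[f.name]
            sub = _NESTED.get((cls, f.name))
            kwargs[f.name] = (
                _from_dict(sub, val, f"{path}.{f.name}") if sub else val
            )
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class CellSpec:
    diameter: float = 16.0
    nc_ratio: float = 0.29
    n_vertices: int = 3500
    fil_density: float = 3.5
    cl_density: float = 0.525
    fil_density_nucleus: float | None = None
    polymerize_steps: int = 10_000
    cl_max_steps: int = 600_000
    link_max_steps: int = 200_000
    convergence_window: int = 10_000
    check_every: int = 50

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0.0 <= self.nc_ratio < 1.0:
            raise ValueError("nc_ratio must be in [0, 1)")


@dataclass
class ThermoSpec:
    kbt: float = 1.0
    dt: float = 1.0e-3
    steps: int = 500_000
    seed: int = 0


@dataclass
class ExperimentSpec:
    kind: str = "aspiration"          # aspiration | transit
    pipette_radius: float = 3.0
    rate_pa_s: float = 3.27
    max_pressure_pa: float = 117.72
    baseline_pa: float = 2.0
    hold_pressure_pa: float | None = None
    ramp_steps: int = 20_000
    gap: float = 12.0
    depth: float = 25.8
    row_spacing: float = 60.0
    pillar_side: float = 20.0
    first_row_y: float = 20.0
    pressure_gradient_pa_um: float = 0.67
    transit_steps: int = 40_000

    def __post_init__(self) -> None:
        if self.kind not in ("aspiration", "transit"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")


@dataclass
class OutputSpec:
    directory: str = "out"
    cadence: int = 1000
    trajectory_format: str = "xyz"    # xyz | vtk | h5


@dataclass
class RunConfig:
    cell: CellSpec = field(default_factory=CellSpec)
    thermo: ThermoSpec = field(default_factory=ThermoSpec)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    output: OutputSpec = field(default_factory=OutputSpec)


_NESTED = {
    (RunConfig, "cell"): CellSpec,
    (RunConfig, "thermo"): ThermoSpec,
    (RunConfig, "experiment"): ExperimentSpec,
    (RunConfig, "output"): OutputSpec,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"{path}: empty configuration; missing sections "
                          f"(cell, thermo, experiment, output)")
    return _from_dict(RunConfig, raw, "config")


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
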