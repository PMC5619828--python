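"""Assembly configuration and topology statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

from mesocell.cytoskeleton.bell import (
    BellParameters,
    CL_BELL,
    CELL_LINK_BELL,
    NUCLEUS_LINK_BELL,
)


@dataclass
class AssemblyConfig:
    """Densities, radii, kinetics and phase lengths of network generation.

    Step counts follow the generation protocol (polymerization 1e4 steps,
    cross-linking up to ~6e5 steps, membrane linking until the linked count
    converges); tests shrink them.  ``check_every`` is the interval (steps)
    between binding/unbinding event sweeps.
    """

    fil_density: float = 3.5          # filament particles / um^3
    filament_length: float = 4.0      # um
    fil_spacing: float = 0.5          # particle spacing along a chain, um
    cl_density: float = 0.525         # CL particles / um^3
    growth_radius: float = 0.5        # polymerization binding radius, um
    cl_bell: BellParameters = CL_BELL                 # binding radius 0.25 um
    cell_link_bell: BellParameters = CELL_LINK_BELL   # radius 0.5 um
    nucleus_link_bell: BellParameters = NUCLEUS_LINK_BELL  # radius 0.4 um
    fil_density_nucleus: float | None = None  # chromatin; default = fil_density

    polymerize_steps: int = 10_000
    cl_max_steps: int = 600_000
    link_max_steps: int = 200_000
    convergence_window: int = 10_000  # steps per convergence check
    convergence_rtol: float = 0.01
    check_every: int = 50

    min_chain_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fil_density", "cl_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("filament_length", "fil_spacing", "growth_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def particles_per_filament(self) -> int:
        return int(round(self.filament_length / self.fil_spacing)) + 1

    @property
    def chromatin_density(self) -> float:
        return (
            self.fil_density
            if self.fil_density_nucleus is None
            else self.fil_density_nucleus
        )


@dataclass
class TopologyStats:
    """Summary of a generated network's connectivity."""

    mean_cls_per_filament: float = 0.0
    sd_cls_per_filament: float = 0.0
    n_filaments: int = 0
    n_cl_bonds: int = 0
    cell_linked_fraction: float = 0.0
    nucleus_linked_fraction: float = 0.0
    free_cl_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in (self.cell_linked_fraction, self.nucleus_linked_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("linked fractions must lie in [0, 1]")
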