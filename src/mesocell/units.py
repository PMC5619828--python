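"""Mapping between simulation units and SI.

The model is scale-free: length, energy and time scales are fixed only when
results are compared with experiments.  One simulation length unit is 1 um.
The default energy unit is inferred from the filament spring constant
(0.092 N/m <-> 8e4 sim at 1 um), the default time unit from the membrane
viscosity parameter (1.15e-9 N s/m <-> 30 sim).  The membrane bending rows
of the parameter table imply a *different* energy scale; both are therefore
plain configuration constants rather than derived quantities, and no
consistency between them is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors between simulation units and SI.

    Parameters
    ----------
    length_si : float
        Metres per simulation length unit (default 1 um).
    energy_si : float
        Joules per simulation energy unit (k_B T = 1 in sim units).
    time_si : float
        Seconds per simulation time unit.
    """

    length_si: float = 1.0e-6
    energy_si: float = 1.15e-18
    # (1.15e-9 N s/m / 30) * (1 um)^2 / (1.15e-18 J) = 3.333e-5 s
    time_si: float = (1.15e-9 / 30.0) * 1.0e-12 / 1.15e-18

    @property
    def force_si(self) -> float:
        """Newtons per simulation force unit."""
        return self.energy_si / self.length_si

    @property
    def pressure_si(self) -> float:
        """Pascals per simulation pressure unit."""
        return self.energy_si / self.length_si**3

    @property
    def velocity_si(self) -> float:
        """m/s per simulation velocity unit."""
        return self.length_si / self.time_si

    @property
    def viscosity_si(self) -> float:
        """Pa s per simulation dynamic-viscosity unit."""
        return self.pressure_si * self.time_si

    # -- converters (SI -> sim) ------------------------------------------
    def pressure_to_sim(self, pascals: float) -> float:
        return pascals / self.pressure_si

    def pressure_gradient_to_sim(self, pa_per_um: float) -> float:
        """Pressure gradient given in Pa/um -> sim pressure / sim length."""
        pa_per_m = pa_per_um * 1.0e6
        return pa_per_m * self.length_si / self.pressure_si

    def time_to_sim(self, seconds: float) -> float:
        return seconds / self.time_si

    # -- converters (sim -> SI) ------------------------------------------
    def pressure_to_si(self, sim: float) -> float:
        return sim * self.pressure_si

    def velocity_to_si(self, sim: float) -> float:
        return sim * self.velocity_si

    def time_to_si(self, sim: float) -> float:
        return sim * self.time_si


DEFAULT_UNITS = UnitSystem()
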