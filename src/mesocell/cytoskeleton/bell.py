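"""Force-dependent bond dissociation (Bell kinetics).

    kappa(F) = kappa0 * exp(lambda F / kbt)   if r >= r0
             = kappa0                         if r <  r0

Rates are physical (1/s); conversion to a per-step probability goes through
the configured time unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mesocell.units import UnitSystem, DEFAULT_UNITS

_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class BellParameters:
    """Zero-force rate (1/s), mechanical sensitivity (um), binding radius (um)."""

    kappa0: float
    lam: float
    r0: float

    def __post_init__(self) -> None:
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


# default parameter sets per bond class
CL_BELL = BellParameters(kappa0=78.0, lam=3.5e-5, r0=0.25)
CELL_LINK_BELL = BellParameters(kappa0=30.0, lam=1.0e-4, r0=0.5)
NUCLEUS_LINK_BELL = BellParameters(kappa0=78.0, lam=2.0e-4, r0=0.4)


def bell_rate(
    force: float | np.ndarray,
    r: float | np.ndarray,
    params: BellParameters,
    kbt: float = 1.0,
) -> np.ndarray:
    """Unbinding rate in 1/s.  ``force`` is the spring-force magnitude in
    simulation force units, ``r`` the bond separation in um."""
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force magnitude must be nonnegative")
    arg = np.minimum(params.lam * force / kbt, _EXP_CLAMP)
    loaded = params.kappa0 * np.exp(arg)
    return np.where(np.asarray(r) < params.r0, params.kappa0, loaded)


def bell_unbind_probability(
    force: float | np.ndarray,
    r: float | np.ndarray,
    params: BellParameters,
    kbt: float = 1.0,
    dt_phys: float | None = None,
    dt_sim: float | None = None,
    units: UnitSystem = DEFAULT_UNITS,
) -> np.ndarray:
    """Per-step unbinding probability 1 - exp(-kappa(F) dt).

    Pass either ``dt_phys`` (seconds) directly or ``dt_sim`` (simulation
    time) to be converted through ``units``.  Monotone nondecreasing in F
    for r >= r0; clamps to 1 on exponent overflow.
    """
    if dt_phys is None:
        if dt_sim is None:
            raise ValueError("provide dt_phys or dt_sim")
        dt_phys = dt_sim * units.time_si
    if dt_phys <= 0:
        raise ValueError("time step must be positive")
    rate = bell_rate(force, r, params, kbt)
    return -np.expm1(-rate * dt_phys)
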