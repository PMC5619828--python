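"""Symmetric type-pair table of DPD interaction parameters.

Default values (format a/gamma), with type ids
1=fluid, 2=filament, 3=membrane, 4=nucleus, 5=wall:

          1.fluid  2.filament  3.membrane  4.nucleus  5.wall
1.fluid   10/30    10/45       4/45        4/45       10/30
2.fil              100/65 *    100/65 *    4/65       4/65
3.mem                          100/45 +    100/45 +   10/45
4.nuc                                      100/45 +   10/45
5.wall                                                excl.

Entries marked * use R_c = 0.5 for the repulsion and R_c = 1.0 for the
thermostat; entries marked + use R_c = 0.5 for both.  The short repulsion
cutoff with a = 100 keeps filaments (and membranes) from crossing, while
the thermostat cutoff/gamma stay free to tune viscosity.  Wall-wall pairs
are excluded (walls are frozen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mesocell.dpd_core.particles import N_TYPES, WALL


@dataclass
class InteractionTable:
    """Per-type-pair conservative/dissipative parameters with dual cutoffs.

    sigma is always derived as sqrt(2 * gamma * kbt) so the fluctuation-
    dissipation relation holds exactly for every pair.  Matrices are indexed
    by type id (1-based; row/col 0 unused).
    """

    kbt: float = 1.0
    weight_exponent: float = 0.25
    a: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    rc_rep: np.ndarray = field(default=None)  # type: ignore[assignment]
    rc_th: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = N_TYPES + 1
        if self.a is None:
            self.a = np.zeros((n, n))
        if self.gamma is None:
            self.gamma = np.zeros((n, n))
        if self.rc_rep is None:
            self.rc_rep = np.ones((n, n))
        if self.rc_th is None:
            self.rc_th = np.ones((n, n))
        if self.excluded is None:
            self.excluded = np.zeros((n, n), dtype=bool)

    def set_pair(
        self,
        ti: int,
        tj: int,
        a: float,
        gamma: float,
        rc_rep: float = 1.0,
        rc_th: float = 1.0,
        excluded: bool = False,
    ) -> None:
        if gamma < 0:
            raise ValueError("gamma must be nonnegative")
        for (x, y) in ((ti, tj), (tj, ti)):
            self.a[x, y] = a
            self.gamma[x, y] = gamma
            self.rc_rep[x, y] = rc_rep
            self.rc_th[x, y] = rc_th
            self.excluded[x, y] = excluded

    @property
    def sigma(self) -> np.ndarray:
        """Random-force strengths, sigma^2 = 2 gamma kbt exactly."""
        return np.sqrt(2.0 * self.gamma * self.kbt)

    def max_cutoff(self) -> float:
        active = ~self.excluded
        return float(max(self.rc_rep[active].max(), self.rc_th[active].max()))

    def validate(self) -> None:
        for m in (self.a, self.gamma, self.rc_rep, self.rc_th):
            if not np.allclose(m, m.T):
                raise ValueError("interaction table must be symmetric in type pair")
        if not np.array_equal(self.excluded, self.excluded.T):
            raise ValueError("exclusion flags must be symmetric")
        if np.any(self.gamma < 0):
            raise ValueError("gamma must be nonnegative")

    def copy(self) -> "InteractionTable":
        return InteractionTable(
            kbt=self.kbt,
            weight_exponent=self.weight_exponent,
            a=self.a.copy(),
            gamma=self.gamma.copy(),
            rc_rep=self.rc_rep.copy(),
            rc_th=self.rc_th.copy(),
            excluded=self.excluded.copy(),
        )


def default_interactions(
    kbt: float = 1.0,
    filament_gamma: float = 65.0,
    filament_rc_th: float = 1.0,
) -> InteractionTable:
    """Interaction table with the default parameter set.

    ``filament_gamma`` and ``filament_rc_th`` control the thermostat acting
    on filament pairs (filament-filament and filament-membrane); they are the
    two knobs used to tune whole-cell viscosity.
    """
    t = InteractionTable(kbt=kbt)
    t.set_pair(1, 1, 10.0, 30.0)
    t.set_pair(1, 2, 10.0, 45.0)
    t.set_pair(1, 3, 4.0, 45.0)
    t.set_pair(1, 4, 4.0, 45.0)
    t.set_pair(1, 5, 10.0, 30.0)
    t.set_pair(2, 2, 100.0, filament_gamma, rc_rep=0.5, rc_th=filament_rc_th)
    t.set_pair(2, 3, 100.0, filament_gamma, rc_rep=0.5, rc_th=filament_rc_th)
    t.set_pair(2, 4, 4.0, 65.0)
    t.set_pair(2, 5, 4.0, 65.0)
    t.set_pair(3, 3, 100.0, 45.0, rc_rep=0.5, rc_th=0.5)
    t.set_pair(3, 4, 100.0, 45.0, rc_rep=0.5, rc_th=0.5)
    t.set_pair(3, 5, 10.0, 45.0)
    t.set_pair(4, 4, 100.0, 45.0, rc_rep=0.5, rc_th=0.5)
    t.set_pair(4, 5, 10.0, 45.0)
    t.set_pair(WALL, WALL, 0.0, 0.0, excluded=True)
    t.validate()
    return t
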