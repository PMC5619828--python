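"""Derived mechanical quantities from experiment records.

Elastic modulus: half-space rigid-punch model of pipette aspiration,

    E = 3 Phi_p dP / (2 pi L_n),

with wall function Phi_p = 2.1 by default; fitted as the least-squares
slope of dP against L_n over the linear (low-pressure) regime.

Viscosity: creep extension of the punch model.  At constant suction the
normalized length follows L_n(t) = L_inf (1 - exp(-t / tau)); the
effective viscosity is eta = E * tau (Kelvin-Voigt-type relaxation,
tau = eta / E), reported in mPa s.  Eta is strictly increasing in tau at
fixed E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from mesocell.experiments import ExperimentRecord
from mesocell.units import UnitSystem, DEFAULT_UNITS


class FitError(RuntimeError):
    pass


@dataclass
class ModulusFit:
    modulus_pa: float
    phi_p: float
    slope_pa: float          # d(dP)/d(L_n)
    fit_range_pa: tuple
    residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.modulus_pa <= 0:
            raise FitError("nonpositive elastic modulus")


@dataclass
class ViscosityFit:
    eta_mpa_s: float
    tau_s: float
    plateau_l_n: float
    hold_pressure_pa: float

    def __post_init__(self) -> None:
        if self.eta_mpa_s < 0 or self.tau_s < 0:
            raise FitError("negative viscosity or time constant")


def theret_modulus(
    record: ExperimentRecord,
    phi_p: float = 2.1,
    fit_fraction: float = 0.5,
    dp_range: tuple | None = None,
) -> ModulusFit:
    """Elastic modulus from the linear regime of L_n(dP).

    ``fit_fraction`` selects the lower part of the ramp (default: lower
    half) unless an explicit ``dp_range`` (Pa) is given.
    """
    df = record.data
    if dp_range is None:
        dp_max = df["dp_pa"].max()
        dp_range = (0.0, fit_fraction * dp_max)
    sel = df[(df["dp_pa"] >= dp_range[0]) & (df["dp_pa"] <= dp_range[1])]
    sel = sel[sel["l_n"] > 0]
    if len(sel) < 3:
        raise FitError("need >= 3 (dP, L_n) points in the linear regime")
    # slope of dP vs L_n through the origin (baseline already subtracted)
    ln = sel["l_n"].to_numpy()
    dp = sel["dp_pa"].to_numpy()
    slope = float(np.dot(ln, dp) / np.dot(ln, ln))
    if slope <= 0:
        raise FitError("nonpositive slope in dP vs L_n")
    resid = float(np.sqrt(np.mean((dp - slope * ln) ** 2)))
    e = 3.0 * phi_p * slope / (2.0 * np.pi)
    return ModulusFit(
        modulus_pa=e,
        phi_p=phi_p,
        slope_pa=slope,
        fit_range_pa=tuple(dp_range),
        residual=resid,
        n_points=len(sel),
    )


def point_modulus(dp_pa: float, l_n: float, phi_p: float = 2.1) -> float:
    """Single-point evaluation E = 3 Phi_p dP / (2 pi L_n)."""
    if l_n <= 0:
        raise FitError("L_n must be positive")
    return 3.0 * phi_p * dp_pa / (2.0 * np.pi * l_n)


def creep_viscosity(
    record: ExperimentRecord,
    modulus_fit: ModulusFit,
    plateau_rtol: float = 0.1,
) -> ViscosityFit:
    """Viscosity from a constant-pressure (hold) record via the creep fit."""
    df = record.data
    if "t_s" not in df or "l_n" not in df:
        raise FitError("record lacks t_s / l_n columns")
    t = df["t_s"].to_numpy()
    ln = df["l_n"].to_numpy()
    if len(t) < 5:
        raise FitError("record too short for a creep fit")
    t = t - t[0]

    def model(tt, l_inf, tau):
        return l_inf * (1.0 - np.exp(-tt / np.maximum(tau, 1e-30)))

    l_guess = max(float(ln[-1]), 1e-6)
    tau_guess = max(float(t[-1]) / 5.0, 1e-12)
    try:
        popt, _ = curve_fit(
            model, t, ln, p0=(l_guess, tau_guess),
            bounds=((0.0, 0.0), (np.inf, np.inf)), maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"creep fit failed: {exc}") from exc
    l_inf, tau = float(popt[0]), float(popt[1])
    # plateau must be approached within the record
    if tau > 0 and t[-1] < 2.0 * tau:
        raise FitError("no plateau reached within the record (t_end < 2 tau)")
    tail = ln[int(0.9 * len(ln)) :]
    if l_inf > 0 and abs(float(tail.mean()) - l_inf) > plateau_rtol * l_inf:
        raise FitError("record tail is not at the fitted plateau")
    eta_pa_s = modulus_fit.modulus_pa * tau
    hold = float(df["dp_pa"].iloc[-1]) if "dp_pa" in df else float("nan")
    return ViscosityFit(
        eta_mpa_s=eta_pa_s * 1e3,
        tau_s=tau,
        plateau_l_n=l_inf,
        hold_pressure_pa=hold,
    )


def sweep_summary(runs: list, swept_parameter: str) -> pd.DataFrame:
    """Tidy per-level mean +/- SD for a one-parameter sweep.

    ``runs`` is a list of dicts with keys: ``swept_parameter``, and either
    ``modulus_pa`` or ``velocity_mm_s`` (one kind per sweep).
    """
    if not runs:
        raise ValueError("empty sweep")
    df = pd.DataFrame(runs)
    if swept_parameter not in df:
        raise KeyError(f"missing swept parameter column {swept_parameter!r}")
    value_cols = [c for c in ("modulus_pa", "velocity_mm_s") if c in df]
    if not value_cols:
        raise ValueError("runs carry neither modulus_pa nor velocity_mm_s")
    if len(value_cols) == 2 and df[value_cols].notna().all(axis=None):
        pass  # both measured for every run is fine
    elif len(value_cols) == 2:
        raise ValueError("mixed experiment types in one sweep")
    levels = df.groupby(swept_parameter)
    if len(levels) < 1:
        raise ValueError("no parameter levels")
    out = []
    for level, grp in levels:
        for col in value_cols:
            vals = grp[col].dropna()
            out.append(
                {
                    "parameter": swept_parameter,
                    "level": level,
                    "quantity": col,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(out)
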