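"""Pairwise DPD forces: soft conservative repulsion plus thermostat pair.

The conservative force is a(1 - r/R_c) r_hat for r < R_c.  The dissipative
and random forces use the generalized weight w_R(r) = (1 - r/R_c)^s with
s = 0.25 and w_D = (w_R)^2; sigma^2 = 2 gamma k_B T closes the
fluctuation-dissipation relation.  The random force carries the 1/sqrt(dt)
scaling inside the integrator kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


class DegeneratePairError(ValueError):
    """Raised for coincident particles (zero separation)."""


def conservative_force(r_ij: np.ndarray, a: float, rc: float) -> np.ndarray:
    """Soft repulsion on particle i from particle j, r_ij = r_i - r_j."""
    r_ij = np.asarray(r_ij, dtype=np.float64)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise DegeneratePairError("coincident particles: |r_ij| = 0")
    if r >= rc:
        return np.zeros(3)
    return a * (1.0 - r / rc) * (r_ij / r)


def dissipative_random_forces(
    r_ij: np.ndarray,
    v_ij: np.ndarray,
    gamma: float,
    sigma: float,
    rc: float,
    kbt: float,
    theta: float,
    s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Thermostat force pair (f_D, f_R) on particle i, without dt scaling.

    ``theta`` is the symmetric per-pair unit-variance noise (theta_ij =
    theta_ji).  Raises on gamma < 0 or sigma inconsistent with 2 gamma kbt.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if abs(sigma * sigma - 2.0 * gamma * kbt) > 1e-10 * max(1.0, gamma * kbt):
        raise ValueError("sigma^2 must equal 2 gamma k_B T")
    r_ij = np.asarray(r_ij, dtype=np.float64)
    v_ij = np.asarray(v_ij, dtype=np.float64)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise DegeneratePairError("coincident particles: |r_ij| = 0")
    if r >= rc:
        return np.zeros(3), np.zeros(3)
    rhat = r_ij / r
    w_r = (1.0 - r / rc) ** s
    w_d = w_r * w_r
    f_d = -gamma * w_d * float(np.dot(rhat, v_ij)) * rhat
    f_r = sigma * w_r * theta * rhat
    return f_d, f_r


@njit(cache=True)
def pair_forces_kernel(
    pos,
    vel,
    types,
    pi,
    pj,
    a_mat,
    gamma_mat,
    sigma_mat,
    rc_rep_mat,
    rc_th_mat,
    excluded_mat,
    s_exp,
    box,
    periodic,
    inv_sqrt_dt,
    theta,
    forces,
):
    """Accumulate conservative + dissipative + random pair forces in place.

    ``theta`` holds one standard normal per candidate pair, shared by both
    pair members (antisymmetric force -> exact momentum conservation).
    """
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        ti = types[i]
        tj = types[j]
        if excluded_mat[ti, tj]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic[0]:
            dx -= box[0] * np.round(dx / box[0])
        if periodic[1]:
            dy -= box[1] * np.round(dy / box[1])
        if periodic[2]:
            dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        rc_r = rc_rep_mat[ti, tj]
        rc_t = rc_th_mat[ti, tj]
        rc_max = rc_r if rc_r > rc_t else rc_t
        if r2 >= rc_max * rc_max or r2 == 0.0:
            continue
        r = np.sqrt(r2)
        ex = dx / r
        ey = dy / r
        ez = dz / r
        fmag = 0.0
        if r < rc_r:
            fmag += a_mat[ti, tj] * (1.0 - r / rc_r)
        if r < rc_t:
            gamma = gamma_mat[ti, tj]
            if gamma > 0.0:
                w_r = (1.0 - r / rc_t) ** s_exp
                w_d = w_r * w_r
                dvx = vel[i, 0] - vel[j, 0]
                dvy = vel[i, 1] - vel[j, 1]
                dvz = vel[i, 2] - vel[j, 2]
                rdotv = ex * dvx + ey * dvy + ez * dvz
                fmag += -gamma * w_d * rdotv
                fmag += sigma_mat[ti, tj] * w_r * theta[k] * inv_sqrt_dt
        if fmag != 0.0:
            forces[i, 0] += fmag * ex
            forces[i, 1] += fmag * ey
            forces[i, 2] += fmag * ez
            forces[j, 0] -= fmag * ex
            forces[j, 1] -= fmag * ey
            forces[j, 2] -= fmag * ez
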