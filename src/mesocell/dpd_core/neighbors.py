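"""Cell-list neighbor search.

Every unordered pair within the cutoff is listed exactly once.  The numba
kernel bins particles into cells of side >= cutoff and scans the half
stencil of 13 neighbor offsets plus the home cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from mesocell.dpd_core.particles import ParticleSystem


class ConfigurationError(ValueError):
    pass


@njit(cache=True)
def _min_image(dx: float, box: float, periodic: bool) -> float:
    if periodic:
        dx -= box * np.round(dx / box)
    return dx


# half stencil: home cell handled separately
_STENCIL = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _cell_pairs(pos, box, periodic, cutoff, stencil, buf):
    n = pos.shape[0]
    ncx = max(1, int(box[0] // cutoff))
    ncy = max(1, int(box[1] // cutoff))
    ncz = max(1, int(box[2] // cutoff))
    ncells = ncx * ncy * ncz
    nc = np.array([ncx, ncy, ncz], dtype=np.int64)

    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        x0, x1, x2 = pos[i, 0], pos[i, 1], pos[i, 2]
        if periodic[0]:
            x0 -= box[0] * np.floor(x0 / box[0])
        if periodic[1]:
            x1 -= box[1] * np.floor(x1 / box[1])
        if periodic[2]:
            x2 -= box[2] * np.floor(x2 / box[2])
        cx = int(x0 / box[0] * ncx)
        cy = int(x1 / box[1] * ncy)
        cz = int(x2 / box[2] * ncz)
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    cut2 = cutoff * cutoff
    m = 0
    cap = buf.shape[0]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                start = counts[c]
                end = counts[c + 1]
                # home cell, i < j
                for ii in range(start, end):
                    i = order[ii]
                    for jj in range(ii + 1, end):
                        j = order[jj]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0], periodic[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1], periodic[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2], periodic[2])
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if m >= cap:
                                return -1, buf
                            buf[m, 0] = i
                            buf[m, 1] = j
                            m += 1
                # stencil cells
                for s in range(stencil.shape[0]):
                    ox = cx + stencil[s, 0]
                    oy = cy + stencil[s, 1]
                    oz = cz + stencil[s, 2]
                    skip = False
                    oxyz = np.array([ox, oy, oz], dtype=np.int64)
                    for d in range(3):
                        if oxyz[d] < 0 or oxyz[d] >= nc[d]:
                            if periodic[d] and nc[d] >= 3:
                                oxyz[d] = oxyz[d] % nc[d]
                            elif periodic[d] and nc[d] < 3:
                                # small periodic dim: wrap but avoid double
                                oxyz[d] = oxyz[d] % nc[d]
                            else:
                                skip = True
                    if skip:
                        continue
                    c2 = (oxyz[0] * ncy + oxyz[1]) * ncz + oxyz[2]
                    if c2 == c:
                        continue
                    s2 = counts[c2]
                    e2 = counts[c2 + 1]
                    for ii in range(start, end):
                        i = order[ii]
                        for jj in range(s2, e2):
                            j = order[jj]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0], periodic[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1], periodic[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2], periodic[2])
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if m >= cap:
                                    return -1, buf
                                buf[m, 0] = i
                                buf[m, 1] = j
                                m += 1
    return m, buf


def build_neighbor_lists(
    system: ParticleSystem, max_cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered pairs within ``max_cutoff``; returns (i, j) index arrays.

    Raises ``ConfigurationError`` when a periodic box dimension is smaller
    than 3x the cutoff (the half-stencil would double count images).
    """
    for d in range(3):
        if system.periodic[d] and system.box[d] < 3.0 * max_cutoff:
            raise ConfigurationError(
                f"periodic box dimension {d} ({system.box[d]}) must exceed "
                f"3 x cutoff ({3.0 * max_cutoff})"
            )
    pos = system.positions
    n = pos.shape[0]
    cap = max(1024, n * 64)
    while True:
        buf = np.empty((cap, 2), dtype=np.int64)
        m, buf = _cell_pairs(
            pos, system.box, system.periodic, float(max_cutoff), _STENCIL, buf
        )
        if m >= 0:
            return np.ascontiguousarray(buf[:m, 0]), np.ascontiguousarray(buf[:m, 1])
        cap *= 2


def brute_force_pairs(
    system: ParticleSystem, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """O(N^2) reference pair scan (oracle for the cell list)."""
    pos = system.positions
    n = pos.shape[0]
    dr = pos[:, None, :] - pos[None, :, :]
    for d in range(3):
        if system.periodic[d]:
            dr[:, :, d] -= system.box[d] * np.round(dr[:, :, d] / system.box[d])
    dist2 = np.sum(dr * dr, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    mask = dist2[iu, ju] < cutoff * cutoff
    return iu[mask], ju[mask]
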