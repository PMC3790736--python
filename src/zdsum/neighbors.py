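"""Pair enumeration under the minimum-image convention.

Two interchangeable strategies are provided: a brute-force O(n²) distance
matrix and a cell-list search. Both return the identical pair set (tested),
so evaluators may pick by system size.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .system import ParticleSystem

__all__ = ["minimum_image_displacements", "brute_force_pairs", "cell_list_pairs", "pairs_within"]


def minimum_image_displacements(
    positions: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """(n, n, 3) displacement tensor r_i − r_j, minimum-imaged if periodic."""
    d = positions[:, None, :] - positions[None, :, :]
    if box is not None:
        d -= np.round(d / box) * box
    return d


def brute_force_pairs(
    system: ParticleSystem, r_c: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All i<j pairs with minimum-image distance < r_c.

    Returns (i, j, r) index arrays plus distances.
    """
    d = minimum_image_displacements(system.positions, system.box)
    dist = np.linalg.norm(d, axis=-1)
    iu, ju = np.triu_indices(system.n_particles, k=1)
    mask = dist[iu, ju] < r_c
    return iu[mask], ju[mask], dist[iu, ju][mask]


def cell_list_pairs(
    system: ParticleSystem, r_c: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-list pair search; identical pair set to :func:`brute_force_pairs`.

    Periodic systems only (open clusters fall back to brute force). Cells
    have edge >= r_c; each cell is compared with its 26 neighbors through
    periodic wrapping, and exact distances filter the candidates.
    """
    if system.box is None:
        return brute_force_pairs(system, r_c)
    box = system.box
    n_cells = np.maximum(1, np.floor(box / r_c).astype(int))
    if np.any(n_cells < 3):
        # too few cells for a meaningful neighbor stencil
        return brute_force_pairs(system, r_c)
    frac = (system.positions / box) % 1.0
    cell_idx = np.minimum((frac * n_cells).astype(int), n_cells - 1)
    flat = np.ravel_multi_index(cell_idx.T, n_cells)
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    # member lists per cell
    boundaries = np.searchsorted(sorted_flat, np.arange(np.prod(n_cells) + 1))
    members = [order[boundaries[c]: boundaries[c + 1]] for c in range(int(np.prod(n_cells)))]

    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    pos = system.positions
    out_i, out_j, out_r = [], [], []
    nx, ny, nz = n_cells
    for cx in range(nx):
        for cy in range(ny):
            for cz in range(nz):
                c = (cx * ny + cy) * nz + cz
                mine = members[c]
                if mine.size == 0:
                    continue
                for off in offsets:
                    ox, oy, oz = (np.array([cx, cy, cz]) + off) % n_cells
                    o = (ox * ny + oy) * nz + oz
                    if o < c:
                        continue
                    other = members[o]
                    if other.size == 0:
                        continue
                    if o == c:
                        ii, jj = np.triu_indices(mine.size, k=1)
                        ai, aj = mine[ii], mine[jj]
                    else:
                        ai = np.repeat(mine, other.size)
                        aj = np.tile(other, mine.size)
                    d = pos[ai] - pos[aj]
                    d -= np.round(d / box) * box
                    r = np.linalg.norm(d, axis=1)
                    keep = r < r_c
                    lo = np.minimum(ai[keep], aj[keep])
                    hi = np.maximum(ai[keep], aj[keep])
                    out_i.append(lo)
                    out_j.append(hi)
                    out_r.append(r[keep])
    if not out_i:
        e = np.empty(0, np.int64)
        return e, e.copy(), np.empty(0)
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    r = np.concatenate(out_r)
    # duplicates can arise when the same cell pair is reachable through two
    # wrapped offsets on small grids; keep unique (i, j)
    key = i * system.n_particles + j
    _, uniq = np.unique(key, return_index=True)
    order = np.sort(uniq)
    return i[order], j[order], r[order]


def pairs_within(system: ParticleSystem, r_c: float, prefer_cells: bool = True):
    """Pair set within r_c, using cell lists when they can pay off."""
    if prefer_cells and system.periodic and system.n_particles > 2000:
        return cell_list_pairs(system, r_c)
    return brute_force_pairs(system, r_c)
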