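"""Compiled inner loops for the per-step update.

These kernels are pure accumulation passes — all stochastic draws stay
outside in the engine, so results are deterministic given their inputs.
They exist because the jammed regimes pack hundreds of cells onto piles
of secreted FN, producing 10^5-scale cell–FN pair lists per step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def fn_accumulate(pos, fn_pos, fn_fiber, fn_phi, pair_i, pair_j,
                  R_cell, R_filo, sigma):
    """Per-cell sums over FN elements in the sensing annulus.

    Returns (sensed count, kernel-density gradient x/y before the γ
    scaling, summed radial force strength, fiber orientation sums x/y,
    fiber count). Pairs outside the annulus are skipped.
    """
    n = pos.shape[0]
    cnt = np.zeros(n, dtype=np.int64)
    ghx = np.zeros(n)
    ghy = np.zeros(n)
    mag = np.zeros(n)
    cgx = np.zeros(n)
    cgy = np.zeros(n)
    ncg = np.zeros(n, dtype=np.int64)
    s2 = sigma * sigma
    for k in range(pair_i.size):
        i = pair_i[k]
        j = pair_j[k]
        dx = fn_pos[j, 0] - pos[i, 0]
        dy = fn_pos[j, 1] - pos[i, 1]
        d2 = dx * dx + dy * dy
        d = np.sqrt(d2)
        if d <= R_cell or d > R_filo:
            continue
        cnt[i] += 1
        w = np.exp(-d2 / (2.0 * s2)) / s2
        ghx[i] += dx * w
        ghy[i] += dy * w
        q = 1.0 - d / R_filo
        mag[i] += q * q
        if fn_fiber[j]:
            ncg[i] += 1
            cgx[i] += np.cos(fn_phi[j])
            cgy[i] += np.sin(fn_phi[j])
    return cnt, ghx, ghy, mag, cgx, cgy, ncg


@njit(cache=True)
def contact_repulsion(pos, R_cell, strength):
    """Deterministic pairwise repulsion between overlapping cell bodies.

    For d < 2 R_cell the pair repels along the line of centers with
    magnitude ``strength (1 - d/(2 R_cell))^2`` (overlapping-spheres
    mechanics); returns the per-cell force vectors.
    """
    n = pos.shape[0]
    fx = np.zeros(n)
    fy = np.zeros(n)
    two_r = 2.0 * R_cell
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d = np.sqrt(dx * dx + dy * dy)
            if d == 0.0 or d >= two_r:
                continue
            q = 1.0 - d / two_r
            f = strength * q * q / d
            fx[i] += f * dx
            fy[i] += f * dy
            fx[j] -= f * dx
            fy[j] -= f * dy
    return fx, fy


@njit(cache=True)
def cell_accumulate(pos, R_cell, R_filo):
    """Per-cell sums over neighbouring cells within R_filo (all pairs).

    Returns (neighbour count, density gradient x/y before the γ scaling,
    summed radial force strength before the repulsion-strength scaling).
    Coincident cells (d = 0) are skipped.
    """
    n = pos.shape[0]
    cnt = np.zeros(n, dtype=np.int64)
    gx = np.zeros(n)
    gy = np.zeros(n)
    mag = np.zeros(n)
    s2 = R_cell * R_cell
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            d2 = dx * dx + dy * dy
            d = np.sqrt(d2)
            if d == 0.0 or d > R_filo:
                continue
            cnt[i] += 1
            w = np.exp(-d2 / (2.0 * s2)) / s2
            gx[i] += dx * w
            gy[i] += dy * w
            q = 1.0 - d / R_filo
            mag[i] += q * q
    return cnt, gx, gy, mag


@njit(cache=True)
def remodel_pass(pos, vel, active, theta, fn_pos, fn_fiber, fn_phi,
                 pair_i, pair_j, R_cell, rate, n_cells):
    """Sequential remodeling sweep in ascending cell id (in place).

    Each covered FN element (d ≤ R_cell) is visited by its covering
    active cells from lowest id up: a punctum is converted to a fiber
    along the first cell's heading, each later visit applies one Euler
    step of the reorientation dynamics with step ``rate = dt ln2/T_half``.
    """
    P = pair_i.size
    # counting sort of covered pairs by cell id
    counts = np.zeros(n_cells + 1, dtype=np.int64)
    covered = np.zeros(P, dtype=np.bool_)
    for k in range(P):
        i = pair_i[k]
        if not active[i]:
            continue
        dx = pos[i, 0] - fn_pos[pair_j[k], 0]
        dy = pos[i, 1] - fn_pos[pair_j[k], 1]
        if dx * dx + dy * dy <= R_cell * R_cell:
            covered[k] = True
            counts[i + 1] += 1
    for i in range(n_cells):
        counts[i + 1] += counts[i]
    order = np.empty(counts[n_cells], dtype=np.int64)
    cursor = counts[:-1].copy()
    for k in range(P):
        if covered[k]:
            i = pair_i[k]
            order[cursor[i]] = k
            cursor[i] += 1
    for idx in range(order.size):
        k = order[idx]
        i = pair_i[k]
        j = pair_j[k]
        if fn_fiber[j]:
            phi = fn_phi[j] + rate * np.sin(theta[i] - fn_phi[j])
            phi = (phi + np.pi) % (2.0 * np.pi) - np.pi
            if phi == -np.pi:
                phi = np.pi
            fn_phi[j] = phi
        else:
            fn_fiber[j] = True
            fn_phi[j] = theta[i]
    return order.size
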