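"""Dynamic-programming search for the optimal curve reparameterization.

The elastic matching energy between two SRVFs,

    E[gamma] = \\int_0^1 || q1(t) - sqrt(gamma'(t)) q2(gamma(t)) ||^2 dt,

is minimised over piecewise-linear monotone warps whose breakpoints live on
the sample grid.  Predecessor steps are integer offsets (di, dj) with
1 <= di, dj <= MAX_SLOPE and gcd(di, dj) = 1, bounding the local slope to
[1/MAX_SLOPE, MAX_SLOPE].  The same segment-energy definition is shared by
the exhaustive-path oracle used in the tests.

Kernels are compiled with numba; the module-level helpers are plain numpy.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MAX_SLOPE = 5


def _allowed_steps(max_slope: int = MAX_SLOPE) -> np.ndarray:
    steps = [
        (di, dj)
        for di in range(1, max_slope + 1)
        for dj in range(1, max_slope + 1)
        if math.gcd(di, dj) == 1
    ]
    return np.asarray(steps, dtype=np.int64)


STEPS = _allowed_steps()


@njit(cache=True)
def _segment_energy(q1, q2, i1, j1, i2, j2, dt):
    """Energy of matching grid nodes (i1,j1)->(i2,j2) with linear warp.

    Trapezoid rule over the fine-grid samples i1..i2 of
    ||q1(t_i) - sqrt(m) * q2(j1 + m (i - i1))||^2 with slope m.
    """
    m = (j2 - j1) / (i2 - i1)
    sqm = np.sqrt(m)
    total = 0.0
    for i in range(i1, i2 + 1):
        jj = j1 + m * (i - i1)
        j0 = int(jj)
        if j0 >= q2.shape[0] - 1:
            j0 = q2.shape[0] - 2
        frac = jj - j0
        e = 0.0
        for k in range(3):
            q2v = q2[j0, k] + frac * (q2[j0 + 1, k] - q2[j0, k])
            d = q1[i, k] - sqm * q2v
            e += d * d
        if i == i1 or i == i2:
            e *= 0.5
        total += e
    return total * dt


@njit(cache=True)
def _dp_tables(q1, q2, steps):
    n = q1.shape[0]
    dt = 1.0 / (n - 1)
    big = 1e30
    H = np.full((n, n), big)
    back = np.full((n, n), -1, dtype=np.int64)
    H[0, 0] = 0.0
    for i in range(1, n):
        for j in range(1, n):
            best = big
            bidx = -1
            for s in range(steps.shape[0]):
                di = steps[s, 0]
                dj = steps[s, 1]
                ip = i - di
                jp = j - dj
                if ip < 0 or jp < 0:
                    continue
                h = H[ip, jp]
                if h >= big:
                    continue
                c = h + _segment_energy(q1, q2, ip, jp, i, j, dt)
                if c < best:
                    best = c
                    bidx = s
            H[i, j] = best
            back[i, j] = bidx
    return H, back


def dp_optimal_warp(q1: np.ndarray, q2: np.ndarray):
    """Optimal monotone warp gamma aligning q2 to q1.

    Returns ``(gamma, energy)`` where gamma is sampled on the uniform grid of
    q1 (gamma[0] = 0, gamma[-1] = 1, nondecreasing).
    """
    q1 = np.ascontiguousarray(q1, dtype=np.float64)
    q2 = np.ascontiguousarray(q2, dtype=np.float64)
    if q1.shape != q2.shape:
        raise ValueError("q1 and q2 must share the grid")
    n = q1.shape[0]
    H, back = _dp_tables(q1, q2, STEPS)
    # walk back from (n-1, n-1)
    path = [(n - 1, n - 1)]
    i, j = n - 1, n - 1
    while (i, j) != (0, 0):
        s = back[i, j]
        if s < 0:
            raise RuntimeError("DP table has no path to the corner")
        i, j = i - STEPS[s, 0], j - STEPS[s, 1]
        path.append((i, j))
    path.reverse()
    pi = np.array([p[0] for p in path], dtype=float) / (n - 1)
    pj = np.array([p[1] for p in path], dtype=float) / (n - 1)
    grid = np.linspace(0.0, 1.0, n)
    gamma = np.interp(grid, pi, pj)
    return gamma, float(H[n - 1, n - 1])


def exhaustive_optimal_warp(q1: np.ndarray, q2: np.ndarray):
    """Brute-force enumeration of all monotone lattice paths (tiny grids).

    Shares `_segment_energy` with the DP so the two routes are comparable
    bit-for-bit.  Exponential cost: use only for n <= ~12.
    """
    q1 = np.ascontiguousarray(q1, dtype=np.float64)
    q2 = np.ascontiguousarray(q2, dtype=np.float64)
    n = q1.shape[0]
    dt = 1.0 / (n - 1)
    best = [np.inf, None]

    def recurse(i, j, cost, nodes):
        if cost >= best[0]:
            return
        if i == n - 1 and j == n - 1:
            best[0] = cost
            best[1] = list(nodes)
            return
        for di, dj in STEPS:
            ii, jj = i + di, j + dj
            if ii > n - 1 or jj > n - 1:
                continue
            c = _segment_energy(q1, q2, i, j, ii, jj, dt)
            nodes.append((ii, jj))
            recurse(ii, jj, cost + c, nodes)
            nodes.pop()

    recurse(0, 0, 0.0, [(0, 0)])
    if best[1] is None:
        raise RuntimeError("no admissible path")
    pi = np.array([p[0] for p in best[1]], dtype=float) / (n - 1)
    pj = np.array([p[1] for p in best[1]], dtype=float) / (n - 1)
    grid = np.linspace(0.0, 1.0, n)
    gamma = np.interp(grid, pi, pj)
    return gamma, float(best[0])


def apply_warp(q: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Group action of a warp on an SRVF: (q, gamma) -> (q o gamma) sqrt(gamma')."""
    n = q.shape[0]
    grid = np.linspace(0.0, 1.0, n)
    dgamma = np.gradient(gamma, grid)
    dgamma = np.clip(dgamma, 0.0, None)
    out = np.empty_like(q)
    for k in range(3):
        out[:, k] = np.interp(gamma, grid, q[:, k])
    return out * np.sqrt(dgamma)[:, None]
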