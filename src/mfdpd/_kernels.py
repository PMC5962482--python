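"""Compiled hot loops: pair enumeration and the sequential pairwise sweeps.

numba-jitted when available; the pure-Python fallbacks are identical code
(same arithmetic, same order) so results do not depend on the compiler.
"""

import numpy as np

try:
    from numba import njit as _njit

    def njit(fn):
        return _njit(cache=True, fastmath=False)(fn)
except ImportError:                                   # pragma: no cover
    def njit(fn):
        return fn


@njit
def _pair_fill(cell_order, starts, members, half_nbrs, half_shifts, pos,
               cutoff):
    """Enumerate within-cutoff pairs cell by cell.

    Candidates: all pairs inside one cell plus all pairs between a cell
    and its designated 13 half-set neighbors.  Periodic wrapping is baked
    into ``half_shifts`` (the displacement of each neighbor cell's frame),
    which is the exact minimum image for any pair below the cutoff when
    the grid has >= 3 cells per axis.  Returns (i, j, r, e, n_candidates)
    with i < j and e = (r_i - r_j)/r.
    """
    n_cells = cell_order.shape[0]
    cut2 = cutoff * cutoff
    # exact candidate count for allocation
    n_alloc = 0
    for oc in range(n_cells):
        c = cell_order[oc]
        nc = starts[c + 1] - starts[c]
        n_alloc += nc * (nc - 1) // 2
        for k in range(half_nbrs.shape[1]):
            h = half_nbrs[c, k]
            if h >= 0:
                n_alloc += nc * (starts[h + 1] - starts[h])
    pi = np.empty(n_alloc, np.int64)
    pj = np.empty(n_alloc, np.int64)
    pr = np.empty(n_alloc, np.float64)
    pe = np.empty((n_alloc, 3), np.float64)
    m = 0
    for oc in range(n_cells):
        c = cell_order[oc]
        s0, s1 = starts[c], starts[c + 1]
        for a in range(s0, s1):
            ia = members[a]
            xa, ya, za = pos[ia, 0], pos[ia, 1], pos[ia, 2]
            for b in range(a + 1, s1):
                ib = members[b]
                dx = xa - pos[ib, 0]
                dy = ya - pos[ib, 1]
                dz = za - pos[ib, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cut2:
                    m = _store(pi, pj, pr, pe, m, ia, ib, dx, dy, dz, r2)
        for k in range(half_nbrs.shape[1]):
            h = half_nbrs[c, k]
            if h < 0:
                continue
            sx = half_shifts[c, k, 0]
            sy = half_shifts[c, k, 1]
            sz = half_shifts[c, k, 2]
            t0, t1 = starts[h], starts[h + 1]
            for a in range(s0, s1):
                ia = members[a]
                xa, ya, za = pos[ia, 0] - sx, pos[ia, 1] - sy, pos[ia, 2] - sz
                for b in range(t0, t1):
                    ib = members[b]
                    dx = xa - pos[ib, 0]
                    dy = ya - pos[ib, 1]
                    dz = za - pos[ib, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < cut2:
                        m = _store(pi, pj, pr, pe, m, ia, ib, dx, dy, dz, r2)
    return pi[:m], pj[:m], pr[:m], pe[:m], n_alloc


@njit
def _store(pi, pj, pr, pe, m, ia, ib, dx, dy, dz, r2):
    # canonical i < j; e points from j toward i
    if ia > ib:
        ia, ib = ib, ia
        dx, dy, dz = -dx, -dy, -dz
    r = np.sqrt(r2)
    pi[m] = ia
    pj[m] = ib
    pr[m] = r
    if r > 0.0:
        pe[m, 0] = dx / r
        pe[m, 1] = dy / r
        pe[m, 2] = dz / r
    else:
        # coincident particles: no defined direction, no force
        pe[m, 0] = 0.0
        pe[m, 1] = 0.0
        pe[m, 2] = 0.0
    return m + 1


@njit
def _s1_sweep(pi, pj, pr, pe, v, inv_m, gamma, sigma, dt, zeta):
    """Shardlow S1 fluctuation-dissipation sweep, sequential over pairs.

    Per pair: an explicit half-step of friction + noise followed by an
    implicit half-step solved in closed form for the relative velocity
    projection.  Each update is equal and opposite in momentum, so every
    pair conserves its total momentum exactly.
    """
    sq = np.sqrt(dt)
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        wR = 1.0 - pr[k]
        wD = wR * wR
        ex, ey, ez = pe[k, 0], pe[k, 1], pe[k, 2]
        S = inv_m[a] + inv_m[b]
        noise = 0.5 * sq * sigma * wR * zeta[k]
        # explicit half
        u = ((v[a, 0] - v[b, 0]) * ex + (v[a, 1] - v[b, 1]) * ey
             + (v[a, 2] - v[b, 2]) * ez)
        dp = -0.5 * dt * gamma * wD * u + noise
        v[a, 0] += dp * ex * inv_m[a]
        v[a, 1] += dp * ey * inv_m[a]
        v[a, 2] += dp * ez * inv_m[a]
        v[b, 0] -= dp * ex * inv_m[b]
        v[b, 1] -= dp * ey * inv_m[b]
        v[b, 2] -= dp * ez * inv_m[b]
        # implicit half: u' = (u + noise*S) / (1 + dt/2 * gamma * wD * S)
        u = ((v[a, 0] - v[b, 0]) * ex + (v[a, 1] - v[b, 1]) * ey
             + (v[a, 2] - v[b, 2]) * ez)
        up = (u + noise * S) / (1.0 + 0.5 * dt * gamma * wD * S)
        dp = (up - u) / S
        v[a, 0] += dp * ex * inv_m[a]
        v[a, 1] += dp * ey * inv_m[a]
        v[a, 2] += dp * ez * inv_m[a]
        v[b, 0] -= dp * ex * inv_m[b]
        v[b, 1] -= dp * ey * inv_m[b]
        v[b, 2] -= dp * ez * inv_m[b]


@njit
def _pnhl_sweep(pi, pj, pr, pe, v, inv_m, xi, kBT, dt, zeta):
    """Pairwise Nose-Hoover-Langevin sweep at fixed auxiliary friction xi.

    Implicit full-step friction (coefficient xi, weight wD) plus a pairwise
    random kick whose variance is matched so that the discrete pair map
    leaves the relative-velocity projection with stationary variance
    exactly kBT * (1/m_a + 1/m_b) — the discrete fluctuation-dissipation
    condition.  Sequential over pairs; pair momentum conserved exactly.
    """
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        wR = 1.0 - pr[k]
        wD = wR * wR
        ex, ey, ez = pe[k, 0], pe[k, 1], pe[k, 2]
        S = inv_m[a] + inv_m[b]
        u = ((v[a, 0] - v[b, 0]) * ex + (v[a, 1] - v[b, 1]) * ey
             + (v[a, 2] - v[b, 2]) * ez)
        alpha = dt * xi * wD * S
        # noise variance solving (V + S^2 q^2) / (1 + alpha)^2 = V
        # at the target V = kBT * S
        q = np.sqrt(kBT * alpha * (2.0 + alpha) / S)
        up = (u + S * q * zeta[k]) / (1.0 + alpha)
        dp = (up - u) / S
        v[a, 0] += dp * ex * inv_m[a]
        v[a, 1] += dp * ey * inv_m[a]
        v[a, 2] += dp * ez * inv_m[a]
        v[b, 0] -= dp * ex * inv_m[b]
        v[b, 1] -= dp * ey * inv_m[b]
        v[b, 2] -= dp * ez * inv_m[b]
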