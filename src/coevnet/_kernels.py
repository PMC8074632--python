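"""Numba kernels: steepest-descent routing, topological ordering, unit-rate
accumulation, and the receiver-first implicit reaction sweep.

All kernels work on flat (raveled, C-order) arrays; receivers are flat cell
indices. The routing kernels compute descent and ascent maps in a single pass
(ascent is steepest descent of -h with the absorbing face at the flow start).
"""

import math

import numpy as np
from numba import njit

__all__ = [
    "route_2d",
    "route_3d",
    "topo_order",
    "accumulate_flat",
    "sink_sweep_flat",
]


@njit(cache=True)
def route_2d(h, flow_axis, spacing):
    """D8 receivers for descent and ascent on a 2D raster.

    Returns (recv_d, slope_d, dist_d, recv_a, slope_a, dist_a), flat arrays.
    Cells on the absorbing face (flow end for descent, flow start for ascent)
    and cells without a strictly downhill/uphill neighbour are outlets
    (receiver = self). Ties between equally steep neighbours break to the
    first neighbour in lexicographic offset order.
    """
    n0, n1 = h.shape
    N = n0 * n1
    recv_d = np.empty(N, np.int64)
    slope_d = np.zeros(N, np.float64)
    dist_d = np.full(N, spacing)
    recv_a = np.empty(N, np.int64)
    slope_a = np.zeros(N, np.float64)
    dist_a = np.full(N, spacing)
    for i in range(n0):
        for j in range(n1):
            c = i * n1 + j
            hc = h[i, j]
            bsd = 0.0
            bd = c
            bdd = spacing
            bsa = 0.0
            ba = c
            bda = spacing
            for di in range(-1, 2):
                ii = i + di
                if ii < 0 or ii >= n0:
                    continue
                for dj in range(-1, 2):
                    if di == 0 and dj == 0:
                        continue
                    jj = j + dj
                    if jj < 0 or jj >= n1:
                        continue
                    d = spacing * math.sqrt(float(di * di + dj * dj))
                    s = (hc - h[ii, jj]) / d
                    if s > bsd:
                        bsd = s
                        bd = ii * n1 + jj
                        bdd = d
                    if -s > bsa:
                        bsa = -s
                        ba = ii * n1 + jj
                        bda = d
            if flow_axis == 0:
                fi = i
                nf = n0
            else:
                fi = j
                nf = n1
            slope_d[c] = bsd
            if fi == nf - 1 or bd == c:
                recv_d[c] = c
            else:
                recv_d[c] = bd
                dist_d[c] = bdd
            slope_a[c] = bsa
            if fi == 0 or ba == c:
                recv_a[c] = c
            else:
                recv_a[c] = ba
                dist_a[c] = bda
    return recv_d, slope_d, dist_d, recv_a, slope_a, dist_a


@njit(cache=True)
def route_3d(h, flow_axis, spacing):
    """26-neighbour receivers for descent and ascent on a 3D raster."""
    n0, n1, n2 = h.shape
    N = n0 * n1 * n2
    recv_d = np.empty(N, np.int64)
    slope_d = np.zeros(N, np.float64)
    dist_d = np.full(N, spacing)
    recv_a = np.empty(N, np.int64)
    slope_a = np.zeros(N, np.float64)
    dist_a = np.full(N, spacing)
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                c = (i * n1 + j) * n2 + k
                hc = h[i, j, k]
                bsd = 0.0
                bd = c
                bdd = spacing
                bsa = 0.0
                ba = c
                bda = spacing
                for di in range(-1, 2):
                    ii = i + di
                    if ii < 0 or ii >= n0:
                        continue
                    for dj in range(-1, 2):
                        jj = j + dj
                        if jj < 0 or jj >= n1:
                            continue
                        for dk in range(-1, 2):
                            if di == 0 and dj == 0 and dk == 0:
                                continue
                            kk = k + dk
                            if kk < 0 or kk >= n2:
                                continue
                            d = spacing * math.sqrt(float(di * di + dj * dj + dk * dk))
                            s = (hc - h[ii, jj, kk]) / d
                            if s > bsd:
                                bsd = s
                                bd = (ii * n1 + jj) * n2 + kk
                                bdd = d
                            if -s > bsa:
                                bsa = -s
                                ba = (ii * n1 + jj) * n2 + kk
                                bda = d
                if flow_axis == 0:
                    fi = i
                    nf = n0
                elif flow_axis == 1:
                    fi = j
                    nf = n1
                else:
                    fi = k
                    nf = n2
                slope_d[c] = bsd
                if fi == nf - 1 or bd == c:
                    recv_d[c] = c
                else:
                    recv_d[c] = bd
                    dist_d[c] = bdd
                slope_a[c] = bsa
                if fi == 0 or ba == c:
                    recv_a[c] = c
                else:
                    recv_a[c] = ba
                    dist_a[c] = bda
    return recv_d, slope_d, dist_d, recv_a, slope_a, dist_a


@njit(cache=True)
def mfd_accumulate_2d(g, flow_axis, spacing, absorb_at_end, order, seed_val):
    """Partitioned (multiple-flow-direction) accumulation on a 2D raster.

    Every cell passes its accumulated density to all strictly lower
    neighbours of g, split in proportion to the distance-weighted slope.
    ``order`` must list cells from high to low g, so donors are processed
    before receivers. Cells on the absorbing face retain what they receive
    (their density is the exiting flux); interior pits retain too.
    """
    n0, n1 = g.shape
    N = n0 * n1
    a = np.full(N, seed_val)
    for k in range(N):
        c = order[k]
        i = c // n1
        j = c - i * n1
        if flow_axis == 0:
            fi = i
            nf = n0
        else:
            fi = j
            nf = n1
        if (fi == nf - 1) if absorb_at_end else (fi == 0):
            continue
        wsum = 0.0
        for di in range(-1, 2):
            ii = i + di
            if ii < 0 or ii >= n0:
                continue
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                jj = j + dj
                if jj < 0 or jj >= n1:
                    continue
                d = spacing * math.sqrt(float(di * di + dj * dj))
                s = (g[i, j] - g[ii, jj]) / d
                if s > 0.0:
                    wsum += s
        if wsum <= 0.0:
            continue
        ac = a[c] / wsum
        for di in range(-1, 2):
            ii = i + di
            if ii < 0 or ii >= n0:
                continue
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                jj = j + dj
                if jj < 0 or jj >= n1:
                    continue
                d = spacing * math.sqrt(float(di * di + dj * dj))
                s = (g[i, j] - g[ii, jj]) / d
                if s > 0.0:
                    a[ii * n1 + jj] += ac * s
    return a


@njit(cache=True)
def mfd_accumulate_3d(g, flow_axis, spacing, absorb_at_end, order, seed_val):
    """Partitioned accumulation on a 3D raster (26-neighbour version)."""
    n0, n1, n2 = g.shape
    N = n0 * n1 * n2
    a = np.full(N, seed_val)
    for idx in range(N):
        c = order[idx]
        i = c // (n1 * n2)
        rem = c - i * n1 * n2
        j = rem // n2
        k = rem - j * n2
        if flow_axis == 0:
            fi = i
            nf = n0
        elif flow_axis == 1:
            fi = j
            nf = n1
        else:
            fi = k
            nf = n2
        if (fi == nf - 1) if absorb_at_end else (fi == 0):
            continue
        wsum = 0.0
        for di in range(-1, 2):
            ii = i + di
            if ii < 0 or ii >= n0:
                continue
            for dj in range(-1, 2):
                jj = j + dj
                if jj < 0 or jj >= n1:
                    continue
                for dk in range(-1, 2):
                    if di == 0 and dj == 0 and dk == 0:
                        continue
                    kk = k + dk
                    if kk < 0 or kk >= n2:
                        continue
                    d = spacing * math.sqrt(float(di * di + dj * dj + dk * dk))
                    s = (g[i, j, k] - g[ii, jj, kk]) / d
                    if s > 0.0:
                        wsum += s
        if wsum <= 0.0:
            continue
        ac = a[c] / wsum
        for di in range(-1, 2):
            ii = i + di
            if ii < 0 or ii >= n0:
                continue
            for dj in range(-1, 2):
                jj = j + dj
                if jj < 0 or jj >= n1:
                    continue
                for dk in range(-1, 2):
                    if di == 0 and dj == 0 and dk == 0:
                        continue
                    kk = k + dk
                    if kk < 0 or kk >= n2:
                        continue
                    d = spacing * math.sqrt(float(di * di + dj * dj + dk * dk))
                    s = (g[i, j, k] - g[ii, jj, kk]) / d
                    if s > 0.0:
                        a[(ii * n1 + jj) * n2 + kk] += ac * s
    return a


@njit(cache=True)
def topo_order(recv):
    """Upstream-first (donors before receivers) order by Kahn's algorithm.

    Returns (order, n_sorted); n_sorted < len(recv) signals a cycle in the
    receiver graph, which steepest-descent routing can never produce.
    """
    N = recv.shape[0]
    indeg = np.zeros(N, np.int64)
    for c in range(N):
        r = recv[c]
        if r != c:
            indeg[r] += 1
    order = np.empty(N, np.int64)
    tail = 0
    for c in range(N):
        if indeg[c] == 0:
            order[tail] = c
            tail += 1
    head = 0
    while head < tail:
        c = order[head]
        head += 1
        r = recv[c]
        if r != c:
            indeg[r] -= 1
            if indeg[r] == 0:
                order[tail] = r
                tail += 1
    return order, tail


@njit(cache=True)
def accumulate_flat(recv, order, seed_value):
    """a_i = seed_value * (number of cells whose flow path passes through i)."""
    N = recv.shape[0]
    a = np.full(N, seed_value)
    for k in range(N):
        c = order[k]
        r = recv[c]
        if r != c:
            a[r] += a[c]
    return a


@njit(cache=True)
def sink_sweep_flat(h, recv, dist, a_pow_m, order, fixed, w, n_exp, tol, max_iter):
    """Implicit erosion sweep in receiver-first order, in place.

    Each non-outlet, non-fixed cell solves
        x - h_old + w * a^m * ((x - h_recv)/dist)^n = 0
    with the receiver value already updated (w = dt * K_eff). For n = 1 the
    closed form is used; otherwise a guarded Newton iteration with bisection
    fallback on [h_recv, h_old]. Cells at or below their receiver are left
    unchanged (the slope factor is never negative). Returns the maximum
    Newton iteration count used.
    """
    N = order.shape[0]
    max_it_used = 0
    for k in range(N - 1, -1, -1):
        c = order[k]
        r = recv[c]
        if r == c or fixed[c]:
            continue
        hr = h[r]
        h0 = h[c]
        if h0 <= hr:
            continue
        wa = w * a_pow_m[c]
        dl = dist[c]
        if n_exp == 1.0:
            coef = wa / dl
            h[c] = (h0 + coef * hr) / (1.0 + coef)
        else:
            lo = hr
            hi = h0
            x = h0
            scale = max(1.0, abs(h0))
            it = 0
            while it < max_iter:
                t = (x - hr) / dl
                fx = x - h0 + wa * t ** n_exp
                if abs(fx) < tol * scale:
                    break
                if fx > 0.0:
                    hi = x
                else:
                    lo = x
                dfx = 1.0
                if t > 0.0:
                    dfx = 1.0 + wa * n_exp * t ** (n_exp - 1.0) / dl
                xn = x - fx / dfx
                if not np.isfinite(xn) or xn <= lo or xn >= hi:
                    xn = 0.5 * (lo + hi)
                if xn == x:
                    break
                x = xn
                it += 1
            if it > max_it_used:
                max_it_used = it
            h[c] = x
    return max_it_used
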