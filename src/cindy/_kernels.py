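"""Numba kernels for recursive adaptive partitioning of rank space.

The kernels operate on integer rank vectors (permutations of 1..n) and return
the leaf cells of the partition as flat arrays; the public wrappers in
:mod:`cindy.ap` turn those into estimates and partition objects.  Cells are
half-open boxes ``[lo, hi)`` in rank coordinates; the root is ``[1, n+1)`` per
dimension.  A cell is subdivided at its per-dimension interval midpoint (the
median of the rank distribution restricted to the cell, since rank marginals
are uniform) whenever a chi-square test rejects uniformity of the prospective
2^d sub-cell counts and the cell holds at least ``min_cell`` points.
"""

import numpy as np
from numba import njit


@njit(cache=True, nogil=True)
def ap_cells_2d(x, y, crit, min_cell, cap):
    """Leaf cells of the 2-D adaptive partition.

    Returns ``(out, m)`` where ``out[:m]`` has columns
    ``lox, hix, loy, hiy, count``.  ``m == -1`` signals capacity overflow.
    """
    n = x.shape[0]
    idx = np.arange(n)
    tmp = np.empty(n, np.int64)
    st = np.empty((cap, 6), np.int64)
    out = np.empty((cap, 5), np.int64)
    st[0, 0] = 0
    st[0, 1] = n
    st[0, 2] = 1
    st[0, 3] = n + 1
    st[0, 4] = 1
    st[0, 5] = n + 1
    top = 1
    m = 0
    counts = np.empty(4, np.int64)
    while top > 0:
        top -= 1
        s = st[top, 0]
        e = st[top, 1]
        lox = st[top, 2]
        hix = st[top, 3]
        loy = st[top, 4]
        hiy = st[top, 5]
        cnt = e - s
        split = False
        vx = (lox + hix) // 2
        vy = (loy + hiy) // 2
        if cnt >= min_cell and hix - lox > 1 and hiy - loy > 1:
            counts[:] = 0
            for i in range(s, e):
                j = idx[i]
                q = 0
                if x[j] >= vx:
                    q += 2
                if y[j] >= vy:
                    q += 1
                counts[q] += 1
            exp = cnt / 4.0
            stat = 0.0
            for q in range(4):
                d = counts[q] - exp
                stat += d * d / exp
            if stat > crit:
                split = True
        if split:
            # counting-sort the segment by quadrant (stable)
            off = np.empty(4, np.int64)
            off[0] = s
            for q in range(1, 4):
                off[q] = off[q - 1] + counts[q - 1]
            pos = off.copy()
            for i in range(s, e):
                j = idx[i]
                q = 0
                if x[j] >= vx:
                    q += 2
                if y[j] >= vy:
                    q += 1
                tmp[pos[q]] = j
                pos[q] += 1
            for i in range(s, e):
                idx[i] = tmp[i]
            if top + 4 > cap:
                return out, -1
            for q in range(4):
                st[top, 0] = off[q]
                st[top, 1] = off[q] + counts[q]
                if q >= 2:
                    st[top, 2] = vx
                    st[top, 3] = hix
                else:
                    st[top, 2] = lox
                    st[top, 3] = vx
                if q % 2 == 1:
                    st[top, 4] = vy
                    st[top, 5] = hiy
                else:
                    st[top, 4] = loy
                    st[top, 5] = vy
                top += 1
        else:
            if m >= cap:
                return out, -1
            out[m, 0] = lox
            out[m, 1] = hix
            out[m, 2] = loy
            out[m, 3] = hiy
            out[m, 4] = cnt
            m += 1
    return out, m


@njit(cache=True, nogil=True)
def ap_cells_3d(x, y, z, crit, min_cell, cap):
    """Leaf cells of the 3-D adaptive partition.

    Returns ``(out, nxz, nyz, m)``; ``out[:m]`` has columns
    ``lox, hix, loy, hiy, loz, hiz, count``.  ``nxz[c]``/``nyz[c]`` count the
    points of the whole sample falling in the cell's (x,z)/(y,z) projected
    rectangle (the 2-D marginal counts of the plug-in CMI).  ``m == -1``
    signals capacity overflow.
    """
    n = x.shape[0]
    idx = np.arange(n)
    tmp = np.empty(n, np.int64)
    st = np.empty((cap, 8), np.int64)
    out = np.empty((cap, 7), np.int64)
    st[0, 0] = 0
    st[0, 1] = n
    st[0, 2] = 1
    st[0, 3] = n + 1
    st[0, 4] = 1
    st[0, 5] = n + 1
    st[0, 6] = 1
    st[0, 7] = n + 1
    top = 1
    m = 0
    counts = np.empty(8, np.int64)
    while top > 0:
        top -= 1
        s = st[top, 0]
        e = st[top, 1]
        lox = st[top, 2]
        hix = st[top, 3]
        loy = st[top, 4]
        hiy = st[top, 5]
        loz = st[top, 6]
        hiz = st[top, 7]
        cnt = e - s
        split = False
        vx = (lox + hix) // 2
        vy = (loy + hiy) // 2
        vz = (loz + hiz) // 2
        if cnt >= min_cell and hix - lox > 1 and hiy - loy > 1 and hiz - loz > 1:
            counts[:] = 0
            for i in range(s, e):
                j = idx[i]
                q = 0
                if x[j] >= vx:
                    q += 4
                if y[j] >= vy:
                    q += 2
                if z[j] >= vz:
                    q += 1
                counts[q] += 1
            exp = cnt / 8.0
            stat = 0.0
            for q in range(8):
                d = counts[q] - exp
                stat += d * d / exp
            if stat > crit:
                split = True
        if split:
            off = np.empty(8, np.int64)
            off[0] = s
            for q in range(1, 8):
                off[q] = off[q - 1] + counts[q - 1]
            pos = off.copy()
            for i in range(s, e):
                j = idx[i]
                q = 0
                if x[j] >= vx:
                    q += 4
                if y[j] >= vy:
                    q += 2
                if z[j] >= vz:
                    q += 1
                tmp[pos[q]] = j
                pos[q] += 1
            for i in range(s, e):
                idx[i] = tmp[i]
            if top + 8 > cap:
                return out, np.empty(0, np.int64), np.empty(0, np.int64), -1
            for q in range(8):
                st[top, 0] = off[q]
                st[top, 1] = off[q] + counts[q]
                if q >= 4:
                    st[top, 2] = vx
                    st[top, 3] = hix
                else:
                    st[top, 2] = lox
                    st[top, 3] = vx
                if (q // 2) % 2 == 1:
                    st[top, 4] = vy
                    st[top, 5] = hiy
                else:
                    st[top, 4] = loy
                    st[top, 5] = vy
                if q % 2 == 1:
                    st[top, 6] = vz
                    st[top, 7] = hiz
                else:
                    st[top, 6] = loz
                    st[top, 7] = vz
                top += 1
        else:
            if m >= cap:
                return out, np.empty(0, np.int64), np.empty(0, np.int64), -1
            out[m, 0] = lox
            out[m, 1] = hix
            out[m, 2] = loy
            out[m, 3] = hiy
            out[m, 4] = loz
            out[m, 5] = hiz
            out[m, 6] = cnt
            m += 1
    nxz = np.zeros(m, np.int64)
    nyz = np.zeros(m, np.int64)
    for c in range(m):
        lox = out[c, 0]
        hix = out[c, 1]
        loy = out[c, 2]
        hiy = out[c, 3]
        loz = out[c, 4]
        hiz = out[c, 5]
        a = 0
        b = 0
        for i in range(n):
            if loz <= z[i] < hiz:
                if lox <= x[i] < hix:
                    a += 1
                if loy <= y[i] < hiy:
                    b += 1
        nxz[c] = a
        nyz[c] = b
    return out, nxz, nyz, m

@njit(cache=True, nogil=True)
def mi_null_2d(n, crit, min_cell, n_perm, seed, cap):
    """MI estimates between a fixed rank vector and ``n_perm`` shuffled ones.

    Under rank permutation this samples the null MI distribution for
    independent profiles of length ``n``, which depends only on ``n`` and the
    partition settings.  Seeded Fisher-Yates shuffles make the draw
    reproducible.
    """
    np.random.seed(seed)
    x = np.arange(1, n + 1)
    y = np.arange(1, n + 1)
    res = np.empty(n_perm, np.float64)
    for t in range(n_perm):
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            v = y[i]
            y[i] = y[j]
            y[j] = v
        out, m = ap_cells_2d(x, y, crit, min_cell, cap)
        total = 0.0
        if m > 0:
            for c in range(m):
                cnt = out[c, 4]
                if cnt == 0:
                    continue
                wx = out[c, 1] - out[c, 0]
                wy = out[c, 3] - out[c, 2]
                total += (cnt / n) * np.log((cnt * n) / (wx * wy))
        if total < 0.0:
            total = 0.0
        res[t] = total
    return res
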