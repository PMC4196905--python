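"""Independent brute-force reference implementation of the adaptive partition.

Written without reference to the production kernels: a direct recursive
translation of the algorithm definition, using plain Python lists and floats.
Used by the oracle-equivalence tests, which require bit-for-bit agreement of
cell structure and MI/CMI values on small inputs.
"""

import math

from scipy.stats import chi2


def _subdivide(counts, crit):
    total = sum(counts)
    if total == 0:
        return False
    k = len(counts)
    e = total / k
    stat = sum((c - e) ** 2 for c in counts) / e
    return stat > crit


def brute_partition_2d(x, y, alpha=0.01, min_cell=4):
    """Leaf cells [(lox, hix, loy, hiy, count)] sorted by (lox, loy)."""
    n = len(x)
    crit = float(chi2.isf(alpha, 3))
    leaves = []

    def recurse(pts, lox, hix, loy, hiy):
        cnt = len(pts)
        vx, vy = (lox + hix) // 2, (loy + hiy) // 2
        split = False
        if cnt >= min_cell and hix - lox > 1 and hiy - loy > 1:
            quads = [[], [], [], []]
            for (px, py) in pts:
                q = (2 if px >= vx else 0) + (1 if py >= vy else 0)
                quads[q].append((px, py))
            if _subdivide([len(q) for q in quads], crit):
                split = True
        if not split:
            leaves.append((lox, hix, loy, hiy, cnt))
            return
        recurse(quads[0], lox, vx, loy, vy)
        recurse(quads[1], lox, vx, vy, hiy)
        recurse(quads[2], vx, hix, loy, vy)
        recurse(quads[3], vx, hix, vy, hiy)

    recurse(list(zip(x, y)), 1, n + 1, 1, n + 1)
    return sorted(leaves, key=lambda c: (c[0], c[2]))


def brute_mi(x, y, alpha=0.01, min_cell=4):
    n = len(x)
    total = 0.0
    for (lox, hix, loy, hiy, cnt) in brute_partition_2d(x, y, alpha, min_cell):
        if cnt == 0:
            continue
        wx = hix - lox
        wy = hiy - loy
        total += (cnt / n) * math.log((cnt * n) / (wx * wy))
    return max(total, 0.0)


def brute_partition_3d(x, y, z, alpha=0.01, min_cell=8):
    """Leaf cells [(lox,hix,loy,hiy,loz,hiz,count,nxz,nyz)] sorted by lo bounds."""
    n = len(x)
    crit = float(chi2.isf(alpha, 7))
    leaves = []

    def recurse(pts, lox, hix, loy, hiy, loz, hiz):
        cnt = len(pts)
        vx, vy, vz = (lox + hix) // 2, (loy + hiy) // 2, (loz + hiz) // 2
        split = False
        if cnt >= min_cell and hix - lox > 1 and hiy - loy > 1 and hiz - loz > 1:
            octs = [[] for _ in range(8)]
            for (px, py, pz) in pts:
                q = (4 if px >= vx else 0) + (2 if py >= vy else 0) + (1 if pz >= vz else 0)
                octs[q].append((px, py, pz))
            if _subdivide([len(o) for o in octs], crit):
                split = True
        if not split:
            leaves.append((lox, hix, loy, hiy, loz, hiz, cnt))
            return
        bounds = [
            (lox, vx, loy, vy, loz, vz), (lox, vx, loy, vy, vz, hiz),
            (lox, vx, vy, hiy, loz, vz), (lox, vx, vy, hiy, vz, hiz),
            (vx, hix, loy, vy, loz, vz), (vx, hix, loy, vy, vz, hiz),
            (vx, hix, vy, hiy, loz, vz), (vx, hix, vy, hiy, vz, hiz),
        ]
        for q in range(8):
            recurse(octs[q], *bounds[q])

    recurse(list(zip(x, y, z)), 1, n + 1, 1, n + 1, 1, n + 1)
    leaves.sort(key=lambda c: (c[0], c[2], c[4]))
    out = []
    for (lox, hix, loy, hiy, loz, hiz, cnt) in leaves:
        nxz = sum(1 for i in range(n) if loz <= z[i] < hiz and lox <= x[i] < hix)
        nyz = sum(1 for i in range(n) if loz <= z[i] < hiz and loy <= y[i] < hiy)
        out.append((lox, hix, loy, hiy, loz, hiz, cnt, nxz, nyz))
    return out


def brute_cmi(x, y, z, alpha=0.01, min_cell=8):
    n = len(x)
    total = 0.0
    for (lox, hix, loy, hiy, loz, hiz, cnt, nxz, nyz) in brute_partition_3d(
        x, y, z, alpha, min_cell
    ):
        if cnt == 0:
            continue
        wz = hiz - loz
        total += (cnt / n) * math.log((cnt * wz) / (nxz * nyz))
    return max(total, 0.0)
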