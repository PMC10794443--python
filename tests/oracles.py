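"""Independent brute-force oracles used to validate the package.

Nothing here imports the implementation under test: persistence is
computed by exhaustive simplex enumeration and textbook column reduction
of the full boundary matrix; the spike measures by naive O(n^2)
matching and dense numerical integration of the dissimilarity profile.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# persistence: exhaustive simplexwise reduction (dims 0 and 1)


def brute_force_diagrams(M: np.ndarray, eps_max: float = np.inf):
    """(dim0 bars, dim1 bars) of the Rips filtration up to 2-simplices.

    Enumerates every vertex, edge and triangle, sorts them into a
    simplexwise filtration and reduces the full boundary matrix over
    GF(2) with plain column additions.  Zero-length bars are dropped;
    essential classes get death = inf.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    simplices = []  # (value, dim, vertex tuple)
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for i in range(n):
        for j in range(i + 1, n):
            if M[i, j] <= eps_max:
                simplices.append((float(M[i, j]), 1, (i, j)))
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                val = max(M[i, j], M[i, k], M[j, k])
                if val <= eps_max:
                    simplices.append((float(val), 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: idx for idx, s in enumerate(simplices)}

    columns: dict[int, set[int]] = {}
    for idx, (_val, dim, verts) in enumerate(simplices):
        if dim == 0:
            columns[idx] = set()
        else:
            faces = [tuple(v for h, v in enumerate(verts) if h != drop)
                     for drop in range(len(verts))]
            columns[idx] = {index_of[f] for f in faces}

    low_to_col: dict[int, int] = {}
    pair_of: dict[int, int] = {}
    for idx in range(len(simplices)):
        col = columns[idx]
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col = col ^ columns[low_to_col[low]]
        columns[idx] = col
        if col:
            low = max(col)
            low_to_col[low] = idx
            pair_of[low] = idx

    bars0, bars1 = [], []
    paired_as_death = set(pair_of.values())
    for idx, (val, dim, _verts) in enumerate(simplices):
        if dim == 2 or idx in paired_as_death:
            continue
        if idx in pair_of:
            death = simplices[pair_of[idx]][0]
        else:
            death = math.inf
        if death > val:
            (bars0 if dim == 0 else bars1).append((val, death))
    bars0.sort()
    bars1.sort()
    return bars0, bars1


def betti_numbers_at(M: np.ndarray, eps: float) -> tuple[int, int]:
    """(beta0, beta1) of the Rips complex at a fixed threshold, from ranks.

    beta0 from connected components; beta1 = #edges - #vertices + beta0
    - rank of the triangle boundary matrix over GF(2) (Gaussian
    elimination).  Independent of any persistence pairing.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if M[i, j] <= eps]
    # components by repeated flood fill
    adj = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen, beta0 = set(), 0
    for s in range(n):
        if s in seen:
            continue
        beta0 += 1
        stack = [s]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x])
    edge_idx = {e: k for k, e in enumerate(edges)}
    tris = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if max(M[i, j], M[i, k], M[j, k]) <= eps:
                    tris.append((i, j, k))
    rows = []
    for (i, j, k) in tris:
        mask = 0
        for e in ((i, j), (i, k), (j, k)):
            mask |= 1 << edge_idx[e]
        rows.append(mask)
    rank = 0
    pivots: list[int] = []
    for mask in rows:
        for pv in pivots:
            if mask & (1 << (pv.bit_length() - 1)):
                mask ^= pv
        if mask:
            pivots.append(mask)
            pivots.sort(key=lambda m: -m.bit_length())
            rank += 1
    beta1 = len(edges) - n + beta0 - rank
    return beta0, beta1


# ---------------------------------------------------------------------------
# SPIKE measures


def brute_sync_fraction(a, b, t_start, t_end) -> float:
    """O(n^2) SPIKE-synchronization: every spike checked against every
    spike of the other train for its nearest partner and adaptive window."""
    a = list(map(float, a))
    b = list(map(float, b))

    def matched(x, other, i):
        best = min(range(len(other)), key=lambda j: abs(other[j] - x[i]))
        isis = []
        if i > 0:
            isis.append(x[i] - x[i - 1])
        if i + 1 < len(x):
            isis.append(x[i + 1] - x[i])
        if best > 0:
            isis.append(other[best] - other[best - 1])
        if best + 1 < len(other):
            isis.append(other[best + 1] - other[best])
        tau = 0.5 * min(isis) if isis else 0.5 * (t_end - t_start)
        d = abs(other[best] - x[i])
        return d < tau or d == 0.0

    total = sum(matched(a, b, i) for i in range(len(a)))
    total += sum(matched(b, a, i) for i in range(len(b)))
    return total / (len(a) + len(b))


def dense_spike_distance(a, b, t_start, t_end, n_points=200_001) -> float:
    """Midpoint-rule integration of the dissimilarity profile on a dense
    uniform grid; pointwise evaluation is written directly from the
    definition (previous/following spikes, nearest partners)."""
    def aug(tr):
        tr = list(map(float, tr))
        if not tr or tr[0] > t_start:
            tr = [t_start] + tr
        if tr[-1] < t_end:
            tr = tr + [t_end]
        return np.array(tr)

    A, B = aug(a), aug(b)
    ts = np.linspace(t_start, t_end, n_points)
    mid = 0.5 * (ts[:-1] + ts[1:])

    def s_of(tr, other, t):
        iP = np.searchsorted(tr, t, side="right") - 1
        tP, tF = tr[iP], tr[iP + 1]
        dP = np.abs(other - tP).min()
        dF = np.abs(other - tF).min()
        isi = tF - tP
        return (dP * (tF - t) + dF * (t - tP)) / isi, isi

    vals = np.empty(mid.size)
    for k, t in enumerate(mid):
        s1, i1 = s_of(A, B, t)
        s2, i2 = s_of(B, A, t)
        m = 0.5 * (i1 + i2)
        vals[k] = (s1 * i2 + s2 * i1) / (2.0 * m * m)
    return float(vals.mean())
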