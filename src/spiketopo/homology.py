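"""Vietoris-Rips persistent homology of a dissimilarity matrix.

The filtration sweeps a threshold eps from 0 to 1 (the full range of the
normalized dissimilarities): a simplex enters when all its pairwise
weights are <= eps (closed convention); Betti curves use the half-open
[birth, death) convention, so boundary choices never affect integrals.

Dimension 0 comes from the minimum spanning tree: the finite deaths of
the n-1 merge events are exactly the MST edge weights (elder rule), plus
one essential bar for the component that survives the whole filtration.
Dimension 1 is computed by standard GF(2) boundary-matrix reduction of
the triangle columns over the edge basis, with columns stored as Python
integer bitmasks (one bit per edge, pivot = highest set bit).  Only
simplices up to dimension 2 are needed for beta_0 and beta_1.

Four scalar summaries of the Betti curves are extracted per diagram
pair, computed exactly from the bars (no sampling grid):

* f1 - the turning point of the Betti-0 curve (the threshold at which it
  first decreases, i.e. the smallest pairwise dissimilarity);
* f2 - the area under the Betti-0 curve on [0, eps_max];
* f3 - the global maximum of the Betti-1 curve;
* f4 - the area under the Betti-1 curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "PersistenceDiagram",
    "BettiCurve",
    "TopoFeatures",
    "vr_h0",
    "vr_h1",
    "vr_diagrams",
    "betti_curve",
    "extract_features",
    "features_from_matrix",
]


@dataclass
class PersistenceDiagram:
    """Birth-death bars of one homology dimension (death may be +inf)."""

    dim: int
    births: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        if self.births.shape != self.deaths.shape:
            raise ValueError("births and deaths must align")
        if np.any(self.deaths < self.births):
            raise ValueError("bars must satisfy birth <= death")

    @property
    def n_bars(self) -> int:
        return int(self.births.size)

    def bars(self) -> list[tuple[float, float]]:
        return list(zip(self.births.tolist(), self.deaths.tolist()))


@dataclass
class BettiCurve:
    """Betti number as a step function sampled on a threshold grid."""

    grid: np.ndarray
    beta: np.ndarray
    dim: int


@dataclass(frozen=True)
class TopoFeatures:
    f1: float
    f2: float
    f3: int
    f4: float
    measure: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"f1": self.f1, "f2": self.f2, "f3": float(self.f3), "f4": self.f4}


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n == 0:
        raise ValueError("need a non-empty square matrix")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if D.min() < 0:
        raise ValueError("weights must be non-negative")
    return D


def _as_array(D) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return _check_matrix(D.M)
    return _check_matrix(D)


def vr_h0(D) -> PersistenceDiagram:
    """Dimension-0 diagram: all bars born at 0, finite deaths = MST edges.

    Kruskal sweep over the weight-sorted edges: each component merge is
    one death (elder rule), and the surviving component is the single
    essential bar.
    """
    M = _as_array(D)
    n = M.shape[0]
    if n == 1:
        return PersistenceDiagram(dim=0, births=np.zeros(1),
                                  deaths=np.array([np.inf]))
    iu, ju = np.triu_indices(n, k=1)
    w = M[iu, ju]
    order = np.argsort(w, kind="stable")
    uf = _UnionFind(n)
    deaths = []
    for k in order:
        if uf.union(int(iu[k]), int(ju[k])):
            deaths.append(float(w[k]))
            if len(deaths) == n - 1:
                break
    return PersistenceDiagram(dim=0, births=np.zeros(n),
                              deaths=np.array(sorted(deaths) + [np.inf]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def vr_h1(D, eps_max: float = 1.0) -> PersistenceDiagram:
    """Dimension-1 diagram of the Rips filtration truncated at ``eps_max``.

    Bars still alive at ``eps_max`` are reported with death = +inf
    (downstream features cap them at ``eps_max``).
    """
    M = _as_array(D)
    n = M.shape[0]
    if n < 3:
        return PersistenceDiagram(dim=1, births=np.empty(0), deaths=np.empty(0))

    iu, ju = np.triu_indices(n, k=1)
    w = M[iu, ju]
    keep = w <= eps_max
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))          # by weight, ties by vertex pair
    iu, ju, w = iu[order], ju[order], w[order]
    n_edges = w.size
    edge_index = {}                          # (i, j) -> position in filtration order
    for k in range(n_edges):
        edge_index[(int(iu[k]), int(ju[k]))] = k

    # positive edges create cycles (candidate H1 births)
    uf = _UnionFind(n)
    positive = np.zeros(n_edges, dtype=bool)
    for k in range(n_edges):
        if not uf.union(int(iu[k]), int(ju[k])):
            positive[k] = True

    # triangles, filtered by their maximum edge weight
    tri: list[tuple[float, int, int, int]] = []
    for a in range(n):
        for b in range(a + 1, n):
            wab = M[a, b]
            if wab > eps_max:
                continue
            row_a, row_b = M[a], M[b]
            for c in range(b + 1, n):
                val = max(wab, row_a[c], row_b[c])
                if val <= eps_max:
                    tri.append((val, a, b, c))
    tri.sort()

    pivot_of: dict[int, int] = {}            # edge position -> reduced column
    pivot_val: dict[int, float] = {}         # edge position -> triangle value
    columns: dict[int, int] = {}
    births, deaths = [], []
    for val, a, b, c in tri:
        col = (1 << edge_index[(a, b)]) | (1 << edge_index[(a, c)]) \
            | (1 << edge_index[(b, c)])
        while col:
            low = col.bit_length() - 1
            if low not in pivot_of:
                break
            col ^= columns[pivot_of[low]]
        if col:
            low = col.bit_length() - 1
            key = len(columns)
            columns[key] = col
            pivot_of[low] = key
            pivot_val[low] = val

    for k in np.flatnonzero(positive):
        birth = float(w[k])
        death = pivot_val.get(int(k), np.inf)
        if death > birth:                    # drop zero-length bars
            births.append(birth)
            deaths.append(death)
    order2 = np.lexsort((deaths, births)) if births else []
    return PersistenceDiagram(dim=1, births=np.asarray(births, dtype=float)[order2],
                              deaths=np.asarray(deaths, dtype=float)[order2])


def vr_diagrams(D, eps_max: float = 1.0) -> tuple[PersistenceDiagram, PersistenceDiagram]:
    """Both diagrams of the truncated Rips filtration."""
    return vr_h0(D), vr_h1(D, eps_max=eps_max)


def betti_curve(diag: PersistenceDiagram, grid) -> BettiCurve:
    """beta(eps) = #{bars : birth <= eps < death} on an increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    born = np.searchsorted(np.sort(diag.births), grid, side="right")
    dead = np.searchsorted(np.sort(diag.deaths), grid, side="right")
    return BettiCurve(grid=grid, beta=(born - dead).astype(np.int64), dim=diag.dim)


def _bar_area(diag: PersistenceDiagram, eps_max: float) -> float:
    """Exact integral of the Betti curve over [0, eps_max] from the bars."""
    births = np.clip(diag.births, 0.0, eps_max)
    deaths = np.clip(diag.deaths, 0.0, eps_max)
    return float(np.sum(deaths - births))


def _max_betti(diag: PersistenceDiagram) -> int:
    """Global maximum of the Betti curve, by sweeping bar endpoints."""
    if diag.n_bars == 0:
        return 0
    events = sorted([(b, 1) for b in diag.births]
                    + [(d, -1) for d in diag.deaths if np.isfinite(d)])
    best = cur = 0
    # deaths sort before births at equal value ((-1) < 1): half-open bars
    for _, delta in events:
        cur += delta
        best = max(best, cur)
    return best


def extract_features(diag0: PersistenceDiagram, diag1: PersistenceDiagram,
                     eps_max: float = 1.0, measure: str = "") -> TopoFeatures:
    """The four Betti-curve features, computed exactly from the diagrams."""
    finite0 = diag0.deaths[np.isfinite(diag0.deaths)]
    f1 = float(finite0.min()) if finite0.size else float(eps_max)
    f2 = _bar_area(diag0, eps_max)
    f3 = _max_betti(diag1)
    f4 = _bar_area(diag1, eps_max)
    return TopoFeatures(f1=f1, f2=f2, f3=f3, f4=f4, measure=measure)


def features_from_matrix(D, eps_max: float = 1.0) -> TopoFeatures:
    """Convenience: dissimilarity matrix -> the four features."""
    d0, d1 = vr_diagrams(D, eps_max=eps_max)
    measure = D.measure if isinstance(D, DissimilarityMatrix) else ""
    return extract_features(d0, d1, eps_max=eps_max, measure=measure)


# ---------------------------------------------------------------------------
# text round trips


def save_diagrams(path: str | Path, *diagrams: PersistenceDiagram) -> None:
    lines = ["dim,birth,death"]
    for d in diagrams:
        for b, de in d.bars():
            lines.append(f"{d.dim},{b:.17g},{'inf' if np.isinf(de) else f'{de:.17g}'}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_diagrams(path: str | Path) -> dict[int, PersistenceDiagram]:
    by_dim: dict[int, list[tuple[float, float]]] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        d, b, de = line.split(",")
        by_dim.setdefault(int(d), []).append((float(b), float(de)))
    return {dim: PersistenceDiagram(
        dim=dim,
        births=np.array([b for b, _ in bars]),
        deaths=np.array([d for _, d in bars]))
        for dim, bars in by_dim.items()}
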