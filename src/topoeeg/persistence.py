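"""Vietoris-Rips persistent homology (dimensions 0 and 1) from scratch.

The filtration ``VR(X, eps_1) subset ... subset VR(X, eps_M)`` adds a
simplex at the scale equal to its diameter (the largest pairwise distance
among its vertices); two points are joined at the scale equal to their
distance, matching the circles-of-radius-eps/2 picture.

Dimension 0 is computed by union-find over distance-sorted edges: every
point is born at 0 and dies when its component merges into an older one, so
the finite death multiset equals the minimum-spanning-tree edge weights and
one bar lives forever.  Dimension 1 uses the standard persistence pairing:
the boundary matrix of the triangles (columns over Z/2 in the edge basis,
simplices ordered by filtration value, then dimension, then lexicographic
vertex tuple) is column-reduced; a triangle whose reduced column has pivot
edge *e* kills the 1-cycle born at *e*, and cycle-creating edges left
unpaired at ``eps_max`` yield infinite bars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .cloud import FiltrationConfig, PointCloud

__all__ = [
    "PersistenceInterval",
    "Barcode",
    "vr_persistence",
    "betti_numbers",
    "betti_curve",
    "save_barcode",
    "load_barcode",
]


@dataclass(frozen=True)
class PersistenceInterval:
    """One bar: a homology class alive on ``[birth, death)``."""

    dim: int
    birth: float
    death: float  # math.inf for classes alive at eps_max

    def __post_init__(self) -> None:
        if self.dim not in (0, 1):
            raise ValueError("only dimensions 0 and 1 are supported")
        if not self.birth < self.death:
            raise ValueError(f"interval requires birth < death, got [{self.birth}, {self.death})")
        if self.dim == 0 and self.birth != 0.0:
            raise ValueError("dim-0 intervals are born at 0")

    @property
    def finite(self) -> bool:
        return math.isfinite(self.death)


@dataclass
class Barcode:
    """Multiset of persistence intervals for one cloud.

    ``n_points`` counts distinct points; there are exactly ``n_points``
    dim-0 intervals, and exactly one of them is infinite whenever
    ``eps_max`` reaches the cloud diameter.
    """

    intervals: list[PersistenceInterval]
    eps_max: float
    n_points: int

    def by_dim(self, dim: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.dim == dim]


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Drop exact duplicate points (first occurrence kept, order preserved)."""
    _, idx = np.unique(points, axis=0, return_index=True)
    if len(idx) < len(points):
        warnings.warn(
            f"merged {len(points) - len(idx)} duplicate point(s) before the "
            "Rips filtration",
            stacklevel=3,
        )
        return points[np.sort(idx)]
    return points


def vr_persistence(cloud: PointCloud, config: Optional[FiltrationConfig] = None) -> Barcode:
    """Compute the dim-0/1 barcode of the Rips filtration of ``cloud``."""
    if config is None:
        config = FiltrationConfig(n_folds=cloud.n_folds)
    points = _dedupe(cloud.points)
    n = len(points)
    if n == 0:
        raise ValueError("cannot compute persistence of an empty cloud")
    if n == 1:
        eps_max = config.eps_max_rule if isinstance(config.eps_max_rule, (int, float)) else 0.0
        return Barcode([PersistenceInterval(0, 0.0, math.inf)], float(eps_max), 1)

    diff = points[:, None, :] - points[None, :, :]
    dmat = np.sqrt((diff * diff).sum(axis=2))
    max_pairwise = float(dmat.max())
    if isinstance(config.eps_max_rule, (int, float)):
        eps_max = float(config.eps_max_rule)
    else:
        eps_max = max_pairwise

    # Edges sorted by (weight, lexicographic vertex pair) = filtration order.
    iu, ju = np.triu_indices(n, k=1)
    w = dmat[iu, ju]
    keep = w <= eps_max
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    iu, ju, w = iu[order], ju[order], w[order]

    intervals: list[PersistenceInterval] = []
    uf = _UnionFind(n)
    cycle_edges: list[int] = []  # positions (in sorted edge order) of cycle creators
    for pos in range(len(w)):
        if uf.union(int(iu[pos]), int(ju[pos])):
            if w[pos] > 0:
                intervals.append(PersistenceInterval(0, 0.0, float(w[pos])))
        else:
            cycle_edges.append(pos)
    n_components = len({uf.find(i) for i in range(n)})
    intervals.extend(PersistenceInterval(0, 0.0, math.inf) for _ in range(n_components))

    if config.max_homology_dim >= 1:
        intervals.extend(
            _h1_intervals(dmat, iu, ju, w, cycle_edges, eps_max)
        )

    intervals.sort(key=lambda iv: (iv.dim, iv.birth, iv.death))
    return Barcode(intervals, eps_max, n)


def _h1_intervals(dmat, iu, ju, w, cycle_edges, eps_max):
    """Pair triangles against cycle-creating edges by column reduction.

    Columns live in the edge basis (bit *e* = e-th edge in filtration
    order) and are reduced in triangle filtration order; reducing the
    triangle block alone yields exactly the (edge, triangle) persistence
    pairs of the full boundary matrix.
    """
    n = dmat.shape[0]
    edge_index: dict[tuple[int, int], int] = {}
    for pos in range(len(w)):
        edge_index[(int(iu[pos]), int(ju[pos]))] = pos

    tris: list[tuple[float, int, int, int]] = []
    for i, j, k in combinations(range(n), 3):
        diam = max(dmat[i, j], dmat[i, k], dmat[j, k])
        if diam <= eps_max:
            tris.append((diam, i, j, k))
    tris.sort()

    pivots: dict[int, int] = {}  # pivot edge position -> reduced column bitmask
    deaths: dict[int, float] = {}  # creator edge position -> death value
    for diam, i, j, k in tris:
        col = (
            (1 << edge_index[(i, j)])
            | (1 << edge_index[(i, k)])
            | (1 << edge_index[(j, k)])
        )
        while col:
            low = col.bit_length() - 1
            other = pivots.get(low)
            if other is None:
                pivots[low] = col
                if diam > w[low]:
                    deaths[low] = float(diam)
                # diam == w[low]: zero-length bar, dropped
                break
            col ^= other

    out = [
        PersistenceInterval(1, float(w[pos]), deaths[pos])
        for pos in cycle_edges
        if pos in deaths
    ]
    out.extend(
        PersistenceInterval(1, float(w[pos]), math.inf)
        for pos in cycle_edges
        if pos not in pivots
    )
    return out


def betti_numbers(barcode: Barcode, eps: float) -> tuple[int, int]:
    """(beta_0, beta_1) at scale ``eps``: bars with ``birth <= eps < death``.

    Valid for ``eps <= barcode.eps_max`` (beyond that the filtration was
    not computed).
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    b0 = sum(1 for iv in barcode.intervals if iv.dim == 0 and iv.birth <= eps < iv.death)
    b1 = sum(1 for iv in barcode.intervals if iv.dim == 1 and iv.birth <= eps < iv.death)
    return b0, b1


def betti_curve(barcode: Barcode, eps_grid) -> np.ndarray:
    """Stack (beta_0, beta_1) over a grid of scales; shape ``(len(grid), 2)``."""
    return np.array([betti_numbers(barcode, float(e)) for e in eps_grid])


def save_barcode(barcode: Barcode, path) -> None:
    """One interval per line: ``dim<TAB>birth<TAB>death`` with ``inf`` allowed."""
    with open(path, "w") as fh:
        fh.write(f"# eps_max={barcode.eps_max!r} n_points={barcode.n_points}\n")
        for iv in barcode.intervals:
            death = "inf" if not iv.finite else repr(iv.death)
            fh.write(f"{iv.dim}\t{iv.birth!r}\t{death}\n")


def load_barcode(path) -> Barcode:
    intervals = []
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=", 1) for item in header)
        for line in fh:
            dim, birth, death = line.split("\t")
            intervals.append(
                PersistenceInterval(int(dim), float(birth), float(death))
            )
    return Barcode(intervals, float(kv["eps_max"]), int(kv["n_points"]))
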