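"""Exhaustive Betti-number computation for small clouds.

Independent verification route for the persistence engine: build the full
Vietoris-Rips complex at a single scale explicitly and compute Betti
numbers as ranks of the Z/2 boundary operators by Gaussian elimination
(``beta_k = dim ker d_k - rank d_{k+1}``).  Quadratic-to-cubic in the
simplex counts, so restricted to small point sets; shares no code with the
union-find / column-reduction implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .cloud import PointCloud, distance_matrix

__all__ = ["oracle_betti", "CloudTooLargeError"]

_MAX_POINTS = 12


class CloudTooLargeError(ValueError):
    """The exhaustive oracle is limited to small clouds."""


def _gf2_rank(columns: list[int]) -> int:
    """Rank over Z/2 of a matrix given as column bitmasks."""
    rank = 0
    pivots: dict[int, int] = {}
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low not in pivots:
                pivots[low] = col
                rank += 1
                break
            col ^= pivots[low]
    return rank


def oracle_betti(cloud: PointCloud, eps: float) -> tuple[int, int]:
    """(beta_0, beta_1) of ``VR(cloud, eps)`` by explicit rank computation."""
    if cloud.n_points > _MAX_POINTS:
        raise CloudTooLargeError(
            f"oracle limited to {_MAX_POINTS} points, got {cloud.n_points}"
        )
    pts = np.unique(cloud.points, axis=0)
    n = len(pts)
    dmat = (
        distance_matrix(
            PointCloud(pts, n_channels=n, n_folds=0, source="oracle")
        )
        if n > 1
        else np.zeros((1, 1))
    )

    edges = [(i, j) for i, j in combinations(range(n), 2) if dmat[i, j] <= eps]
    edge_pos = {e: p for p, e in enumerate(edges)}
    triangles = [
        (i, j, k)
        for i, j, k in combinations(range(n), 3)
        if max(dmat[i, j], dmat[i, k], dmat[j, k]) <= eps
    ]

    # d1: vertices x edges; d2: edges x triangles (columns as bitmasks).
    d1_cols = [(1 << i) | (1 << j) for i, j in edges]
    d2_cols = [
        (1 << edge_pos[(i, j)]) | (1 << edge_pos[(i, k)]) | (1 << edge_pos[(j, k)])
        for i, j, k in triangles
    ]
    rank_d1 = _gf2_rank(d1_cols)
    rank_d2 = _gf2_rank(d2_cols)

    beta0 = n - rank_d1
    beta1 = (len(edges) - rank_d1) - rank_d2
    return beta0, beta1
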