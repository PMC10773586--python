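"""Rips persistence engine vs. the exhaustive Z/2 rank oracle and
single-linkage structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from topoeeg import (
    Barcode,
    FiltrationConfig,
    PersistenceInterval,
    PointCloud,
    betti_numbers,
    oracle_betti,
    vr_persistence,
)
from topoeeg.oracle import CloudTooLargeError
from topoeeg.persistence import load_barcode, save_barcode

SQRT5 = math.sqrt(5.0)


def cloud_of(points):
    points = np.asarray(points, dtype=float)
    return PointCloud(points, n_channels=len(points), n_folds=0)


def critical_scales(barcode):
    """All birth/death values of a barcode plus midpoints between them."""
    vals = sorted(
        {iv.birth for iv in barcode.intervals}
        | {iv.death for iv in barcode.intervals if math.isfinite(iv.death)}
    )
    out = []
    for i, v in enumerate(vals):
        out.append(v)
        if i + 1 < len(vals):
            out.append((v + vals[i + 1]) / 2)
    return out


class TestFivePointExample:
    """The printed walk-through of the five-point planar cloud."""

    @pytest.mark.parametrize(
        "eps,expected",
        [(0.6, (5, 0)), (1.0, (4, 0)), (1.44, (3, 0)), (2.35, (1, 1))],
    )
    def test_betti_walkthrough(self, five_point_barcode, eps, expected):
        assert betti_numbers(five_point_barcode, eps) == expected

    def test_loop_is_born_when_pentagon_closes(self, five_points, five_point_barcode):
        loops = five_point_barcode.by_dim(1)
        assert len(loops) == 1
        assert loops[0].birth == pytest.approx(SQRT5)
        # death cross-checked against the exhaustive oracle around the value
        death = loops[0].death
        assert oracle_betti(five_points, death - 1e-9)[1] == 1
        assert oracle_betti(five_points, death)[1] == 0

    def test_dim0_deaths_are_merge_scales(self, five_point_barcode):
        finite = sorted(iv.death for iv in five_point_barcode.by_dim(0) if iv.finite)
        assert finite == pytest.approx([1.0, math.sqrt(2), SQRT5, SQRT5])
        assert sum(1 for iv in five_point_barcode.by_dim(0) if not iv.finite) == 1


def test_two_points():
    bc = vr_persistence(cloud_of([[0.0, 0.0], [3.0, 0.0]]))
    bars = {(iv.dim, iv.birth, iv.death) for iv in bc.intervals}
    assert bars == {(0, 0.0, 3.0), (0, 0.0, math.inf)}


def test_engine_matches_oracle_on_random_clouds(rng):
    """Exhaustive Z/2 rank computation agrees with the reduction engine at
    every critical scale and midpoint, on 50 random small clouds."""
    for _ in range(50):
        n = int(rng.integers(3, 11))
        d = int(rng.integers(2, 5))
        cloud = cloud_of(rng.normal(size=(n, d)))
        bc = vr_persistence(cloud)
        for eps in critical_scales(bc):
            assert betti_numbers(bc, eps) == oracle_betti(cloud, eps)


def test_dim0_deaths_equal_mst_edge_weights(rng):
    """Single-linkage structure: finite dim-0 deaths = MST edge weights
    (independent implementation from scipy)."""
    pts = rng.normal(size=(15, 3))
    bc = vr_persistence(cloud_of(pts))
    deaths = sorted(iv.death for iv in bc.by_dim(0) if iv.finite)
    mst = minimum_spanning_tree(squareform(pdist(pts))).toarray()
    weights = sorted(mst[mst > 0])
    assert deaths == pytest.approx(weights)


def test_beta0_monotone_nonincreasing(rng):
    pts = rng.normal(size=(12, 2))
    cloud = cloud_of(pts)
    bc = vr_persistence(cloud)
    grid = np.linspace(0, bc.eps_max, 40)
    b0 = [betti_numbers(bc, e)[0] for e in grid]
    assert b0[0] == 12
    assert all(a >= b for a, b in zip(b0, b0[1:]))
    assert betti_numbers(bc, bc.eps_max)[0] == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_barcode_invariant_under_point_permutation(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 2))
    perm = rng.permutation(8)
    bars = lambda bc: sorted((iv.dim, iv.birth, iv.death) for iv in bc.intervals)
    a = bars(vr_persistence(cloud_of(pts)))
    b = bars(vr_persistence(cloud_of(pts[perm])))
    assert len(a) == len(b)
    for (d1, b1, x1), (d2, b2, x2) in zip(a, b):
        assert d1 == d2
        assert b1 == pytest.approx(b2)
        assert x1 == pytest.approx(x2) if math.isfinite(x1) else math.isinf(x2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=10_000),
    st.floats(min_value=0.1, max_value=50.0),
)
def test_scale_equivariance(seed, c):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(7, 3))
    a = vr_persistence(cloud_of(pts))
    b = vr_persistence(cloud_of(c * pts))
    for iva, ivb in zip(a.intervals, b.intervals):
        assert ivb.birth == pytest.approx(c * iva.birth, rel=1e-9)
        if iva.finite:
            assert ivb.death == pytest.approx(c * iva.death, rel=1e-9)
        else:
            assert math.isinf(ivb.death)


def test_betti_at_zero_counts_all_points(rng):
    pts = rng.normal(size=(9, 2))
    bc = vr_persistence(cloud_of(pts))
    assert betti_numbers(bc, 0.0) == (9, 0)


def test_duplicate_points_merged_with_warning():
    pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
    with pytest.warns(UserWarning, match="duplicate"):
        bc = vr_persistence(cloud_of(pts))
    assert bc.n_points == 2
    assert len(bc.by_dim(0)) == 2


def test_fixed_eps_max_truncates_filtration(five_points):
    bc = vr_persistence(five_points, FiltrationConfig(n_folds=0, eps_max_rule=1.2))
    # only the closest pair merges below 1.2; the rest stay separate forever
    assert sum(1 for iv in bc.by_dim(0) if not iv.finite) == 4
    assert betti_numbers(bc, 1.2) == (4, 0)


def test_invalid_configs_rejected(five_points):
    with pytest.raises(ValueError):
        FiltrationConfig(eps_max_rule=-1.0)
    with pytest.raises(ValueError):
        vr_persistence(
            PointCloud(np.zeros((0, 2)), n_channels=0, n_folds=0), FiltrationConfig()
        )
    with pytest.raises(ValueError):
        PersistenceInterval(0, 1.0, 0.5)
    with pytest.raises(ValueError):
        PersistenceInterval(0, 0.5, 1.0)  # dim-0 must be born at 0


class TestOracle:
    def test_filled_triangle(self):
        tri = cloud_of([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        assert oracle_betti(tri, 1.0) == (1, 0)

    def test_hollow_square(self):
        square = cloud_of([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert oracle_betti(square, 1.0) == (1, 1)  # diagonals sqrt(2) absent
        assert oracle_betti(square, 1.5) == (1, 0)

    def test_size_limit(self, rng):
        big = cloud_of(rng.normal(size=(13, 2)))
        with pytest.raises(CloudTooLargeError):
            oracle_betti(big, 1.0)


def test_barcode_serialization_roundtrip(tmp_path, five_point_barcode):
    path = tmp_path / "barcode.txt"
    save_barcode(five_point_barcode, path)
    back = load_barcode(path)
    assert back.eps_max == five_point_barcode.eps_max
    assert back.n_points == five_point_barcode.n_points
    assert [
        (iv.dim, iv.birth, iv.death) for iv in back.intervals
    ] == [(iv.dim, iv.birth, iv.death) for iv in five_point_barcode.intervals]
    assert "inf" in path.read_text()
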