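"""Kabsch RMSD and single-linkage clustering against independent oracles."""

import numpy as np
import pytest

from polyqmd.cluster import (DistanceMatrix, centroid, cluster_curve,
                             kabsch_rmsd, pairwise_rmsd,
                             representative_fraction, single_linkage,
                             subsample_frames, suggest_cutoff)
from polyqmd.synthetic import make_cluster_blobs, make_ideal_backbone


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# --- RMSD -----------------------------------------------------------------

def test_rmsd_identity_and_rigid_invariance(rng):
    a = rng.normal(size=(12, 3))
    assert kabsch_rmsd(a, a) == 0.0
    b = a @ random_rotation(rng).T + np.array([3.0, -1.0, 7.0])
    assert kabsch_rmsd(a, b) <= 1e-9


def test_rmsd_symmetric_and_triangle(rng):
    a, b, c = rng.normal(size=(3, 10, 3))
    dab = kabsch_rmsd(a, b)
    assert dab == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)
    assert dab <= kabsch_rmsd(a, c) + kabsch_rmsd(c, b) + 1e-9


def test_rmsd_matches_planar_grid_search(rng):
    # for flat structures the optimal rotation is in-plane: brute-force it
    a2 = rng.normal(size=(4, 2))
    b2 = rng.normal(size=(4, 2))
    a = np.c_[a2, np.zeros(4)]
    b = np.c_[b2, np.zeros(4)]
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    # a proper 3D rotation can realise an in-plane reflection of a flat
    # structure (180° turn about an in-plane axis), so scan both parities
    best = np.inf
    for target in (bc[:, :2], bc[:, :2] * np.array([1.0, -1.0])):
        for ang in np.arange(0.0, 360.0, 0.01):
            r = np.deg2rad(ang)
            rot = np.array([[np.cos(r), -np.sin(r)],
                            [np.sin(r), np.cos(r)]])
            d = ac[:, :2] @ rot.T - target
            best = min(best, np.sqrt((d ** 2).sum() / 4))
    assert kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-5)


def test_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


# --- subsampling ----------------------------------------------------------

def test_subsample_every_hundredth():
    times = np.arange(0.0, 5000.0, 10.0)          # saves every 10 tu
    keep = subsample_frames(times, 1000.0)        # 50 ps gap
    assert list(keep) == list(range(0, 500, 100))


def test_subsample_edge_cases():
    assert list(subsample_frames(np.array([42.0]), 1000.0)) == [0]
    assert list(subsample_frames(np.arange(5.0), 0.0)) == [0, 1, 2, 3, 4]


# --- single linkage -------------------------------------------------------

def chain_matrix():
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = 1.5
    d[1, 2] = d[2, 1] = 1.5
    d[0, 2] = d[2, 0] = 3.5
    return d


def test_single_linkage_chains_through_middle():
    res = single_linkage(chain_matrix(), cutoff=2.0)
    assert res.n_clusters == 1
    assert res.clusters[0] == (0, 1, 2)


def test_single_linkage_extremes():
    d = chain_matrix()
    assert single_linkage(d, 1.0).n_clusters == 3
    assert single_linkage(d, 10.0).n_clusters == 1


def union_find_components(d, cutoff):
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((tuple(sorted(g)) for g in groups.values()),
                  key=lambda g: (-len(g), g[0]))


@pytest.mark.parametrize("n,cutoff", [(20, 0.3), (60, 0.15), (60, 0.5)])
def test_single_linkage_equals_union_find(n, cutoff, rng):
    x = rng.uniform(size=(n, n))
    d = np.triu(x, 1)
    d = d + d.T
    assert [tuple(c) for c in single_linkage(d, cutoff).clusters] == \
        union_find_components(d, cutoff)


def test_cluster_curve_monotone_with_plateau(rng):
    # templates are distinct random coils, i.e. genuinely different shapes
    templates = np.stack([make_ideal_backbone("coil", 6, seed=s)
                          for s in range(3)])
    structs, labels = make_cluster_blobs([12, 8, 5], templates, 0.05,
                                         seed=2)
    d = pairwise_rmsd(structs)
    cutoffs = np.linspace(0.05, 30.0, 60)
    curve = cluster_curve(d, cutoffs)
    assert np.all(np.diff(curve[:, 1]) <= 0)
    assert curve[0, 1] == len(structs) and curve[-1, 1] == 1
    # plateau at 3 clusters across the within/between-blob gap
    assert np.any(curve[:, 1] == 3)
    res = single_linkage(d, 1.0)
    got = {frozenset(c) for c in res.clusters}
    want = {frozenset(np.nonzero(labels == b)[0]) for b in range(3)}
    assert got == want
    assert suggest_cutoff(curve) < 30.0


# --- centroids and fractions ----------------------------------------------

def test_centroid_cases():
    # three points on a line: the middle one minimises total distance
    d = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
    assert centroid([0, 1, 2], d) == 1
    assert centroid([2], d) == 2
    # equilateral: tie broken by lowest index
    eq = np.ones((3, 3)) - np.eye(3)
    assert centroid([0, 1, 2], eq) == 0
    with pytest.raises(ValueError):
        centroid([], d)


def test_representative_fraction():
    d = np.full((10, 10), 5.0)
    np.fill_diagonal(d, 0.0)
    singletons = single_linkage(d, 1.0)
    assert representative_fraction(singletons) == pytest.approx(0.1)
    assert single_linkage(d, 10.0).largest_fraction == 1.0


def test_blob_fraction_half(rng):
    templates = np.stack([make_ideal_backbone("coil", 5, seed=10 + s)
                          for s in range(3)])
    structs, _ = make_cluster_blobs([50, 30, 20], templates, 0.1, seed=6)
    res = single_linkage(pairwise_rmsd(structs), 1.0)
    assert res.n_clusters == 3
    assert representative_fraction(res) == pytest.approx(0.5)
    assert res.representative in res.clusters[0]


def test_distance_matrix_round_trip(rng):
    structs = rng.normal(size=(6, 9, 3))
    dm = DistanceMatrix.from_frames(structs, ca_only=False)
    dense = dm.dense()
    assert dense.shape == (6, 6)
    assert np.allclose(dense, dense.T)
    assert np.allclose(np.diag(dense), 0.0)
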