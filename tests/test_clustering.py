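"""Confusion-augmented distance, clustering, Rand index, confusion ratio."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relief_districts import (
    ConfusionSet,
    Partition,
    TriMesh,
    cluster_connectivity,
    cluster_partition,
    confusion_distance,
    confusion_ratio,
    rand_index,
)
from conftest import all_partitions, brute_rand_index


def two_blob_mesh():
    """10 vertices in two well-separated spatial groups, triangulated."""
    left = [(0.0, 0.0), (0.1, 0.0), (0.0, 0.1), (0.1, 0.1), (0.05, 0.2)]
    right = [(1.0, 0.0), (1.1, 0.0), (1.0, 0.1), (1.1, 0.1), (1.05, 0.2)]
    verts = left + right
    faces = [
        (0, 1, 3), (0, 3, 2), (2, 3, 4),
        (5, 6, 8), (6, 7, 8), (7, 9, 8),
        (1, 5, 3), (5, 8, 3),  # bridge keeping the mesh connected
    ]
    return TriMesh(vertices=verts, faces=faces)


# ----------------------------------------------------------------------
def test_confusion_distance_empty_is_euclidean(square_mesh):
    d = confusion_distance(square_mesh, ConfusionSet(pairs=set()))
    np.testing.assert_allclose(d, square_mesh.distance_matrix())


def test_confusion_distance_adds_diameter():
    # two vertices 0.10 apart in a mesh whose diameter is 0.661
    verts = [(0.0, 0.0), (0.10, 0.0), (0.661, 0.0), (0.3, 0.05)]
    mesh = TriMesh(vertices=verts, faces=[(0, 1, 3), (1, 2, 3)])
    assert mesh.diameter() == pytest.approx(0.661)
    d = confusion_distance(mesh, ConfusionSet(pairs={(0, 1)}))
    assert d[0, 1] == pytest.approx(0.10 + 0.661)
    assert d[1, 0] == d[0, 1]
    assert np.all(np.diag(d) == 0)


def test_confused_exceeds_unconfused_by_diameter(grid_mesh):
    conf = ConfusionSet(pairs={(0, 1)})
    d0 = confusion_distance(grid_mesh, ConfusionSet(pairs=set()))
    d1 = confusion_distance(grid_mesh, conf)
    assert d1[0, 1] - d0[0, 1] == pytest.approx(grid_mesh.diameter())
    mask = np.ones_like(d0, dtype=bool)
    mask[0, 1] = mask[1, 0] = False
    np.testing.assert_allclose(d1[mask], d0[mask])


# ----------------------------------------------------------------------
def test_two_group_recovery_exhaustive():
    mesh = two_blob_mesh()
    planted = np.array([0] * 5 + [1] * 5)
    confused = {
        (a, b) for a, b in combinations(range(10), 2) if planted[a] != planted[b]
    }
    d = confusion_distance(mesh, ConfusionSet(pairs=confused))
    part, k, quality = cluster_partition(d, (2, 8), positions=mesh.vertices)
    assert k == 2
    assert rand_index(part, planted) == 1.0


def test_four_blob_recovery(four_bump):
    mesh, field, dm = four_bump
    planted = dm.hill_label
    confused = {
        (a, b)
        for a, b in combinations(range(mesh.n_vertices), 2)
        if planted[a] != planted[b]
    }
    d = confusion_distance(mesh, ConfusionSet(pairs=confused))
    part, k, _ = cluster_partition(d, (2, 10), positions=mesh.vertices)
    assert k == 4
    assert rand_index(part, planted) == 1.0


def test_degenerate_dissimilarity_rejected():
    d = np.ones((5, 5)) - np.eye(5)
    with pytest.raises(ValueError, match="degenerate"):
        cluster_partition(d, (2, 4))


def test_low_confidence_flag_without_confusions(grid_mesh):
    d = confusion_distance(grid_mesh, ConfusionSet(pairs=set()))
    part, k, quality = cluster_partition(d, (2, 10), positions=grid_mesh.vertices)
    assert set(quality.columns) >= {"k", "silhouette", "low_confidence"}
    # a uniform grid has no strong cluster structure at any k
    assert quality["silhouette"].max() < 0.7


def test_labels_canonical_by_mean_x():
    mesh = two_blob_mesh()
    confused = {(a, b) for a, b in combinations(range(10), 2) if (a < 5) != (b < 5)}
    d = confusion_distance(mesh, ConfusionSet(pairs=confused))
    part, _, _ = cluster_partition(d, (2, 8), positions=mesh.vertices)
    assert set(part.labels[:5]) == {0}  # left group gets label 0
    assert set(part.labels[5:]) == {1}


# ----------------------------------------------------------------------
def test_rand_index_identical_and_extremes():
    p = Partition(labels=np.array([0, 0, 1, 1]))
    assert rand_index(p, p) == 1.0
    singletons = Partition(labels=np.arange(4))
    lump = Partition(labels=np.zeros(4, dtype=int))
    assert rand_index(singletons, lump) == 0.0


def test_rand_index_cross_partition():
    assert rand_index(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])) == pytest.approx(2 / 6)


def test_rand_index_matches_brute_force_all_partitions_small():
    parts = [np.array(p) for p in all_partitions(5)]
    for p in parts:
        for q in parts:
            assert rand_index(p, q) == pytest.approx(brute_rand_index(p, q))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    p=st.lists(st.integers(0, 3), min_size=6, max_size=6),
    q=st.lists(st.integers(0, 3), min_size=6, max_size=6),
)
def test_rand_index_symmetric_and_bounded(p, q):
    r = rand_index(np.array(p), np.array(q))
    assert 0.0 <= r <= 1.0
    assert r == pytest.approx(rand_index(np.array(q), np.array(p)))


def test_rand_index_size_mismatch():
    with pytest.raises(ValueError):
        rand_index(np.array([0, 1]), np.array([0, 1, 2]))


# ----------------------------------------------------------------------
def test_confusion_ratio_uniform_rates_is_one():
    labels = np.array([0] * 10 + [1] * 10)
    p = Partition(labels=labels)
    pairs = {(a, b) for a, b in combinations(range(20), 2)}
    # confuse every 10th pair of each class: identical rates by construction
    intra = sorted([pr for pr in pairs if labels[pr[0]] == labels[pr[1]]])
    inter = sorted([pr for pr in pairs if labels[pr[0]] != labels[pr[1]]])
    confused = set(intra[::10]) | set(inter[::10])
    ratio = confusion_ratio(p, ConfusionSet(pairs=confused), pairs)
    assert ratio == pytest.approx(
        (len(inter[::10]) / len(inter)) / (len(intra[::10]) / len(intra))
    )


def test_confusion_ratio_planted_two_rate_simulation():
    rng = np.random.default_rng(2024)
    labels = np.repeat(np.arange(4), 25)  # 100 vertices -> big pair counts
    p = Partition(labels=labels)
    pairs = {(a, b) for a, b in combinations(range(100), 2)}
    ratios = []
    for _ in range(20):
        confused = {
            pr for pr in pairs
            if rng.random() < (0.05 if labels[pr[0]] == labels[pr[1]] else 0.25)
        }
        ratios.append(confusion_ratio(p, ConfusionSet(pairs=confused), pairs))
    assert np.median(ratios) == pytest.approx(5.0, rel=0.15)


def test_confusion_ratio_markers():
    labels = np.array([0, 0, 1, 1])
    p = Partition(labels=labels)
    pairs = {(a, b) for a, b in combinations(range(4), 2)}
    only_inter = ConfusionSet(pairs={(0, 2)})
    assert confusion_ratio(p, only_inter, pairs) == math.inf
    assert math.isnan(confusion_ratio(p, ConfusionSet(pairs=set()), pairs))
    with pytest.raises(ValueError):
        confusion_ratio(p, only_inter, set())


# ----------------------------------------------------------------------
def test_connectivity_singleton_true(grid_mesh):
    labels = np.zeros(grid_mesh.n_vertices, dtype=int)
    labels[0] = 1
    conn = cluster_connectivity(Partition(labels=labels), grid_mesh)
    assert conn[1] is True


def test_connectivity_split_cluster_false(grid_mesh):
    labels = np.zeros(grid_mesh.n_vertices, dtype=int)
    labels[0] = labels[grid_mesh.n_vertices - 1] = 1  # opposite corners
    conn = cluster_connectivity(Partition(labels=labels), grid_mesh)
    assert conn[1] is False


def test_connectivity_planted_blobs_true(four_bump):
    mesh, _, dm = four_bump
    conn = cluster_connectivity(Partition(labels=dm.hill_label), mesh)
    assert all(conn.values())
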