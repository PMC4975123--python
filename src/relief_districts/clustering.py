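"""Segmentation of the region of interest by the confusion-augmented metric.

The key idea: define a dissimilarity between vertices that is the plain
picture-plane distance for pairs the observer ordered consistently, and that
same distance plus the diameter of the triangulation for confused pairs.
Agglomerative (average-linkage) clustering of this matrix segments the
region into districts inside which depth comparisons are reliable.
Partitions are compared with the Rand index, and the segmentation quality is
quantified by the ratio of inter- to intra-cluster confusion probability.

The dissimilarity can violate the triangle inequality (a confused short pair
is "further apart" than an unconfused long one), so only methods that
consume a raw dissimilarity matrix are used -- no coordinate embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn import metrics as _skmetrics

from .judgements import ConfusionSet, n_pairs
from .mesh import TriMesh

__all__ = [
    "Partition",
    "confusion_distance",
    "cluster_partition",
    "rand_index",
    "confusion_ratio",
    "cluster_connectivity",
    "ConfusionClusterModel",
    "ClusterResults",
]

#: mean silhouette below which a chosen partition is flagged low-confidence
LOW_CONFIDENCE_SILHOUETTE = 0.25


@dataclass
class Partition:
    """Cluster labels per vertex; labels are 0..k-1, every cluster non-empty."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            # compact arbitrary label values to 0..k-1 preserving order
            remap = {int(v): i for i, v in enumerate(uniq)}
            self.labels = np.array([remap[int(v)] for v in self.labels], dtype=np.int64)

    @property
    def k(self) -> int:
        return int(len(np.unique(self.labels)))

    def __len__(self) -> int:
        return len(self.labels)


# ----------------------------------------------------------------------
def confusion_distance(mesh: TriMesh, confusions: ConfusionSet) -> np.ndarray:
    """Dissimilarity d(A,B) = |AB|, plus the triangulation diameter when confused.

    Returns a symmetric V x V matrix with zero diagonal.  The offset for
    confused pairs is the largest vertex separation of the mesh, so a single
    confusion dominates any picture-plane proximity.
    """
    d = mesh.distance_matrix()
    diam = mesh.diameter()
    for a, b in confusions.pairs:
        if a >= mesh.n_vertices or b >= mesh.n_vertices:
            raise ValueError(f"confusion pair ({a},{b}) outside vertex range")
        d[a, b] += diam
        d[b, a] += diam
    return d


def cluster_partition(
    d: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    positions: np.ndarray | None = None,
) -> tuple[Partition, int, pd.DataFrame]:
    """Average-linkage clustering with silhouette-based selection of k.

    For each k in ``k_range`` (inclusive) the agglomerative tree is cut into
    k clusters and the mean silhouette width is computed on the same
    dissimilarities; the k with the largest mean silhouette wins, ties going
    to the smaller k.  When ``positions`` are given, labels are renumbered by
    ascending mean x coordinate for stable reporting.

    Returns ``(partition, chosen_k, quality)`` where ``quality`` has columns
    ``k``, ``silhouette`` and ``low_confidence`` (max silhouette < 0.25).
    """
    d = np.asarray(d, dtype=float)
    v = d.shape[0]
    if d.shape != (v, v):
        raise ValueError("dissimilarity matrix must be square")
    off = d[~np.eye(v, dtype=bool)]
    if np.allclose(off, off[0]):
        raise ValueError("degenerate input: all dissimilarities equal")
    k_lo = max(2, k_range[0])
    k_hi = min(v - 1, k_range[1])
    if k_lo > k_hi:
        raise ValueError(f"empty k range [{k_range[0]}, {k_range[1]}] for V={v}")

    z = linkage(squareform(d, checks=False), method="average")
    rows = []
    labelings: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        labels = fcluster(z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        sil = float(_skmetrics.silhouette_score(d, labels, metric="precomputed"))
        labelings[k] = labels
        rows.append({"k": k, "n_clusters": int(len(np.unique(labels))), "silhouette": sil})
    if not rows:
        raise ValueError("no valid clustering in the requested k range")
    quality = pd.DataFrame(rows)
    best = quality.sort_values(["silhouette", "k"], ascending=[False, True]).iloc[0]
    chosen_k = int(best["k"])
    quality["low_confidence"] = quality["silhouette"].max() < LOW_CONFIDENCE_SILHOUETTE

    labels = labelings[chosen_k]
    if positions is not None:
        labels = _canonicalize_labels(labels, np.asarray(positions))
    return Partition(labels=labels), chosen_k, quality


def _canonicalize_labels(labels: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Renumber clusters by ascending mean x coordinate."""
    uniq = np.unique(labels)
    mean_x = [positions[labels == c, 0].mean() for c in uniq]
    order = uniq[np.argsort(mean_x, kind="stable")]
    remap = {int(c): i for i, c in enumerate(order)}
    return np.array([remap[int(c)] for c in labels], dtype=np.int64)


def rand_index(p: Partition | np.ndarray, q: Partition | np.ndarray) -> float:
    """Fraction of vertex pairs on which two partitions agree (Rand index)."""
    lp = p.labels if isinstance(p, Partition) else np.asarray(p)
    lq = q.labels if isinstance(q, Partition) else np.asarray(q)
    if len(lp) != len(lq):
        raise ValueError("partitions cover different vertex sets")
    return float(_skmetrics.rand_score(lp, lq))


def confusion_ratio(
    p: Partition, confusions: ConfusionSet, all_pairs: set[tuple[int, int]] | None = None
) -> float:
    """Ratio of inter-cluster to intra-cluster confusion probability.

    Probabilities are confusion counts divided by the number of pairs of
    each class among ``all_pairs`` (default: all unordered vertex pairs).
    Returns ``inf`` when only inter-cluster confusions occur and ``nan``
    when there are no confusions at all (undefined ratio).
    """
    labels = p.labels
    v = len(labels)
    if all_pairs is None:
        all_pairs = {(a, b) for a in range(v) for b in range(a + 1, v)}
    if not all_pairs:
        raise ValueError("empty pair set")
    inter = intra = inter_conf = intra_conf = 0
    for a, b in all_pairs:
        same = labels[a] == labels[b]
        confused = (a, b) in confusions
        if same:
            intra += 1
            intra_conf += confused
        else:
            inter += 1
            inter_conf += confused
    inter_rate = inter_conf / inter if inter else 0.0
    intra_rate = intra_conf / intra if intra else 0.0
    if intra_rate == 0.0:
        return math.inf if inter_rate > 0 else math.nan
    return inter_rate / intra_rate


def cluster_connectivity(p: Partition, mesh: TriMesh) -> dict[int, bool]:
    """True per cluster iff its vertices induce a connected mesh subgraph."""
    if len(p) != mesh.n_vertices:
        raise ValueError("partition and mesh cover different vertex sets")
    adj = mesh.vertex_adjacency
    out: dict[int, bool] = {}
    for c in np.unique(p.labels):
        members = np.flatnonzero(p.labels == c)
        idx = {int(v): i for i, v in enumerate(members)}
        n = len(members)
        mat = np.zeros((n, n))
        for v in members:
            for w in adj[v]:
                if w in idx:
                    mat[idx[int(v)], idx[w]] = 1
        n_comp, _ = connected_components(mat, directed=False)
        out[int(c)] = bool(n_comp == 1)
    return out


# ----------------------------------------------------------------------
class ConfusionClusterModel:
    """Segments the region of interest from one session's confusions.

    Parameters
    ----------
    mesh : TriMesh
        The triangulated region of interest (positions in picture widths).
    confusions : ConfusionSet
        Discordant pairs of the session (from :class:`DepthOrderModel`).
    k_range : (int, int)
        Inclusive range of cluster counts to evaluate.
    """

    def __init__(self, mesh: TriMesh, confusions: ConfusionSet,
                 k_range: tuple[int, int] = (2, 10)):
        self.mesh = mesh
        self.confusions = confusions
        self.k_range = (int(k_range[0]), int(k_range[1]))

    def fit(self) -> "ClusterResults":
        d = confusion_distance(self.mesh, self.confusions)
        partition, chosen_k, quality = cluster_partition(
            d, self.k_range, positions=self.mesh.vertices
        )
        return ClusterResults(self, partition, chosen_k, quality)


class ClusterResults:
    """A fitted segmentation: partition, chosen k, silhouette table."""

    def __init__(self, model: ConfusionClusterModel, partition: Partition,
                 chosen_k: int, quality: pd.DataFrame):
        self.model = model
        self.partition = partition
        self.chosen_k = chosen_k
        self.quality = quality

    @property
    def low_confidence(self) -> bool:
        return bool(self.quality["low_confidence"].iloc[0])

    def connectivity(self) -> dict[int, bool]:
        return cluster_connectivity(self.partition, self.model.mesh)

    def confusion_ratio(self) -> float:
        v = self.model.mesh.n_vertices
        pairs = {(a, b) for a in range(v) for b in range(a + 1, v)}
        assert len(pairs) == n_pairs(v)
        return confusion_ratio(self.partition, self.model.confusions, pairs)

    def rand_vs(self, other: "ClusterResults | Partition | np.ndarray") -> float:
        q = other.partition if isinstance(other, ClusterResults) else other
        return rand_index(self.partition, q)

    def to_dict(self) -> dict:
        ratio = self.confusion_ratio()
        return {
            "chosen_k": self.chosen_k,
            "labels": self.partition.labels.tolist(),
            "silhouette_table": self.quality[["k", "silhouette"]].to_dict("records"),
            "low_confidence": self.low_confidence,
            "confusion_ratio": None if math.isnan(ratio) else ratio,
            "connectivity": {str(k): v for k, v in self.connectivity().items()},
        }

    def summary(self) -> str:
        ratio = self.confusion_ratio()
        conn = self.connectivity()
        lines = [
            "Confusion-metric segmentation (average linkage)",
            f"  vertices          : {self.model.mesh.n_vertices}",
            f"  confusions        : {len(self.model.confusions)}",
            f"  chosen k          : {self.chosen_k}"
            + ("  [low confidence]" if self.low_confidence else ""),
            f"  inter/intra ratio : {ratio:.2f}",
            f"  connected clusters: {sum(conn.values())}/{len(conn)}",
        ]
        return "\n".join(lines)
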