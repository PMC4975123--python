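"""Hill/dale geography of a relief: peaks, pits, passes, ridges, courses.

A depth relief on a triangulated region has a "geography" in Maxwell's
sense: summits (peaks, local depth maxima, the tips of bulges turned toward
the observer), immits (pits), and passes (saddles).  Running downhill from
every vertex partitions the region into dale districts (one per pit);
running uphill yields the hill districts (one per peak).  These two natural
parcellations are fully distinct, and swap under depth inversion: negating
the relief turns every hill district into a dale district and vice versa.

Discrete construction on the mesh:

* a vertex is classified by the sign pattern of its one-ring (the cyclic
  sequence of higher/lower neighbors): no sign change means peak or pit,
  two changes a regular point, 2m changes a saddle of multiplicity m-1;
* steepest ascent/descent follows the mesh edge with the largest value
  difference per unit length; exact value ties are broken by vertex index
  ("simulation of simplicity"), giving a strict total order and guaranteed
  termination;
* ridges run from each saddle's upper sectors to peaks, water courses
  (ruts) from its lower sectors to pits; ridges bound the dales, courses
  bound the hills.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh
from .surface import VertexField

logger = logging.getLogger(__name__)

__all__ = [
    "CriticalPointSet",
    "DistrictMap",
    "FeatureGraph",
    "classify_critical",
    "districts",
    "feature_paths",
    "geography_summary",
]


@dataclass
class CriticalPointSet:
    """Classified vertices: peaks, pits, saddles (with multiplicity)."""

    peaks: list[int]
    pits: list[int]
    saddles: dict[int, int]  # vertex -> multiplicity (1 = simple saddle)
    boundary: dict[str, list[int]] = field(default_factory=dict)

    @property
    def saddle_multiplicity_total(self) -> int:
        return sum(self.saddles.values())


@dataclass
class DistrictMap:
    """Per-vertex basin labels: the peak reached uphill, the pit reached downhill."""

    hill_label: np.ndarray
    dale_label: np.ndarray

    def n_hills(self) -> int:
        return len(np.unique(self.hill_label))

    def n_dales(self) -> int:
        return len(np.unique(self.dale_label))


@dataclass
class FeatureGraph:
    """Steepest paths through saddles: ridges end at peaks, courses at pits."""

    ridges: list[list[int]]
    courses: list[list[int]]


# ----------------------------------------------------------------------
def _key(z: np.ndarray):
    """Strict total order on vertices: value first, index breaks exact ties."""

    def key(v: int) -> tuple[float, int]:
        return (float(z[v]), int(v))

    return key


def _ring_signs(z: np.ndarray, v: int, ring: list[int]) -> list[bool]:
    key = _key(z)
    kv = key(v)
    return [key(n) > kv for n in ring]


def _count_sign_changes(signs: list[bool], closed: bool) -> int:
    if len(signs) < 2:
        return 0
    pairs = zip(signs, signs[1:] + ([signs[0]] if closed else []))
    return sum(a != b for a, b in pairs)


def classify_critical(mesh: TriMesh, field: VertexField) -> CriticalPointSet:
    """Classify every vertex by one-ring sign changes.

    Interior vertices: 0 changes with all neighbors lower -> peak, all
    higher -> pit; 2 changes -> regular; 2m changes -> saddle of
    multiplicity m-1.  Boundary vertices are tested against all their
    neighbors for the peak/pit condition but are never counted as saddles
    (the occluding contour makes the sector structure ill-posed there);
    they are listed separately under ``boundary``.
    """
    z = field.z
    if len(z) != mesh.n_vertices:
        raise ValueError("field and mesh cover different vertex sets")
    boundary_mask = mesh.boundary_vertices
    peaks, pits, saddles = [], [], {}
    b_peaks, b_pits = [], []
    for v in range(mesh.n_vertices):
        ring, closed = mesh.vertex_link(v)
        if not ring:
            continue
        signs = _ring_signs(z, v, ring)
        if boundary_mask[v] or not closed:
            if not any(signs):
                b_peaks.append(v)
            elif all(signs):
                b_pits.append(v)
            continue
        if len(ring) < 3:
            raise ValueError(f"interior vertex {v} has fewer than 3 neighbors")
        changes = _count_sign_changes(signs, closed=True)
        if changes == 0:
            (pits if signs[0] else peaks).append(v)
        elif changes >= 4:
            m = changes // 2 - 1
            saddles[v] = m
            if m >= 2:
                logger.info("vertex %d is a monkey saddle (multiplicity %d)", v, m)
    return CriticalPointSet(
        peaks=peaks, pits=pits, saddles=saddles,
        boundary={"peaks": b_peaks, "pits": b_pits},
    )


# ----------------------------------------------------------------------
def _steepest_up_neighbor(
    mesh_adj: list[list[int]], pos: np.ndarray, z: np.ndarray, v: int
) -> int | None:
    """Neighbor reached by the steepest ascending edge, or None at a maximum.

    Steepness is the value difference per unit edge length; among the
    strictly higher neighbors (in the tie-broken order) the one with the
    largest slope wins, slope ties going to the smaller index.
    """
    key = _key(z)
    kv = key(v)
    best, best_slope = None, -np.inf
    for n in mesh_adj[v]:
        if key(n) > kv:
            length = float(np.hypot(*(pos[n] - pos[v])))
            slope = (z[n] - z[v]) / max(length, 1e-300)
            if slope > best_slope or (slope == best_slope and (best is None or n < best)):
                best, best_slope = n, slope
    return best


def _ascend_all(mesh: TriMesh, z: np.ndarray) -> np.ndarray:
    """Basin root (local maximum reached by steepest ascent) for every vertex."""
    adj = mesh.vertex_adjacency
    pos = mesh.vertices
    root = np.full(mesh.n_vertices, -1, dtype=np.int64)
    for v in range(mesh.n_vertices):
        path = []
        cur = v
        while root[cur] == -1:
            path.append(cur)
            up = _steepest_up_neighbor(adj, pos, z, cur)
            if up is None:
                root[cur] = cur
                break
            cur = up
        target = root[cur]
        for p in path:
            root[p] = target
    return root


def districts(mesh: TriMesh, field: VertexField) -> DistrictMap:
    """Hill and dale districts by steepest ascent / descent along edges.

    The dale labels are computed as the hill labels of the negated field, so
    the inversion duality (hills of -z are exactly the dales of z) holds by
    construction, including the tie-break.
    """
    z = np.asarray(field.z, dtype=float)
    return DistrictMap(
        hill_label=_ascend_all(mesh, z),
        dale_label=_ascend_all(mesh, -z),
    )


def _ascend_path(mesh: TriMesh, z: np.ndarray, start: int) -> list[int]:
    adj = mesh.vertex_adjacency
    pos = mesh.vertices
    path = [start]
    while True:
        up = _steepest_up_neighbor(adj, pos, z, path[-1])
        if up is None:
            return path
        path.append(up)


def _sectors(signs: list[bool], ring: list[int], want: bool) -> list[list[int]]:
    """Maximal cyclic runs of ring neighbors with the requested sign."""
    n = len(signs)
    if all(s == want for s in signs):
        return [ring]
    # rotate so the ring starts just after a run boundary
    start = next(i for i in range(n) if signs[i] != want)
    runs, cur = [], []
    for i in range(start, start + n):
        i %= n
        if signs[i] == want:
            cur.append(ring[i])
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def feature_paths(mesh: TriMesh, field: VertexField, cps: CriticalPointSet) -> FeatureGraph:
    """Ridges and water courses launched from every saddle.

    From each upper sector of a saddle one steepest-ascent path is traced to
    a peak (a ridge); from each lower sector one steepest-descent path is
    traced to a pit or to the boundary (a course).  A simple saddle yields
    two of each; monkey saddles one per sector.
    """
    z = np.asarray(field.z, dtype=float)
    ridges, courses = [], []
    for s in cps.saddles:
        ring, _closed = mesh.vertex_link(s)
        signs = _ring_signs(z, s, ring)
        def slope(n: int) -> float:
            length = float(np.hypot(*(mesh.vertices[n] - mesh.vertices[s])))
            return (z[n] - z[s]) / max(length, 1e-300)

        for sector in _sectors(signs, ring, want=True):
            first = max(sector, key=lambda n: (slope(n), -n))
            ridges.append([s] + _ascend_path(mesh, z, first))
        for sector in _sectors(signs, ring, want=False):
            first = min(sector, key=lambda n: (slope(n), n))
            # descent on z is ascent on -z
            courses.append([s] + _ascend_path(mesh, -z, first))
    return FeatureGraph(ridges=ridges, courses=courses)


def geography_summary(mesh: TriMesh, field: VertexField) -> dict:
    """Counts of critical points, districts, and feature paths."""
    cps = classify_critical(mesh, field)
    dm = districts(mesh, field)
    fg = feature_paths(mesh, field, cps)
    return {
        "n_peaks": len(cps.peaks),
        "n_pits": len(cps.pits),
        "n_saddles": len(cps.saddles),
        "saddle_multiplicity_total": cps.saddle_multiplicity_total,
        "n_boundary_peaks": len(cps.boundary.get("peaks", [])),
        "n_boundary_pits": len(cps.boundary.get("pits", [])),
        "n_hill_districts": dm.n_hills(),
        "n_dale_districts": dm.n_dales(),
        "n_ridges": len(fg.ridges),
        "n_courses": len(fg.courses),
    }
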