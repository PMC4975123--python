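"""Triangulated planar region of interest.

The stimulus region is a 2D domain triangulated into vertices, edges and
faces; every later stage (depth orders, confusion clustering, gauge-figure
integration, hill/dale geography) works on this shared structure.  Vertex
coordinates live in picture coordinates scaled so that the picture width is
1, which makes the confusion distance function scale-free.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "MeshValidationError",
    "MeshFormatError",
    "load_mesh",
    "save_mesh",
    "mesh_stats",
    "face_barycenters",
]


class MeshValidationError(ValueError):
    """The vertex/face arrays do not describe a valid manifold triangulation."""


class MeshFormatError(ValueError):
    """A mesh file could not be parsed in the requested format."""


@dataclass
class TriMesh:
    """Triangle mesh with 2D vertex positions (picture coordinates).

    Parameters
    ----------
    vertices : (V, 2) float array
        Vertex positions; x is measured in picture widths.
    faces : (F, 3) int array
        Counter-clockwise vertex index triples (orientation is not enforced).

    Invariants checked at construction: faces reference three distinct valid
    vertices, every edge borders at most two faces, and the edge graph is
    connected.  A non-disk Euler characteristic only warns, so closed test
    surfaces (spheres, tori) can be carried through the geography stage.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _edges: np.ndarray = field(init=False, repr=False, default=None)
    _edge_faces: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshValidationError("vertices must be an (V, 2) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshValidationError("faces must be an (F, 3) array")
        self.faces = self.faces.reshape(-1, 3)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        v, f = len(self.vertices), self.faces
        if f.size and (f.min() < 0 or f.max() >= v):
            bad = f[(f < 0) | (f >= v)].flat[0]
            raise MeshValidationError(
                f"face references vertex {bad} outside [0, {v})"
            )
        if any(len(set(tri)) != 3 for tri in f):
            raise MeshValidationError("face with repeated vertex index")

        edge_faces: dict[tuple[int, int], list[int]] = defaultdict(list)
        for fi, (a, b, c) in enumerate(f):
            for e in ((a, b), (b, c), (c, a)):
                edge_faces[tuple(sorted(e))].append(fi)
        for e, fs in edge_faces.items():
            if len(fs) > 2:
                raise MeshValidationError(
                    f"non-manifold edge {e} shared by {len(fs)} faces"
                )
        self._edge_faces = dict(edge_faces)
        self._edges = np.array(sorted(edge_faces), dtype=np.int64).reshape(-1, 2)

        if v > 1 and len(self._edges):
            n_comp, _ = connected_components(self._adjacency_sparse(), directed=False)
            if n_comp != 1:
                raise MeshValidationError(
                    f"mesh edge graph has {n_comp} connected components"
                )
        euler = v - len(self._edges) + len(f)
        if len(f) and euler != 1:
            warnings.warn(
                f"Euler characteristic V-E+F = {euler} != 1: not a disk-like region",
                stacklevel=3,
            )

    def _adjacency_sparse(self):
        e = self._edges
        ones = np.ones(len(e))
        return coo_matrix(
            (np.r_[ones, ones], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(len(self.vertices), len(self.vertices)),
        )

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unordered edge index pairs, sorted, shape (E, 2)."""
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    @property
    def boundary_edges(self) -> list[tuple[int, int]]:
        return [e for e, fs in self._edge_faces.items() if len(fs) == 1]

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask, True where the vertex lies on a boundary edge."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        for a, b in self.boundary_edges:
            mask[a] = mask[b] = True
        return mask

    @property
    def vertex_adjacency(self) -> list[list[int]]:
        """Sorted neighbor lists per vertex."""
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b in self._edges:
            adj[a].add(b)
            adj[b].add(a)
        return [sorted(s) for s in adj]

    def edge_lengths(self) -> dict[tuple[int, int], float]:
        d = self.vertices[self._edges[:, 0]] - self.vertices[self._edges[:, 1]]
        lengths = np.hypot(d[:, 0], d[:, 1])
        return {tuple(e): float(l) for e, l in zip(self._edges, lengths)}

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 1, 1] - p[:, 0, 1]
        ) * (p[:, 2, 0] - p[:, 0, 0])
        return 0.5 * np.abs(cross)

    def diameter(self) -> float:
        """Largest pairwise vertex separation (the paper-style 'diameter')."""
        if self.n_vertices < 2:
            return 0.0
        return float(pdist(self.vertices).max())

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.vertices))

    # ------------------------------------------------------------------
    def vertex_link(self, v: int) -> tuple[list[int], bool]:
        """Cyclically ordered one-ring of vertex ``v``.

        Returns ``(ring, closed)`` where ``ring`` lists the neighbors in
        consecutive order around ``v`` (combinatorial, derived from the face
        fan, so it is valid even for meshes whose 2D coordinates are a
        projection) and ``closed`` is True for interior vertices.
        """
        link_edges = []
        for tri in self.faces:
            if v in tri:
                others = [int(x) for x in tri if x != v]
                link_edges.append(others)
        if not link_edges:
            return [int(n) for n in self.vertex_adjacency[v]], False

        nbrs: dict[int, list[int]] = defaultdict(list)
        for a, b in link_edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        endpoints = [n for n, ns in nbrs.items() if len(ns) == 1]
        closed = not endpoints
        start = min(endpoints) if endpoints else min(nbrs)
        ring = [start]
        prev = None
        while True:
            nxt = [n for n in nbrs[ring[-1]] if n != prev]
            if not nxt:
                break
            prev = ring[-1]
            ring.append(nxt[0])
            if closed and ring[-1] == start:
                ring.pop()
                break
            if len(ring) > len(nbrs):
                raise MeshValidationError(f"inconsistent link around vertex {v}")
        return ring, closed


# ----------------------------------------------------------------------
def load_mesh(path: str | Path, fmt: str | None = None) -> TriMesh:
    """Read an OFF or OBJ file into a validated :class:`TriMesh`.

    Only vertex and triangular-face records are consumed; a nonzero z
    coordinate is dropped with a logged notice.  Polygonal faces are
    rejected.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("off", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    except Exception as exc:  # noqa: BLE001 - surface parse diagnostics
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if isinstance(raw, _trimesh.Scene):
        geoms = list(raw.geometry.values())
        if len(geoms) != 1:
            raise MeshFormatError(f"{path}: expected a single mesh, got {len(geoms)}")
        raw = geoms[0]
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if faces.size and faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces are not supported")
    if verts.shape[1] >= 3 and np.any(verts[:, 2] != 0):
        logger.info("%s: dropping nonzero z coordinates (picture plane is 2D)", path)
    return TriMesh(vertices=verts[:, :2], faces=faces)


def save_mesh(mesh: TriMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as OFF or OBJ (z written as 0)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("off", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    v3 = np.column_stack([mesh.vertices, np.zeros(mesh.n_vertices)])
    tm = _trimesh.Trimesh(vertices=v3, faces=mesh.faces, process=False)
    path.write_text(tm.export(file_type=fmt))


def mesh_stats(mesh: TriMesh) -> dict:
    """Vertex/edge/face counts, Euler characteristic and diameter."""
    return {
        "V": mesh.n_vertices,
        "E": mesh.n_edges,
        "F": mesh.n_faces,
        "euler": mesh.euler_characteristic,
        "diameter": mesh.diameter(),
    }


def face_barycenters(mesh: TriMesh) -> np.ndarray:
    """Arithmetic mean of the three vertex positions, one row per face."""
    return mesh.vertices[mesh.faces].mean(axis=1)
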