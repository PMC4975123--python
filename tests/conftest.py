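"""Shared fixtures: tiny meshes, the four-bump relief, brute-force oracles."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from relief_districts import (
    TriMesh,
    VertexField,
    bump_relief,
    districts,
    four_bump_spec,
    make_grid_mesh,
)


@pytest.fixture
def triangle_mesh() -> TriMesh:
    """Smallest valid mesh: one right triangle."""
    return TriMesh(vertices=[(0, 0), (1, 0), (0, 1)], faces=[(0, 1, 2)])


@pytest.fixture
def square_mesh() -> TriMesh:
    """Unit square split into two triangles along a diagonal."""
    return TriMesh(
        vertices=[(0, 0), (1, 0), (1, 1), (0, 1)],
        faces=[(0, 1, 2), (0, 2, 3)],
    )


@pytest.fixture
def grid_mesh() -> TriMesh:
    return make_grid_mesh(four_bump_spec())


@pytest.fixture
def four_bump(grid_mesh):
    """(mesh, field, district_map) for the canonical four-bump relief."""
    field = bump_relief(grid_mesh, four_bump_spec())
    return grid_mesh, field, districts(grid_mesh, field)


# ----------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent of the
# package's implementations)

def brute_rand_index(p, q) -> float:
    p, q = np.asarray(p), np.asarray(q)
    n = len(p)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            same_p = p[i] == p[j]
            same_q = q[i] == q[j]
            agree += same_p == same_q
    return agree / total


def brute_tau_b(x, y) -> float:
    """Tau-b by exhaustive pair classification."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (c - d) / denom if denom else np.nan


def brute_merit(judgements, ranks) -> float:
    """(C - D) / N by direct enumeration of the judged pairs."""
    c = d = 0
    for j in judgements:
        if ranks[j.a] == ranks[j.b]:
            continue
        nearer = j.a if ranks[j.a] < ranks[j.b] else j.b
        if j.chosen == nearer:
            c += 1
        else:
            d += 1
    return (c - d) / len(judgements)


def all_partitions(n: int):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(mx + 2):
            yield from rec(prefix + [lab], max(mx, lab))

    yield from rec([0], 0) if n else iter(())


def all_weak_orders(n: int):
    """All dense rank vectors (ordered set partitions) of n elements."""
    for vec in product(range(n), repeat=n):
        k = len(set(vec))
        if set(vec) == set(range(k)):
            yield vec


@pytest.fixture
def sphere_mesh_and_field():
    """Closed icosphere (projected to 2D) with a generic scalar field.

    The 2D coordinates are just a projection; only the combinatorial
    structure (one-rings) matters for critical-point classification.
    """
    import warnings

    import trimesh as tm

    ico = tm.creation.icosphere(subdivisions=1)
    v3 = np.asarray(ico.vertices)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-disk Euler characteristic
        mesh = TriMesh(vertices=v3[:, :2], faces=np.asarray(ico.faces))
    rng = np.random.default_rng(12345)
    z = v3[:, 0] + 0.5 * v3[:, 1] ** 2 + 0.25 * v3[:, 2] + 0.05 * rng.normal(size=len(v3))
    return mesh, VertexField(z=z)
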