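"""Simulated stimuli and observers.

The human data behind the 2-point and gauge-figure tasks are not deposited,
so every stage of the pipeline is exercised on synthetic material with the
statistical structure the analysis assumes:

* a regular triangulated grid standing in for the ~57-vertex region of
  interest (an 8x8 grid, 64 vertices, is the default scale);
* a multi-bump Gaussian relief whose hill districts play the role of the
  bulges of a pictorial relief;
* a simulated observer whose 2-point error rate is higher when the two
  points lie in different hill districts than within one district — the
  empirical inter/intra confusion-probability ratio is about 2, and the
  default planted rates (0.05 within, 0.25 between) put the simulated
  regime clearly on that side while keeping the consensus order stable;
* noisy gauge-figure attitude samples with an optional curl (non-integrable)
  component.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
from scipy.special import expit as _expit

from .geography import DistrictMap, districts
from .judgements import JudgementSet, PairJudgement, n_pairs
from .mesh import TriMesh
from .surface import AttitudeSample, VertexField, face_gradients

__all__ = [
    "ReliefSpec",
    "ObserverSpec",
    "make_grid_mesh",
    "bump_relief",
    "simulate_judgements",
    "simulate_attitudes",
    "four_bump_spec",
    "planted_partition",
]


@dataclass
class ReliefSpec:
    """A grid domain plus a sum-of-Gaussian-bumps relief.

    ``bumps`` is a list of (center (x, y), amplitude, width); widths are in
    picture-width units, amplitudes in depth units (positive = toward the
    observer).
    """

    bumps: list[tuple[tuple[float, float], float, float]] = dc_field(default_factory=list)
    base: float = 0.0
    domain: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)  # x0, y0, x1, y1
    grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.grid[0] < 3 or self.grid[1] < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.grid}")
        if any(w <= 0 for _, _, w in self.bumps):
            raise ValueError("bump widths must be positive")


@dataclass
class ObserverSpec:
    """District-dependent 2-point error model.

    In ``flip`` mode the truthful answer is inverted with probability
    ``eps_within`` when the two vertices share a hill district and
    ``eps_between`` otherwise.  In ``logistic`` mode the probability of
    calling vertex a nearer is 1/(1+exp(-(z_a - z_b)/sigma)) with sigma
    picked by the same-district rule (a depth-difference-dependent,
    psychophysically more faithful observer).
    """

    eps_within: float = 0.05
    eps_between: float = 0.25
    mode: str = "flip"
    sigma_within: float = 0.05
    sigma_between: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for eps in (self.eps_within, self.eps_between):
            if not 0.0 <= eps <= 0.5:
                raise ValueError(f"error rate must be in [0, 0.5], got {eps}")
        if self.mode not in ("flip", "logistic"):
            raise ValueError(f"unknown observer mode {self.mode!r}")
        if self.sigma_within <= 0 or self.sigma_between <= 0:
            raise ValueError("sigma must be positive")


def four_bump_spec(grid: tuple[int, int] = (8, 8)) -> ReliefSpec:
    """Four bumps in a 2x2 arrangement: the canonical four-district relief."""
    return ReliefSpec(
        bumps=[
            ((0.25, 0.25), 1.0, 0.12),
            ((0.75, 0.25), 1.0, 0.12),
            ((0.25, 0.75), 1.0, 0.12),
            ((0.75, 0.75), 1.0, 0.12),
        ],
        grid=grid,
    )


# ----------------------------------------------------------------------
def make_grid_mesh(spec: ReliefSpec) -> TriMesh:
    """Regular nx x ny grid, each cell split into two triangles.

    V = nx*ny, F = 2(nx-1)(ny-1), E = V + F - 1 (a disk).
    """
    nx, ny = spec.grid
    x0, y0, x1, y1 = spec.domain
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    verts = np.array([(x, y) for y in ys for x in xs])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v00 = j * nx + i
            v10 = v00 + 1
            v01 = v00 + nx
            v11 = v01 + 1
            # split along the cell diagonal v00-v11
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return TriMesh(vertices=verts, faces=np.array(faces))


def bump_relief(mesh: TriMesh, spec: ReliefSpec) -> VertexField:
    """z(v) = base + sum of Gaussian bumps, gauged to zero mean."""
    z = np.full(mesh.n_vertices, float(spec.base))
    for (cx, cy), amp, width in spec.bumps:
        r2 = np.sum((mesh.vertices - [cx, cy]) ** 2, axis=1)
        z += amp * np.exp(-r2 / (2.0 * width**2))
    return VertexField(z=z).zero_mean()


# ----------------------------------------------------------------------
def _session_rng(obs: ObserverSpec, observer: str, session: str) -> np.random.Generator:
    """One reproducible stream per (observer, session, seed)."""
    return np.random.default_rng(
        [obs.seed, zlib.crc32(observer.encode()), zlib.crc32(session.encode())]
    )


def simulate_judgements(
    field: VertexField,
    district_map: DistrictMap,
    obs: ObserverSpec,
    observer: str = "sim",
    session: str = "s1",
) -> JudgementSet:
    """Complete 2-point session of the district-dependent simulated observer.

    Every unordered vertex pair is judged exactly once, in a fixed
    lexicographic order.  The true answer is the vertex with the larger
    depth (exact ties broken by index, matching the geography tie-break).
    """
    z = field.z
    v = len(z)
    hills = district_map.hill_label
    if len(hills) != v:
        raise ValueError("district map and field cover different vertex sets")
    rng = _session_rng(obs, observer, session)
    judgements = []
    for a, b in combinations(range(v), 2):
        truth = a if (z[a], a) > (z[b], b) else b
        same = hills[a] == hills[b]
        if obs.mode == "flip":
            eps = obs.eps_within if same else obs.eps_between
            chosen = truth if rng.random() >= eps else (a + b - truth)
        else:
            sigma = obs.sigma_within if same else obs.sigma_between
            p_a = _expit((z[a] - z[b]) / sigma)
            chosen = a if rng.random() < p_a else b
        judgements.append(PairJudgement(a=a, b=b, chosen=chosen))
    out = JudgementSet(observer=observer, session=session, judgements=judgements)
    assert len(out) == n_pairs(v)
    return out


def _random_smooth_field(mesh: TriMesh, rng: np.random.Generator,
                         n_bumps: int = 6) -> VertexField:
    """Sum of random Gaussian bumps: the independent field whose rotated
    gradient provides the curl component."""
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    span = float(np.max(hi - lo))
    z = np.zeros(mesh.n_vertices)
    for _ in range(n_bumps):
        c = lo + rng.random(2) * (hi - lo)
        amp = rng.normal(0.0, 1.0)
        width = span * (0.1 + 0.2 * rng.random())
        r2 = np.sum((mesh.vertices - c) ** 2, axis=1)
        z += amp * np.exp(-r2 / (2.0 * width**2))
    return VertexField(z=z).zero_mean()


def simulate_attitudes(
    mesh: TriMesh,
    field: VertexField,
    noise_sd: float = 0.0,
    curl_frac: float = 0.0,
    seed: int = 0,
) -> list[AttitudeSample]:
    """Noisy gauge-figure samples: true face gradients + noise + curl.

    The curl component is the 90-degree-rotated gradient of an independent
    random smooth field, rescaled so its area-weighted power matches that of
    the true gradient field (unit power if the true field is flat), then
    multiplied by ``curl_frac``.  ``noise_sd`` adds isotropic Gaussian noise
    per component.
    """
    if noise_sd < 0 or curl_frac < 0:
        raise ValueError("noise_sd and curl_frac must be non-negative")
    rng = np.random.default_rng([seed, 0x617474])  # attitude stream
    g = face_gradients(mesh, field)
    areas = mesh.face_areas()

    if curl_frac > 0:
        aux = _random_smooth_field(mesh, rng)
        ga = face_gradients(mesh, aux)
        rot = np.column_stack([-ga[:, 1], ga[:, 0]])
        true_power = float(np.sum(areas * np.sum(g**2, axis=1)))
        rot_power = float(np.sum(areas * np.sum(rot**2, axis=1)))
        target = true_power if true_power > 0 else float(np.sum(areas))
        if rot_power > 0:
            rot *= np.sqrt(target / rot_power)
        g = g + curl_frac * rot

    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, size=g.shape)

    return [AttitudeSample(face=f, p=float(p), q=float(q))
            for f, (p, q) in enumerate(g)]


def planted_partition(mesh: TriMesh, field: VertexField) -> np.ndarray:
    """The hill-district labels of the generated relief (the ground truth
    the confusion clustering should recover)."""
    return districts(mesh, field).hill_label
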