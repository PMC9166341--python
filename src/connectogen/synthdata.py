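"""Synthetic inputs with known ground truth.

Generators for every input class the framework consumes: growing
geometries (node coordinates on an expanding closed surface and the
distance-matrix sequence they induce), "empirical" networks drawn from
known wiring rules, similarity matrices with an exponential distance
decay plus structured fluctuations (CGE-like), regional depth-intensity
profiles (MPC inputs), and watertight fixture meshes. Every generator is
a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import engine, metrics

#: Default ratio of final to initial geometry scale. Fetal template work
#: shows the maximum interregional distance growing by roughly 74% over
#: the second half of gestation, so the default scale path ends at 1.74x
#: the starting scale.
DEFAULT_SCALE_RATIO = 1.74

#: Default number of developmental stages (18 fetal time points + adult).
DEFAULT_STAGES = 19


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass(frozen=True)
class GeometrySpec:
    """Growing-surface geometry: n nodes, T stages, scale path, jitter.

    ``scale_path`` defaults to a linear ramp from ``base_scale`` to
    ``base_scale * scale_ratio`` (in mm). ``jitter_sd`` adds seeded
    Gaussian displacement (mm) to every stage's coordinates; 0 keeps the
    sequence an exact rescaling of the base shape.
    """

    n: int = 100
    stages: int = DEFAULT_STAGES
    shape: str = "sphere"  # or "ellipsoid"
    base_scale: float = 40.0
    scale_ratio: float = DEFAULT_SCALE_RATIO
    scale_path: tuple[float, ...] | None = None
    ellipsoid_axes: tuple[float, float, float] = (1.0, 0.8, 0.65)
    jitter_sd: float = 0.0
    seed: int = 0

    def scales(self) -> np.ndarray:
        if self.scale_path is not None:
            s = np.asarray(self.scale_path, dtype=float)
            if len(s) != self.stages or np.any(np.diff(s) <= 0) or np.any(s <= 0):
                raise ValueError("scale_path must be strictly increasing, positive, "
                                 "one value per stage")
            return s
        if self.stages == 1:
            return np.array([self.base_scale])
        return np.linspace(self.base_scale, self.base_scale * self.scale_ratio,
                           self.stages)


def make_geometry_sequence(spec: GeometrySpec):
    """Node coordinates per stage and the DistanceSet they induce.

    Returns ``(dset, coords)`` where ``coords[t]`` is the (n, 3) node
    array at stage t and ``dset.matrices[t]`` the matching Euclidean
    distance matrix. With zero jitter, D(t) = s(t)/s(1) * D(1) exactly.
    """
    if spec.n < 3:
        raise ValueError("need at least 3 nodes")
    base = fibonacci_sphere(spec.n)
    if spec.shape == "ellipsoid":
        base = base * np.asarray(spec.ellipsoid_axes)
    elif spec.shape != "sphere":
        raise ValueError(f"unknown base shape {spec.shape!r}")
    rng = np.random.default_rng(spec.seed)
    coords = []
    for s in spec.scales():
        X = s * base
        if spec.jitter_sd > 0:
            X = X + rng.normal(0.0, spec.jitter_sd, size=X.shape)
        coords.append(X)
    mats = []
    for X in coords:
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        mats.append(D)
    return engine.DistanceSet(matrices=mats), coords


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a truth network bit-exactly."""

    spec: engine.ModelSpec
    params: engine.Params
    E: int
    seed: int


def make_truth_network(
    spec: engine.ModelSpec,
    params: engine.Params,
    dset: engine.DistanceSet,
    E: int,
    seed: int,
    constraint: np.ndarray | None = None,
):
    """A ground-truth network plus its replay record."""
    A = engine.grow(spec, params, dset, E, seed=seed, constraint=constraint)
    return A, TruthRecord(spec=spec, params=params, E=E, seed=seed)


def replay(record: TruthRecord, dset: engine.DistanceSet,
           constraint: np.ndarray | None = None) -> np.ndarray:
    """Regenerate the network a TruthRecord describes."""
    return engine.grow(record.spec, record.params, dset, record.E,
                       seed=record.seed, constraint=constraint)


@dataclass(frozen=True)
class PhysioSpec:
    """CGE-like similarity: exponential decay plus structured fluctuations.

    Defaults for (p1, p2, p3) follow published exponential fits of
    correlated gene expression against cortical distance; ``field_sd``
    sets the spread of a per-node latent field f whose pairwise sums
    f_i + f_j create spatially structured (non-distance) covariation,
    and ``noise_sd`` sets unstructured pairwise noise.
    """

    p1: float = 1.12
    p2: float = 0.012
    p3: float = -0.29
    field_sd: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.p2 <= 0:
            raise ValueError("decay rate p2 must be positive")

    @property
    def decay(self) -> metrics.DecayFit:
        return metrics.DecayFit(self.p1, self.p2, self.p3)


def make_cge(D, spec: PhysioSpec):
    """Synthetic CGE matrix over a distance matrix D.

    S_ij = clip(p1 exp(-p2 D_ij) + p3 + f_i + f_j + eps_ij, -1, 1),
    symmetric with zero diagonal. Returns ``(S, n_clipped)`` where
    ``n_clipped`` counts off-diagonal entries affected by clipping.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    rng = np.random.default_rng(spec.seed)
    f = rng.normal(0.0, spec.field_sd, size=n) if spec.field_sd > 0 else np.zeros(n)
    f = f - f.mean()
    noise = rng.normal(0.0, spec.noise_sd, size=(n, n)) if spec.noise_sd > 0 else np.zeros((n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)
    # group symmetric summands so the result is bit-exactly symmetric
    # (float addition is not associative across the diagonal otherwise)
    field = f[:, None] + f[None, :]
    S = spec.decay(D) + (field + noise)
    np.fill_diagonal(S, 0.0)
    off = ~np.eye(n, dtype=bool)
    n_clipped = int(np.count_nonzero((S[off] < -1) | (S[off] > 1)))
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 0.0)
    return S, n_clipped


def make_profiles(
    n_regions: int,
    depth_samples: int = 50,
    n_archetypes: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    assignments: np.ndarray | None = None,
):
    """Regional depth-intensity profiles as archetype mixtures plus noise.

    Each archetype is a smooth curve over cortical depth (low-order
    Fourier series, seeded); each region's profile is a convex mixture
    dominated by its assigned archetype, plus i.i.d. noise. Regions
    sharing an archetype have high profile covariance. Returns
    ``(P, assignments)`` with P of shape (n_regions, depth_samples).
    """
    if depth_samples < 3:
        raise ValueError("need at least 3 depth samples")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, depth_samples)
    arch = np.empty((n_archetypes, depth_samples))
    for k in range(n_archetypes):
        coef = rng.normal(0.0, 1.0, size=4)
        arch[k] = (
            coef[0] * np.sin(np.pi * x) + coef[1] * np.cos(np.pi * x)
            + coef[2] * np.sin(2 * np.pi * x) + coef[3] * np.cos(2 * np.pi * x)
        )
    if assignments is None:
        assignments = rng.integers(0, n_archetypes, size=n_regions)
    else:
        assignments = np.asarray(assignments, dtype=np.int64)
        if assignments.shape != (n_regions,):
            raise ValueError("one archetype assignment per region required")
    W = rng.dirichlet(np.full(n_archetypes, 0.15), size=n_regions)
    # tilt each mixture toward the assigned archetype
    W = 0.2 * W
    W[np.arange(n_regions), assignments] += 0.8
    P = W @ arch
    if noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd, size=P.shape)
    return P, assignments


# ---------------------------------------------------------------------------
# fixture meshes
# ---------------------------------------------------------------------------

def _surface_of_revolution(z: np.ndarray, r: np.ndarray, segments: int) -> trimesh.Trimesh:
    """Closed surface revolving radius profile r(z); r must vanish at the ends."""
    assert r[0] == 0 and r[-1] == 0 and np.all(r[1:-1] > 0)
    ang = np.linspace(0.0, 2.0 * np.pi, segments, endpoint=False)
    verts = [np.array([0.0, 0.0, z[0]])]
    for zi, ri in zip(z[1:-1], r[1:-1]):
        verts.extend(np.column_stack([
            ri * np.cos(ang), ri * np.sin(ang), np.full(segments, zi)
        ]))
    verts.append(np.array([0.0, 0.0, z[-1]]))
    V = np.vstack(verts)
    faces = []
    rings = len(z) - 2
    top = 0

    def ring(i, k):  # ring index i (0-based), segment k
        return 1 + i * segments + (k % segments)

    for k in range(segments):  # top cap (fan around first ring)
        faces.append([top, ring(0, k + 1), ring(0, k)])
    for i in range(rings - 1):
        for k in range(segments):
            a, b = ring(i, k), ring(i, k + 1)
            c, d = ring(i + 1, k), ring(i + 1, k + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    bottom = len(V) - 1
    for k in range(segments):
        faces.append([bottom, ring(rings - 1, k), ring(rings - 1, k + 1)])
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _bent_tube(scale: float, segments: int, stations: int) -> trimesh.Trimesh:
    """Capped tube swept along a 180-degree arc (genus 0, watertight)."""
    tube_r = 0.16 * scale
    arc_r = scale
    t = np.linspace(0.0, np.pi, stations)
    centers = np.column_stack([arc_r * np.cos(t), arc_r * np.sin(t), np.zeros_like(t)])
    tangents = np.column_stack([-np.sin(t), np.cos(t), np.zeros_like(t)])
    ang = np.linspace(0.0, 2.0 * np.pi, segments, endpoint=False)
    up = np.array([0.0, 0.0, 1.0])
    verts = [centers[0]]
    for c, tg in zip(centers, tangents):
        side = np.cross(up, tg)
        side /= np.linalg.norm(side)
        ring = c + tube_r * (np.outer(np.cos(ang), side) + np.outer(np.sin(ang), up))
        verts.extend(ring)
    verts.append(centers[-1])
    V = np.vstack(verts)
    faces = []

    def ring(i, k):
        return 1 + i * segments + (k % segments)

    for k in range(segments):
        faces.append([0, ring(0, k), ring(0, k + 1)])
    for i in range(stations - 1):
        for k in range(segments):
            a, b = ring(i, k), ring(i, k + 1)
            c, d = ring(i + 1, k), ring(i + 1, k + 1)
            faces.append([a, d, b])
            faces.append([a, c, d])
    bottom = len(V) - 1
    for k in range(segments):
        faces.append([bottom, ring(stations - 1, k + 1), ring(stations - 1, k)])
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def make_fixture_meshes(kind: str, scale: float = 1.0, resolution: int = 4) -> trimesh.Trimesh:
    """Watertight oriented fixture meshes: icosphere, bent-tube, dumbbell.

    ``resolution`` controls icosphere subdivisions and the station/ring
    density of the swept and revolved fixtures.
    """
    if kind == "icosphere":
        return trimesh.creation.icosphere(subdivisions=resolution, radius=scale)
    if kind == "bent-tube":
        return _bent_tube(scale, segments=4 * resolution, stations=12 * resolution)
    if kind == "dumbbell":
        k = 16 * resolution
        z = np.linspace(0.0, 2.0 * scale, k)
        bulb_r, neck_r = 0.45 * scale, 0.12 * scale
        c1, c2 = 0.45 * scale, 1.55 * scale
        b1 = bulb_r ** 2 - (z - c1) ** 2
        b2 = bulb_r ** 2 - (z - c2) ** 2
        r = np.sqrt(np.maximum.reduce([b1, b2, np.zeros_like(z)]))
        neck = (z > c1) & (z < c2)
        r[neck] = np.maximum(r[neck], neck_r)
        r[0] = r[-1] = 0.0
        r[1:-1] = np.maximum(r[1:-1], 0.02 * scale)
        return _surface_of_revolution(z, r, segments=6 * resolution)
    raise ValueError(f"unknown fixture kind {kind!r}")
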