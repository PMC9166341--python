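"""Sequential stochastic edge-addition generative models.

Networks grow from an (optionally empty) adjacency matrix by adding one
edge at a time. Each unconnected pair (i, j) receives a connectivity
score theta_ij combining a wiring-cost kernel of the interregional
distance D_ij with either a topological term T_ij recomputed after every
accepted edge, or a fixed physiological constraint PC_ij. Scores are
turned into selection probabilities P_ij = theta_ij / sum(theta), and
an edge is drawn by inverse-CDF sampling over lexicographically ordered
candidates so that runs are reproducible bit-for-bit given a seed.

Formulations
------------
spatial             theta = exp(-eta D)
multiplicative      theta = exp(-eta D) * (T + eps)^gamma
additive            theta = exp(-eta D)/max + alpha * (T + eps)^gamma / max
additive-nogamma    additive with gamma fixed at 1
physio              theta = PC^gamma                 (no distance kernel)
spatial-physio      theta = exp(-eta D)/max + alpha * PC^gamma / max

Normalization maxima in the additive forms are taken over the current
candidate set (pairs not yet connected) at every iteration. In growth
variants the distance matrix changes across developmental stages, with a
per-stage quota of edges added under each geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics

FORMULATIONS = (
    "spatial",
    "multiplicative",
    "additive",
    "additive-nogamma",
    "physio",
    "spatial-physio",
)

KERNELS = ("exponential", "power-law")

#: Formulations whose score uses a topological term recomputed as the
#: network grows.
TOPOLOGY_FORMULATIONS = ("multiplicative", "additive", "additive-nogamma")

#: Formulations whose score uses a fixed physiological constraint matrix.
PHYSIO_FORMULATIONS = ("physio", "spatial-physio")


@dataclass(frozen=True)
class Params:
    """Wiring-rule parameters.

    eta : distance-decay coefficient (per mm). Applied as exp(-eta * D),
        so larger eta means a stronger penalty on long connections.
    gamma : exponent of the topological / physiological term.
    alpha : weight of the topology term in the additive forms (>= 0).
    """

    eta: float = 0.0
    gamma: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass(frozen=True)
class ModelSpec:
    """Identity of a wiring rule: formulation, term, kernel, variant."""

    formulation: str = "additive"
    term: str | None = "matching"
    kernel: str = "exponential"
    epsilon: float = 1e-6
    growth: bool = False

    def __post_init__(self):
        if self.formulation not in FORMULATIONS:
            raise ValueError(
                f"unknown formulation {self.formulation!r}; expected {FORMULATIONS}"
            )
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; expected {KERNELS}")
        if self.uses_topology:
            if self.term not in metrics.TERM_NAMES:
                raise ValueError(
                    f"formulation {self.formulation!r} needs a topological term, "
                    f"got {self.term!r}"
                )
        elif self.formulation == "spatial" and self.term is not None:
            raise ValueError("spatial model takes no term")
        if self.kernel == "power-law":
            if self.formulation != "multiplicative":
                raise ValueError(
                    "power-law kernel is only offered for the multiplicative form"
                )
            if self.growth:
                raise ValueError(
                    "growth variants use the exponential kernel (a power law is "
                    "scale-invariant, so geometry growth would have no effect)"
                )
        if self.formulation == "physio" and self.growth:
            raise ValueError("physio-only model has no distance term to grow")

    @property
    def uses_topology(self) -> bool:
        return self.formulation in TOPOLOGY_FORMULATIONS

    @property
    def uses_constraint(self) -> bool:
        return self.formulation in PHYSIO_FORMULATIONS

    @property
    def uses_distance(self) -> bool:
        return self.formulation != "physio"


def edge_quota(E: int, T: int) -> list[int]:
    """Per-stage edge counts for a constant formation rate.

    quota(t) = floor(E t / T) - floor(E (t-1) / T); the quotas sum to E
    and differ by at most 1 across stages.
    """
    if E < 0 or T < 1:
        raise ValueError("need E >= 0 and T >= 1")
    cum = [E * t // T for t in range(T + 1)]
    return [cum[t + 1] - cum[t] for t in range(T)]


def _validate_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    return D


@dataclass
class DistanceSet:
    """One distance matrix, or an ordered developmental sequence D(t).

    ``matrices[t]`` is the geometry in force while stage-t edges are
    added; ``eval_matrix`` (default: the last matrix) defines edge
    lengths at evaluation time. Optional ``quotas`` fix the per-stage
    edge counts; by default they are derived from ``edge_quota``.
    """

    matrices: list[np.ndarray] = field(default_factory=list)
    eval_matrix: np.ndarray | None = None
    quotas: list[int] | None = None

    def __post_init__(self):
        if not self.matrices:
            raise ValueError("DistanceSet needs at least one distance matrix")
        self.matrices = [_validate_distance(D) for D in self.matrices]
        n = self.matrices[0].shape[0]
        if any(D.shape[0] != n for D in self.matrices):
            raise ValueError("all distance matrices must be conformable")
        if self.eval_matrix is None:
            self.eval_matrix = self.matrices[-1]
        else:
            self.eval_matrix = _validate_distance(self.eval_matrix)
            if self.eval_matrix.shape[0] != n:
                raise ValueError("evaluation matrix must be conformable")
        if self.quotas is not None and len(self.quotas) != len(self.matrices):
            raise ValueError("one quota per stage required")

    @classmethod
    def static(cls, D) -> "DistanceSet":
        return cls(matrices=[np.asarray(D, dtype=float)])

    @property
    def n_nodes(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def n_stages(self) -> int:
        return len(self.matrices)

    def stage_quotas(self, E: int) -> list[int]:
        if self.quotas is not None:
            if sum(self.quotas) != E:
                raise ValueError(
                    f"explicit quotas sum to {sum(self.quotas)}, expected E={E}"
                )
            return list(self.quotas)
        return edge_quota(E, self.n_stages)


def _kernel_vector(spec: ModelSpec, params: Params, dvec: np.ndarray) -> np.ndarray:
    if spec.kernel == "exponential":
        return np.exp(-params.eta * dvec)
    return (dvec + spec.epsilon) ** (-params.eta)


def _score_vectors(
    spec: ModelSpec,
    params: Params,
    kvec: np.ndarray | None,
    tvec: np.ndarray | None,
) -> np.ndarray:
    """Scores over the candidate set from kernel / term value vectors."""
    f = spec.formulation
    if f == "spatial":
        return kvec.copy()
    if f == "multiplicative":
        return kvec * (tvec + spec.epsilon) ** params.gamma
    if f == "physio":
        return tvec ** params.gamma
    gamma = 1.0 if f == "additive-nogamma" else params.gamma
    dmax = kvec.max()
    theta = kvec / dmax if dmax > 0 else np.zeros_like(kvec)
    if f in ("additive", "additive-nogamma"):
        if tvec.max() <= 0:
            # raw topology identically zero over candidates: its normalized
            # contribution is defined as 0 rather than 0/0
            return theta
        tv = (tvec + spec.epsilon) ** gamma
    else:  # spatial-physio; constraint is strictly positive already
        tv = tvec ** gamma
    tmax = tv.max()
    if tmax > 0:
        theta = theta + params.alpha * (tv / tmax)
    return theta


def score_edges(spec, params, D, T_or_PC=None, candidates=None) -> np.ndarray:
    """Connectivity scores theta over a candidate pair set.

    ``candidates`` is a sequence of (i, j) pairs (defaults to all
    off-diagonal upper-triangle pairs). ``T_or_PC`` is the topological
    term or physiological constraint matrix where the formulation needs
    one. Returns theta in candidate order.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if candidates is None:
        iu, ju = np.triu_indices(n, k=1)
    else:
        candidates = np.asarray(candidates)
        if candidates.size == 0:
            raise ValueError("candidate set must be nonempty")
        iu, ju = candidates[:, 0], candidates[:, 1]
    kvec = _kernel_vector(spec, params, D[iu, ju]) if spec.uses_distance else None
    tvec = None
    if spec.uses_topology or spec.uses_constraint:
        if T_or_PC is None:
            raise ValueError(f"formulation {spec.formulation!r} needs a term matrix")
        T = np.asarray(T_or_PC, dtype=float)
        tvec = T[iu, ju]
    theta = _score_vectors(spec, params, kvec, tvec)
    if np.all(theta <= 0):
        raise ValueError("all candidate scores are zero: no viable edge")
    return theta


def selection_probabilities(theta) -> np.ndarray:
    """Normalize scores to selection probabilities P = theta / sum(theta)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("scores must be nonnegative")
    total = theta.sum()
    if total <= 0:
        raise ValueError("sum of scores is zero: no viable edge")
    return theta / total


class _TermTracker:
    """Topology term matrix kept current as edges are added.

    Adding edge (a, b) only changes term entries for pairs involving an
    affected node: {a, b} for degree-, matching- and common-neighbor
    based terms, plus the common neighbors of a and b for clustering
    terms (their triangle counts change). Only those rows/columns are
    recomputed, which keeps the per-edge cost O(|affected| * n) while
    remaining exactly equal to a full recompute.
    """

    def __init__(self, name: str, A: np.ndarray):
        self.name = name
        self.A = A  # shared with grow(); mutated in place there
        self.T = metrics.topo_term(name, A)
        if name.startswith("clu"):
            self._c = metrics.clustering(A)

    def add_edge(self, a: int, b: int) -> None:
        A = self.A
        if self.name.startswith("clu"):
            common = np.flatnonzero(A[a] * A[b])
            S = np.unique(np.concatenate([[a, b], common])).astype(np.int64)
            tri = np.einsum("in,nm,im->i", A[S], A, A[S]) / 2.0
            d = A[S].sum(axis=1)
            denom = d * (d - 1.0)
            c = np.zeros(len(S))
            ok = denom > 0
            c[ok] = 2.0 * tri[ok] / denom[ok]
            self._c[S] = c
        else:
            S = np.array([a, b], dtype=np.int64)
        self._recompute_rows(S)

    def _recompute_rows(self, S: np.ndarray) -> None:
        A = self.A
        name = self.name
        if name == "matching":
            d = A.sum(axis=1)
            C = A[S] @ A
            union = d[S][:, None] + d[None, :] - 2.0 * A[S] - C
            rows = np.zeros_like(C)
            ok = union > 0
            rows[ok] = C[ok] / union[ok]
        elif name == "neighbors":
            rows = A[S] @ A
        else:
            family, combiner = name.split("-")
            x = self._c if family == "clu" else A.sum(axis=1)
            rows = _pairwise_rows(combiner, x[S], x)
        rows[np.arange(len(S)), S] = 0.0
        self.T[S, :] = rows
        self.T[:, S] = rows.T


def _pairwise_rows(combiner: str, xs: np.ndarray, x: np.ndarray) -> np.ndarray:
    if combiner == "avg":
        return (xs[:, None] + x[None, :]) / 2.0
    if combiner == "diff":
        return np.abs(xs[:, None] - x[None, :])
    if combiner == "max":
        return np.maximum(xs[:, None], x[None, :])
    if combiner == "min":
        return np.minimum(xs[:, None], x[None, :])
    return xs[:, None] * x[None, :]  # prod


@dataclass(frozen=True)
class GrowthLog:
    """Per-edge record of a model run: (i, j, stage) in addition order."""

    edges: list[tuple[int, int, int]]
    seed: int | None
    quotas: list[int]


def grow(
    spec: ModelSpec,
    params: Params,
    dset: DistanceSet,
    E: int,
    seed: int | None = None,
    *,
    constraint: np.ndarray | None = None,
    seed_network: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    return_log: bool = False,
):
    """Grow a network of exactly ``E`` edges under a wiring rule.

    Candidate pairs are ordered lexicographically by (i, j); one uniform
    variate is consumed per accepted edge (inverse-CDF sampling), so a
    given seed reproduces the run exactly. In growth variants, stage t
    adds ``quota(t)`` edges under geometry ``dset.matrices[t]``;
    topological terms are recomputed after every accepted edge.
    """
    n = dset.n_nodes
    capacity = n * (n - 1) // 2
    if spec.uses_constraint:
        if constraint is None:
            raise ValueError(f"formulation {spec.formulation!r} needs a constraint matrix")
        constraint = np.asarray(constraint, dtype=float)
        if constraint.shape != (n, n):
            raise ValueError("constraint matrix must be conformable with the geometry")
    if spec.growth and dset.n_stages < 2:
        # permitted: a growth spec over a single geometry reduces to static
        pass
    if rng is None:
        rng = np.random.default_rng(seed)

    A = np.zeros((n, n))
    if seed_network is not None:
        A = metrics.validate_adjacency(seed_network).copy()
    e0 = int(A.sum()) // 2
    if e0 + E > capacity:
        raise ValueError(f"cannot add {E} edges: capacity {capacity}, seeded {e0}")

    iu, ju = np.triu_indices(n, k=1)  # lexicographic by construction
    avail = A[iu, ju] == 0
    quotas = dset.stage_quotas(E)

    pcvec = None
    if spec.uses_constraint:
        # constraint is fixed; its gamma power over pairs is precomputed
        pcvec = constraint[iu, ju] ** params.gamma
    tracker = _TermTracker(spec.term, A) if spec.uses_topology else None
    # flat indices into the term matrix, one gather per iteration
    flat_pairs = iu * n + ju

    log: list[tuple[int, int, int]] = []
    for stage, quota in enumerate(quotas):
        if quota == 0:
            continue
        D = dset.matrices[stage]
        kall = _kernel_vector(spec, params, D[iu, ju]) if spec.uses_distance else None
        for _ in range(quota):
            idx = np.flatnonzero(avail)
            kvec = kall[idx] if kall is not None else None
            if spec.uses_topology:
                tvec = tracker.T.ravel()[flat_pairs[idx]]
                theta = _score_vectors(spec, params, kvec, tvec)
            elif spec.uses_constraint:
                if spec.formulation == "physio":
                    theta = pcvec[idx]
                else:
                    tv = pcvec[idx]
                    dmax = kvec.max()
                    theta = kvec / dmax if dmax > 0 else np.zeros_like(kvec)
                    tmax = tv.max()
                    if tmax > 0:
                        theta = theta + params.alpha * (tv / tmax)
            else:
                theta = kvec
            cum = np.cumsum(theta)
            total = cum[-1]
            if total <= 0:
                raise ValueError("all candidate scores are zero: no viable edge")
            u = rng.random() * total
            pick = int(np.searchsorted(cum, u, side="right"))
            pick = min(pick, len(idx) - 1)
            k = idx[pick]
            i, j = int(iu[k]), int(ju[k])
            A[i, j] = A[j, i] = 1.0
            avail[k] = False
            if tracker is not None:
                tracker.add_edge(i, j)
            log.append((i, j, stage))

    if return_log:
        return A, GrowthLog(edges=log, seed=seed, quotas=quotas)
    return A
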