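"""Binary graph measures, topological wiring-rule terms, and physiological
constraint matrices.

The generative models score candidate edges with a matrix ``T`` computed
from the current network (one of 12 topological rules) or with a fixed
physiological constraint matrix ``PC`` derived from interregional
similarity data (correlated gene expression, CGE, or microstructural
profile covariance, MPC). This module provides all of those quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import optimize as sp_optimize

logger = logging.getLogger(__name__)

#: The 12 topological wiring-rule terms.
TERM_NAMES = (
    "clu-avg", "clu-diff", "clu-max", "clu-min", "clu-prod",
    "deg-avg", "deg-diff", "deg-max", "deg-min", "deg-prod",
    "matching", "neighbors",
)

#: Physiological constraint modes.
CONSTRAINT_MODES = ("uCGE", "cCGE", "MPC")

#: Floor applied to constraint matrices after the +1 shift, so that
#: scores remain strictly positive even when residuals undershoot -1.
CONSTRAINT_FLOOR = 1e-6


class DecayFitError(RuntimeError):
    """Exponential distance-decay fit failed or is degenerate.

    Carries the best iterate found (``fit`` attribute) and a diagnostic
    message.
    """

    def __init__(self, message: str, fit: "DecayFit | None" = None):
        super().__init__(message)
        self.fit = fit


def validate_adjacency(A) -> np.ndarray:
    """Check that ``A`` is a binary, symmetric, zero-diagonal matrix.

    Returns the validated array as float64 (values 0/1).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    return A


@dataclass(frozen=True)
class NodeMetricSet:
    """Nodal degree, clustering coefficient and betweenness centrality."""

    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray


def degrees(A: np.ndarray) -> np.ndarray:
    """Node degrees (row sums of the adjacency matrix)."""
    return np.asarray(A, dtype=float).sum(axis=1)


def clustering(A: np.ndarray) -> np.ndarray:
    """Local clustering coefficient c_i = 2 t_i / (d_i (d_i - 1)).

    ``t_i`` is the number of triangles through node i. Nodes with degree
    below 2 get c_i = 0.
    """
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = d * (d - 1.0)
    c = np.zeros_like(d)
    ok = denom > 0
    c[ok] = 2.0 * tri[ok] / denom[ok]
    return c


def betweenness(A: np.ndarray) -> np.ndarray:
    """Unnormalized, unweighted node betweenness (endpoints excluded).

    For undirected graphs each node pair contributes once, i.e. the sum
    over unordered pairs {s, t} of the fraction of s-t shortest paths
    passing through the node.
    """
    A = np.asarray(A)
    src, dst = np.nonzero(np.triu(A))
    g = ig.Graph(n=A.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    return np.asarray(g.betweenness(), dtype=float)


def node_metrics(A) -> NodeMetricSet:
    """Degree, clustering, and betweenness for every node of ``A``."""
    A = validate_adjacency(A)
    return NodeMetricSet(
        degree=degrees(A), clustering=clustering(A), betweenness=betweenness(A)
    )


def matching_index(A) -> np.ndarray:
    """Matching index: overlap of neighborhoods excluding the pair itself.

    T_ij = |N_i\\j ∩ N_j\\i| / |N_i\\j ∪ N_j\\i|, with 0/0 defined as 0.
    """
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    common = A @ A  # counts k adjacent to both i and j; k = i, j excluded by zero diagonal
    union = d[:, None] + d[None, :] - 2.0 * A - common
    T = np.zeros_like(common)
    ok = union > 0
    T[ok] = common[ok] / union[ok]
    np.fill_diagonal(T, 0.0)
    return T


def neighbors_count(A) -> np.ndarray:
    """Number of common neighbors: sum_k A_ik A_jk (off-diagonal of A^2)."""
    A = np.asarray(A, dtype=float)
    T = A @ A
    np.fill_diagonal(T, 0.0)
    return T


def _pairwise(name: str, x: np.ndarray) -> np.ndarray:
    if name == "avg":
        return (x[:, None] + x[None, :]) / 2.0
    if name == "diff":
        return np.abs(x[:, None] - x[None, :])
    if name == "max":
        return np.maximum(x[:, None], x[None, :])
    if name == "min":
        return np.minimum(x[:, None], x[None, :])
    if name == "prod":
        return x[:, None] * x[None, :]
    raise AssertionError(name)


def topo_term(name: str, A) -> np.ndarray:
    """One of the 12 topological term matrices, by name.

    ``clu-*`` terms combine nodal clustering coefficients, ``deg-*``
    terms nodal degrees (avg/diff/max/min/prod); ``matching`` is the
    matching index and ``neighbors`` the common-neighbor count. The
    ``*-avg`` combinations are arithmetic means.
    """
    if name not in TERM_NAMES:
        raise ValueError(
            f"unknown topological term {name!r}; expected one of {TERM_NAMES}"
        )
    A = np.asarray(A, dtype=float)
    if name == "matching":
        T = matching_index(A)
    elif name == "neighbors":
        T = neighbors_count(A)
    else:
        family, combiner = name.split("-")
        x = clustering(A) if family == "clu" else degrees(A)
        T = _pairwise(combiner, x)
    np.fill_diagonal(T, 0.0)
    return T


@dataclass(frozen=True)
class DecayFit:
    """Least-squares parameters of r(D) = p1 * exp(-p2 * D) + p3."""

    p1: float
    p2: float
    p3: float

    def __call__(self, D) -> np.ndarray:
        return self.p1 * np.exp(-self.p2 * np.asarray(D, dtype=float)) + self.p3


def _decay_model(d, p1, p2, p3):
    return p1 * np.exp(-p2 * d) + p3


def fit_distance_decay(S, D) -> DecayFit:
    """Fit the exponential distance decay r(D) = p1 exp(-p2 D) + p3.

    The fit is over the strict upper triangle of the conformable
    symmetric matrices ``S`` (similarity) and ``D`` (distance).
    Initialization: p1 = range(S), p2 = 1 / median(D), p3 = min(S),
    with p2 bounded positive.

    Raises
    ------
    DecayFitError
        If the optimizer does not converge, or the fitted decay is
        degenerate (amplitude ~ 0 so the length scale is unidentified).
        The exception carries the best iterate on its ``fit`` attribute.
    """
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    if S.shape != D.shape:
        raise ValueError("similarity and distance matrices must be conformable")
    iu = np.triu_indices_from(S, k=1)
    s, d = S[iu], D[iu]
    if len(np.unique(np.round(np.c_[s, d], 12), axis=0)) < 4:
        raise ValueError("need at least 4 distinct upper-triangle pairs")
    srange = float(s.max() - s.min())
    p0 = [srange if srange > 0 else 1.0, 1.0 / max(np.median(d), 1e-12), float(s.min())]
    try:
        popt, _ = sp_optimize.curve_fit(
            _decay_model, d, s, p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger deterministically
        raise DecayFitError(f"decay fit did not converge: {exc}", fit=None) from exc
    fit = DecayFit(*(float(p) for p in popt))
    scale = max(abs(s).max(), 1.0)
    if abs(fit.p1) < 1e-8 * scale:
        raise DecayFitError(
            "degenerate decay fit: amplitude p1 ~ 0 (no distance decay present)",
            fit=fit,
        )
    return fit


def make_constraint(S, mode: str, D=None, floor: float = CONSTRAINT_FLOOR) -> np.ndarray:
    """Shifted, strictly positive physiological constraint matrix PC.

    ``uCGE`` / ``MPC``: PC = S + 1. ``cCGE``: PC = S - r(D) + 1 where
    r is the exponential distance-decay fit of S on D. Values that are
    not positive after the shift are floored at ``floor`` and counted in
    a warning log. The diagonal is set to 0 (never used as a candidate).
    """
    if mode not in CONSTRAINT_MODES:
        raise ValueError(f"unknown constraint mode {mode!r}; expected {CONSTRAINT_MODES}")
    S = np.asarray(S, dtype=float)
    if mode == "cCGE":
        if D is None:
            raise ValueError("cCGE requires a distance matrix")
        decay = fit_distance_decay(S, D)
        PC = S - decay(D) + 1.0
    else:
        PC = S + 1.0
    off = ~np.eye(PC.shape[0], dtype=bool)
    n_floored = int(np.count_nonzero(PC[off] <= 0))
    if n_floored:
        logger.warning(
            "constraint matrix (%s): floored %d non-positive entries at %g",
            mode, n_floored, floor,
        )
    PC = np.maximum(PC, floor)
    np.fill_diagonal(PC, 0.0)
    return PC


def mpc_from_profiles(P) -> np.ndarray:
    """Microstructural profile covariance from depth-intensity profiles.

    ``P`` has one row per region and one column per cortical depth
    sample. The MPC of regions i and j is the partial correlation of
    their profiles controlling for the cortex-wide mean profile m:

        S_ij = (r_ij - r_im r_jm) / sqrt((1 - r_im^2)(1 - r_jm^2))

    The diagonal is set to 0 (excluded by convention).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3 or P.shape[1] < 3:
        raise ValueError("need at least 3 regions and 3 depth samples")
    sd = P.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region {bad} has a zero-variance profile")
    m = P.mean(axis=0)
    R = np.corrcoef(np.vstack([P, m]))
    r = R[:-1, :-1]
    rm = R[:-1, -1]
    denom = np.sqrt((1.0 - rm[:, None] ** 2) * (1.0 - rm[None, :] ** 2))
    if np.any(denom == 0):
        bad = int(np.flatnonzero(np.abs(rm) >= 1.0)[0])
        raise ValueError(
            f"region {bad} is perfectly correlated with the mean profile; "
            "partial correlation undefined"
        )
    S = (r - rm[:, None] * rm[None, :]) / denom
    np.fill_diagonal(S, 0.0)
    return S
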