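"""Adaptive parameter search over wiring-rule parameters.

The search starts with a uniform random sample of the parameter box,
then repeatedly (i) treats every evaluated point as the site of a
Voronoi cell, (ii) picks cells with probability proportional to
fit^(-b) — smaller max(KS) is better, so larger b concentrates sampling
on well-fitting cells — and (iii) draws new points uniformly inside the
chosen cells. Cell-uniform draws are realized by rejection: propose
uniformly in the box and accept when the nearest site (Euclidean after
per-axis min-max standardization by the box bounds) is the chosen one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import engine, evaluation, metrics
from ._seeds import derive_seed

logger = logging.getLogger(__name__)

#: Floor for fit values before raising to the -b power.
FIT_FLOOR = 1e-6

#: Fit recorded when the objective raises on a point.
WORST_FIT = 1.0


@dataclass(frozen=True)
class SearchSpace:
    """Closed parameter intervals, one per active parameter."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1 or len(self.names) != lo.size:
            raise ValueError("names, lower and upper must have matching lengths")
        if np.any(lo > hi):
            raise ValueError("need lower <= upper for every parameter")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def from_bounds(cls, **bounds: tuple[float, float]) -> "SearchSpace":
        names = tuple(bounds)
        lo = np.array([bounds[k][0] for k in names], dtype=float)
        hi = np.array([bounds[k][1] for k in names], dtype=float)
        return cls(names=names, lower=lo, upper=hi)

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.upper - self.lower))

    def standardize(self, X: np.ndarray) -> np.ndarray:
        """Per-axis min-max standardization by the box bounds."""
        span = np.where(self.upper > self.lower, self.upper - self.lower, 1.0)
        return (np.atleast_2d(X) - self.lower) / span

    def to_params(self, x: np.ndarray) -> engine.Params:
        d = dict(zip(self.names, np.asarray(x, dtype=float)))
        return engine.Params(
            eta=d.get("eta", 0.0), gamma=d.get("gamma", 1.0), alpha=d.get("alpha", 1.0)
        )


# Parameter ranges used for the connectome models: the distance-decay
# coefficient spans magnitude 0..2, gamma -8..8, alpha 0..8. The
# no-gamma additive variant restricts alpha to 0..0.05 for degree- and
# clustering-based terms whose raw scale is much larger than matching.
_NOGAMMA_SMALL_ALPHA_TERMS = (
    "clu-avg", "clu-max", "clu-diff", "deg-avg", "deg-max", "deg-diff", "deg-prod",
)


def default_search_space(
    spec: engine.ModelSpec, constraint_kind: str | None = None
) -> SearchSpace:
    """Default parameter box for a model specification.

    ``constraint_kind`` ("CGE" or "MPC") selects the wider gamma ranges
    used for physiological constraint models.
    """
    f = spec.formulation
    if f == "spatial":
        return SearchSpace.from_bounds(eta=(0.0, 2.0))
    if f == "multiplicative":
        return SearchSpace.from_bounds(eta=(0.0, 2.0), gamma=(-8.0, 8.0))
    if f == "additive":
        return SearchSpace.from_bounds(
            eta=(0.0, 2.0), gamma=(-8.0, 8.0), alpha=(0.0, 8.0)
        )
    if f == "additive-nogamma":
        hi = 0.05 if spec.term in _NOGAMMA_SMALL_ALPHA_TERMS else 8.0
        return SearchSpace.from_bounds(eta=(0.0, 2.0), alpha=(0.0, hi))
    gamma_range = {"CGE": (-50.0, 250.0), "MPC": (0.0, 50.0)}.get(
        constraint_kind or "CGE", (-50.0, 250.0)
    )
    if f == "physio":
        return SearchSpace.from_bounds(gamma=gamma_range)
    # spatial-physio
    return SearchSpace.from_bounds(eta=(0.0, 2.0), gamma=gamma_range, alpha=(0.0, 8.0))


@dataclass(frozen=True)
class Schedule:
    """Sampling budget: points per round and the b value of each round."""

    points_per_round: int = 2000
    b_values: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    repeats: int = 1

    def __post_init__(self):
        if self.points_per_round < 1 or self.repeats < 1 or not self.b_values:
            raise ValueError("invalid schedule")
        if self.b_values[0] != 0.0:
            raise ValueError("first round must be uniform (b = 0)")

    @property
    def n_rounds(self) -> int:
        return len(self.b_values)

    @property
    def budget(self) -> int:
        return self.n_rounds * self.points_per_round


@dataclass
class Trace:
    """Evaluated points, their fits, and the round each came from."""

    space: SearchSpace
    points: np.ndarray
    fits: np.ndarray
    rounds: np.ndarray
    seed: int | None = None

    def best_index(self) -> int:
        return int(np.argmin(self.fits))

    def best(self) -> tuple[np.ndarray, float]:
        i = self.best_index()
        return self.points[i], float(self.fits[i])


def initial_sample(space: SearchSpace, n: int, rng) -> np.ndarray:
    """Uniform sample of n points on the parameter box."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(rng)
    return rng.uniform(space.lower, space.upper, size=(n, space.dim))


def voronoi_weights(fits, b: float, floor: float = FIT_FLOOR) -> np.ndarray:
    """Cell-selection probabilities w_c ∝ fit_c^(-b), fits floored at ``floor``."""
    fits = np.maximum(np.asarray(fits, dtype=float), floor)
    logw = -b * np.log(fits)
    logw -= logw.max()  # stabilize before exponentiation
    w = np.exp(logw)
    return w / w.sum()


def _cell_cover_box(Z: np.ndarray, cell: int, n_neighbors: int = 64):
    """Axis-aligned cover of a Voronoi cell in standardized coordinates.

    The cell of site c is the intersection of [0, 1]^d with the
    halfspaces (z - c) . (s - c) <= |s - c|^2 / 2 over other sites s.
    Bounding each coordinate by linear programming over a *subset* of
    those halfspaces (the nearest sites) yields a relaxation, i.e. a box
    guaranteed to contain the cell, so rejection inside it stays exact
    while the acceptance rate no longer collapses for small cells.
    """
    from scipy.optimize import linprog

    c = Z[cell]
    d = Z.shape[1]
    others = np.delete(np.arange(len(Z)), cell)
    if others.size > n_neighbors:
        near = np.argsort(((Z[others] - c) ** 2).sum(axis=1))[:n_neighbors]
        others = others[near]
    delta = Z[others] - c
    r = float(np.sqrt((delta ** 2).sum(axis=1).max()))
    if r == 0:  # duplicated sites: the cell is degenerate
        return c.copy(), c.copy()
    # solve in site-centered coordinates y = (z - c) / r: when refinement
    # clusters sites at scales far below the box, the raw formulation
    # loses the cell geometry to the LP solver's absolute feasibility
    # tolerance and the cover inflates by orders of magnitude
    A_ub = delta / r
    b_ub = (delta ** 2).sum(axis=1) / (2.0 * r * r)
    y_bounds = [((0.0 - c[k]) / r, (1.0 - c[k]) / r) for k in range(d)]
    lo = np.zeros(d)
    hi = np.ones(d)
    for k in range(d):
        cvec = np.zeros(d)
        for sign, store in ((1.0, "lo"), (-1.0, "hi")):
            cvec[k] = sign
            res = linprog(cvec, A_ub=A_ub, b_ub=b_ub, bounds=y_bounds,
                          method="highs")
            if res.status == 0:
                val = c[k] + r * res.x[k]
                if store == "lo":
                    lo[k] = val
                else:
                    hi[k] = val
    lo = np.minimum(lo, c)
    hi = np.maximum(hi, c)
    # small margin against LP round-off shaving the true extremes
    span = np.maximum(hi - lo, 1e-15)
    return np.clip(lo - 1e-6 * span, 0, 1), np.clip(hi + 1e-6 * span, 0, 1)


def sample_in_cell(
    points: np.ndarray,
    cell: int,
    space: SearchSpace,
    rng,
    max_attempts: int = 1_000_000,
    tree: cKDTree | None = None,
    cover: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Uniform draw from the Voronoi cell of ``points[cell]``.

    Rejection sampling: propose uniformly, accept when the nearest site
    (Euclidean, per-axis min-max standardized by the box bounds) is the
    chosen cell's site. Proposals are drawn inside an axis-aligned cover
    of the cell (see :func:`_cell_cover_box`), which leaves the accepted
    distribution exactly cell-uniform but keeps the acceptance rate
    bounded for small cells.
    """
    rng = np.random.default_rng(rng)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if tree is None:
        tree = cKDTree(space.standardize(points))
    if len(points) == 1:
        return rng.uniform(space.lower, space.upper, size=space.dim)
    Z = space.standardize(points)
    lo, hi = cover if cover is not None else _cell_cover_box(Z, cell)
    span = np.where(space.upper > space.lower, space.upper - space.lower, 1.0)
    batch = 64
    attempts = 0
    while attempts < max_attempts:
        m = min(batch, max_attempts - attempts)
        Zx = rng.uniform(lo, hi, size=(m, Z.shape[1]))
        _, nearest = tree.query(Zx, k=1)
        hit = np.flatnonzero(nearest == cell)
        if hit.size:
            return space.lower + Zx[hit[0]] * span
        attempts += m
        batch = min(batch * 2, 16384)
    raise RuntimeError(
        f"could not draw a point from Voronoi cell {cell} within {max_attempts} "
        "proposals; the cell may be vanishingly small (shrink the trace or "
        "enlarge the box)"
    )


@dataclass(frozen=True)
class OptimizeResult:
    best_params: engine.Params
    best_point: np.ndarray
    best_fit: float
    trace: Trace


def optimize(objective, space: SearchSpace, schedule: Schedule, seed=None) -> OptimizeResult:
    """Run the adaptive search.

    ``objective(x, seed)`` maps a parameter vector (in ``space.names``
    order) and an integer seed to a fit value in [0, 1] (lower is
    better). An objective failure on a point is recorded with the worst
    fit and the run continues. Identical seeds reproduce identical
    traces for a deterministic objective.
    """
    rng = np.random.default_rng(seed)
    n = schedule.points_per_round
    all_points = np.empty((0, space.dim))
    all_fits = np.empty(0)
    all_rounds = np.empty(0, dtype=int)

    for r, b in enumerate(schedule.b_values):
        if r == 0:
            X = initial_sample(space, n, rng)
        else:
            # tessellation frozen to the points evaluated before this round
            weights = voronoi_weights(all_fits, b)
            Z = space.standardize(all_points)
            tree = cKDTree(Z)
            cells = rng.choice(len(all_fits), size=n, p=weights)
            covers: dict[int, tuple] = {}
            X = np.empty((n, space.dim))
            for k, c in enumerate(cells):
                # a vanishingly small cell can defeat rejection sampling;
                # treat that like an objective failure: log, redraw another
                # cell, ultimately fall back to uniform exploration
                for attempt in range(8):
                    c = int(c)
                    if c not in covers:
                        covers[c] = _cell_cover_box(Z, c)
                    try:
                        X[k] = sample_in_cell(all_points, c, space, rng,
                                              tree=tree, cover=covers[c],
                                              max_attempts=200_000)
                        break
                    except RuntimeError:
                        logger.warning(
                            "cell %d unsampleable in round %d; redrawing", c, r)
                        c = rng.choice(len(all_fits), p=weights)
                else:
                    X[k] = rng.uniform(space.lower, space.upper,
                                       size=space.dim)
        fits = np.empty(n)
        for k in range(n):
            point_seed = derive_seed(seed if seed is not None else 0, r, k)
            try:
                vals = [
                    float(objective(X[k], derive_seed(point_seed, rep)))
                    for rep in range(schedule.repeats)
                ]
                fits[k] = float(np.mean(vals))
            except Exception:  # noqa: BLE001 - deliberately robust sweep
                logger.exception("objective failed at point %s (round %d)", X[k], r)
                fits[k] = WORST_FIT
        all_points = np.vstack([all_points, X])
        all_fits = np.concatenate([all_fits, fits])
        all_rounds = np.concatenate([all_rounds, np.full(n, r)])

    trace = Trace(space=space, points=all_points, fits=all_fits,
                  rounds=all_rounds, seed=seed)
    x_best, f_best = trace.best()
    return OptimizeResult(
        best_params=space.to_params(x_best),
        best_point=x_best,
        best_fit=f_best,
        trace=trace,
    )


def gnm_objective(
    spec: engine.ModelSpec,
    space: SearchSpace,
    dset: engine.DistanceSet,
    E: int,
    A_emp: np.ndarray,
    constraint: np.ndarray | None = None,
):
    """Objective closure: grow a network at x and return max(KS) vs A_emp."""
    A_emp = metrics.validate_adjacency(A_emp)

    def objective(x, obj_seed):
        params = space.to_params(x)
        A = engine.grow(spec, params, dset, E, seed=obj_seed, constraint=constraint)
        return evaluation.evaluate_fit(A, A_emp, dset.eval_matrix).max_ks

    return objective


def topography_scan(networks, A_emp, D_eval) -> tuple[float, int]:
    """Maximum degree-topography correlation over retained trace networks.

    Returns ``(max rho_degree, argmax index)``. Reporting only — never an
    optimization target.
    """
    if not len(networks):
        raise ValueError("no networks to scan")
    rhos = [
        evaluation.topography(A, A_emp, D_eval).rho_degree for A in networks
    ]
    rhos = np.asarray(rhos, dtype=float)
    if np.all(np.isnan(rhos)):
        return float("nan"), 0
    best = int(np.nanargmax(rhos))
    return float(rhos[best]), best
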