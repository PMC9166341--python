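"""Topological and topographical model fit.

Topological fit compares *distributions* of four benchmark properties —
node degree, node clustering, node betweenness, and edge length — between
a model network and an empirical network using the two-sample
Kolmogorov-Smirnov statistic; the overall fit is the worst (maximum) of
the four. Topographical fit instead compares the *spatial embedding* of
nodal properties via Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import metrics

#: Fixed tie-break priority when several measures attain the maximum KS.
KS_MEASURES = ("degree", "clustering", "betweenness", "edgelength")


def ks_statistic(x, y) -> float:
    """Two-sample KS statistic: sup_t |ECDF_x(t) - ECDF_y(t)|."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


@dataclass(frozen=True)
class FitResult:
    """Four KS statistics, their maximum, and which measure attained it."""

    ks_degree: float
    ks_clustering: float
    ks_betweenness: float
    ks_edgelength: float
    max_ks: float
    determinant: str

    def as_dict(self) -> dict:
        return {
            "ks_degree": self.ks_degree,
            "ks_clustering": self.ks_clustering,
            "ks_betweenness": self.ks_betweenness,
            "ks_edgelength": self.ks_edgelength,
            "max_ks": self.max_ks,
            "determinant": self.determinant,
        }


def _edge_lengths(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(A.shape[0], k=1)
    sel = A[iu, ju] > 0
    return D[iu[sel], ju[sel]]


def evaluate_fit(A_model, A_emp, D_eval) -> FitResult:
    """Topological fit of a model network against an empirical network.

    ``D_eval`` supplies edge lengths for both networks (for growth
    models this is the final-stage, adult geometry). Both networks must
    have at least one edge, otherwise the edge-length distribution is
    undefined.
    """
    A_model = metrics.validate_adjacency(A_model)
    A_emp = metrics.validate_adjacency(A_emp)
    D_eval = np.asarray(D_eval, dtype=float)
    if A_model.shape != A_emp.shape or A_model.shape != D_eval.shape:
        raise ValueError("model, empirical and distance matrices must be conformable")
    if A_model.sum() == 0 or A_emp.sum() == 0:
        raise ValueError("edgeless network: edge-length distribution undefined")

    mm = metrics.node_metrics(A_model)
    me = metrics.node_metrics(A_emp)
    ks = {
        "degree": ks_statistic(mm.degree, me.degree),
        "clustering": ks_statistic(mm.clustering, me.clustering),
        "betweenness": ks_statistic(mm.betweenness, me.betweenness),
        "edgelength": ks_statistic(
            _edge_lengths(A_model, D_eval), _edge_lengths(A_emp, D_eval)
        ),
    }
    max_ks = max(ks.values())
    determinant = next(m for m in KS_MEASURES if ks[m] == max_ks)
    return FitResult(
        ks_degree=ks["degree"],
        ks_clustering=ks["clustering"],
        ks_betweenness=ks["betweenness"],
        ks_edgelength=ks["edgelength"],
        max_ks=max_ks,
        determinant=determinant,
    )


@dataclass(frozen=True)
class TopographyResult:
    """Spearman correlations of nodal property maps (model vs empirical).

    A coefficient is NaN when either nodal vector is constant (rank
    correlation undefined) — deliberately not reported as 0.
    """

    rho_degree: float
    rho_clustering: float
    rho_betweenness: float
    rho_meandistance: float

    def as_dict(self) -> dict:
        return {
            "rho_degree": self.rho_degree,
            "rho_clustering": self.rho_clustering,
            "rho_betweenness": self.rho_betweenness,
            "rho_meandistance": self.rho_meandistance,
        }


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mean_connection_distance(A, D) -> np.ndarray:
    """Mean length of each node's connections (0 for isolated nodes)."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    d = A.sum(axis=1)
    total = (A * D).sum(axis=1)
    out = np.zeros_like(d)
    ok = d > 0
    out[ok] = total[ok] / d[ok]
    return out


def topography(A_model, A_emp, D_eval) -> TopographyResult:
    """Spearman correlation of nodal degree, clustering, betweenness and
    mean connection distance between model and empirical networks."""
    A_model = metrics.validate_adjacency(A_model)
    A_emp = metrics.validate_adjacency(A_emp)
    D_eval = np.asarray(D_eval, dtype=float)
    mm = metrics.node_metrics(A_model)
    me = metrics.node_metrics(A_emp)
    return TopographyResult(
        rho_degree=_spearman(mm.degree, me.degree),
        rho_clustering=_spearman(mm.clustering, me.clustering),
        rho_betweenness=_spearman(mm.betweenness, me.betweenness),
        rho_meandistance=_spearman(
            mean_connection_distance(A_model, D_eval),
            mean_connection_distance(A_emp, D_eval),
        ),
    )


def compare_fits(a, b, m: int = 1) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test with Bonferroni correction.

    Returns ``(p, min(1, m * p))`` for paired fit vectors ``a`` and
    ``b`` over the same subjects. If every paired difference is zero the
    p-value is 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fit vectors must be paired 1-D arrays of equal length")
    if a.size < 6:
        raise ValueError("need at least 6 paired observations")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if np.all(a == b):
        return 1.0, 1.0
    # exact null distribution where feasible (small n, no zero differences);
    # scipy's default falls back to a normal approximation when ranks tie
    method = "exact" if (a.size <= 25 and np.all(a != b)) else "auto"
    p = float(stats.wilcoxon(a, b, alternative="two-sided", method=method).pvalue)
    return p, min(1.0, m * p)
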