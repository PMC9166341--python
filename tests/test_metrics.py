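"""Graph measures, topological terms and physiological constraints."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from connectogen import metrics
from conftest import random_adjacency, random_distance


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_degree(A):
    return [sum(row) for row in A]


def brute_clustering(A):
    n = len(A)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        d = len(nbrs)
        if d < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if A[a][b]
        )
        out.append(2.0 * links / (d * (d - 1)))
    return out


def brute_betweenness(A):
    """Enumerate every path between each pair with DFS; count shortest ones."""
    n = len(A)
    b = [0.0] * n

    def all_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in range(n):
                if A[node][nxt] and nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sps = [p for p in paths if len(p) == shortest]
            for p in sps:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(sps)
    return b


def brute_matching(A):
    n = len(A)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            Ni = {k for k in range(n) if A[i][k]} - {j}
            Nj = {k for k in range(n) if A[j][k]} - {i}
            union = Ni | Nj
            T[i, j] = len(Ni & Nj) / len(union) if union else 0.0
    return T


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------

def test_triangle_graph_metrics():
    A = np.ones((3, 3)) - np.eye(3)
    m = metrics.node_metrics(A)
    assert np.allclose(m.clustering, 1.0)
    assert np.allclose(m.betweenness, 0.0)
    assert np.allclose(m.degree, 2.0)


def test_path_graph_metrics():
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
    m = metrics.node_metrics(A)
    assert m.betweenness[1] == 1.0
    assert m.betweenness[0] == m.betweenness[2] == 0.0
    assert np.allclose(m.clustering, 0.0)


@pytest.mark.parametrize("trial", range(25))
def test_node_metrics_match_bruteforce(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 13))
    A = random_adjacency(rng, n, p=float(rng.uniform(0.15, 0.6)))
    m = metrics.node_metrics(A)
    assert np.allclose(m.degree, brute_degree(A))
    assert np.allclose(m.clustering, brute_clustering(A))
    assert np.allclose(m.betweenness, brute_betweenness(A), atol=1e-9)


def test_adjacency_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="symmetric"):
        metrics.validate_adjacency([[0, 1], [0, 0]])
    with pytest.raises(ValueError, match="diagonal"):
        metrics.validate_adjacency([[1, 1], [1, 0]])
    with pytest.raises(ValueError, match="0 or 1"):
        metrics.validate_adjacency([[0, 2], [2, 0]])


# ---------------------------------------------------------------------------
# matching index and topological terms
# ---------------------------------------------------------------------------

def test_matching_shared_single_neighbor_is_one():
    # i=0 and j=1 each adjacent only to k=2
    A = np.zeros((3, 3))
    A[0, 2] = A[2, 0] = A[1, 2] = A[2, 1] = 1.0
    T = metrics.matching_index(A)
    assert T[0, 1] == 1.0


def test_matching_disjoint_neighborhoods_is_zero():
    A = np.zeros((4, 4))
    A[0, 2] = A[2, 0] = A[1, 3] = A[3, 1] = 1.0
    assert metrics.matching_index(A)[0, 1] == 0.0


@pytest.mark.parametrize("trial", range(20))
def test_matching_equals_set_oracle(trial):
    rng = np.random.default_rng(2000 + trial)
    n = int(rng.integers(4, 13))
    A = random_adjacency(rng, n, p=0.4)
    assert np.allclose(metrics.matching_index(A), brute_matching(A), atol=1e-12)


def test_term_simple_values():
    # clu-avg with c_i = 1, c_j = 0 -> 0.5: triangle plus pendant vertex
    A = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (0, 2), (2, 3)]:
        A[i, j] = A[j, i] = 1.0
    T = metrics.topo_term("clu-avg", A)
    c = metrics.clustering(A)
    assert c[0] == 1.0 and c[3] == 0.0
    assert T[0, 3] == 0.5
    # deg-diff vanishes for equal degrees
    Td = metrics.topo_term("deg-diff", A)
    d = metrics.degrees(A)
    same = d[:, None] == d[None, :]
    assert np.all(Td[same] == 0)


@pytest.mark.parametrize("trial", range(10))
def test_neighbors_equals_matrix_square(trial):
    rng = np.random.default_rng(3000 + trial)
    A = random_adjacency(rng, 10, p=0.4)
    T = metrics.topo_term("neighbors", A)
    sq = A @ A
    np.fill_diagonal(sq, 0)
    assert np.array_equal(T, sq)


@pytest.mark.parametrize("name", metrics.TERM_NAMES)
def test_terms_symmetric_nonnegative(name, rng):
    for _ in range(5):
        A = random_adjacency(rng, 12, p=0.35)
        T = metrics.topo_term(name, A)
        assert np.array_equal(T, T.T)
        assert np.all(T >= 0)
        assert np.all(np.diag(T) == 0)


def test_unknown_term_rejected():
    with pytest.raises(ValueError, match="unknown topological term"):
        metrics.topo_term("deg-mean", np.zeros((3, 3)))


@given(st.integers(0, 2**31 - 1))
def test_matching_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    A = random_adjacency(rng, int(rng.integers(3, 15)), p=0.4)
    T = metrics.matching_index(A)
    assert np.all((T >= 0) & (T <= 1))


# ---------------------------------------------------------------------------
# distance decay and constraints
# ---------------------------------------------------------------------------

def test_decay_fit_noiseless_recovery(rng):
    D = random_distance(rng, 40)
    S = 1.0 * np.exp(-0.02 * D) - 0.2
    np.fill_diagonal(S, 0)
    fit = metrics.fit_distance_decay(S, D)
    assert abs(fit.p1 - 1.0) < 1e-6
    assert abs(fit.p2 - 0.02) < 1e-6
    assert abs(fit.p3 + 0.2) < 1e-6


def test_decay_fit_constant_similarity_flagged(rng):
    D = random_distance(rng, 20)
    S = np.full_like(D, 0.3)
    with pytest.raises(metrics.DecayFitError) as err:
        metrics.fit_distance_decay(S, D)
    assert err.value.fit is None or abs(err.value.fit.p1) < 1e-6


def test_constraint_pure_shift(rng):
    n = 12
    S = np.zeros((n, n))
    PC = metrics.make_constraint(S, "uCGE")
    off = ~np.eye(n, dtype=bool)
    assert np.all(PC[off] == 1.0)


def test_constraint_ccge_noiseless_is_one(rng):
    D = random_distance(rng, 30)
    S = 0.8 * np.exp(-0.015 * D) - 0.1
    np.fill_diagonal(S, 0)
    PC = metrics.make_constraint(S, "cCGE", D=D)
    off = ~np.eye(30, dtype=bool)
    assert np.allclose(PC[off], 1.0, atol=1e-6)


def test_constraint_affine_order_preserving(rng):
    S = rng.uniform(-0.9, 0.9, (10, 10))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0)
    PC = metrics.make_constraint(S, "MPC")
    iu = np.triu_indices(10, 1)
    order_s = np.argsort(S[iu])
    order_pc = np.argsort(PC[iu])
    assert np.array_equal(order_s, order_pc)


def test_constraint_floor_applied():
    S = np.array([[0.0, -1.5], [-1.5, 0.0]])
    # -1.5 + 1 = -0.5 -> floored
    PC = metrics.make_constraint(S, "uCGE")
    assert PC[0, 1] == metrics.CONSTRAINT_FLOOR


# ---------------------------------------------------------------------------
# microstructural profile covariance
# ---------------------------------------------------------------------------

def mpc_regression_oracle(P):
    """Regress out the mean profile, then correlate residuals."""
    P = np.asarray(P, dtype=float)
    m = P.mean(axis=0)
    X = np.column_stack([np.ones_like(m), m])
    resid = P - (X @ np.linalg.lstsq(X, P.T, rcond=None)[0]).T
    R = np.corrcoef(resid)
    np.fill_diagonal(R, 0)
    return R


def test_mpc_identical_profiles_orthogonal_to_mean():
    x = np.linspace(0, 1, 20)
    base = np.sin(2 * np.pi * x)
    # regions 0,1 identical; 2,3 chosen so the mean is orthogonal to base
    P = np.vstack([base, base, -base + np.cos(2 * np.pi * x),
                   -base - np.cos(2 * np.pi * x)])
    S = metrics.mpc_from_profiles(P)
    assert S[0, 1] == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("trial", range(10))
def test_mpc_equals_regression_oracle(trial):
    rng = np.random.default_rng(4000 + trial)
    P = rng.normal(size=(8, 25))
    S = metrics.mpc_from_profiles(P)
    assert np.allclose(S, mpc_regression_oracle(P), atol=1e-10)


def test_mpc_mean_plus_noise_centred_near_zero():
    # profiles i, j each equal the shared base profile plus independent
    # noise: their partial correlation controlling the cortex-wide mean
    # is ~0 on average. Controlling the *empirical* mean leaves a known
    # finite-sample bias of about -1/(R-1) for R regions, so the check
    # runs at a region count where that bias sits inside Monte-Carlo
    # error of the simulation.
    rng = np.random.default_rng(99)
    x = np.linspace(0, 1, 30)
    base = np.cos(np.pi * x)
    R = 120
    vals = []
    for _ in range(1000):
        P = base + rng.normal(0, 0.3, size=(R, 30))
        S = metrics.mpc_from_profiles(P)
        vals.append(S[0, 1])
    mc_err = 3 * np.std(vals) / np.sqrt(len(vals))
    assert abs(np.mean(vals)) < mc_err + 1.0 / (R - 1)


def test_mpc_zero_variance_profile_named():
    P = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
    with pytest.raises(ValueError, match="region 0"):
        metrics.mpc_from_profiles(P)
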