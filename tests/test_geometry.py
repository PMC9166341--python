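"""Mesh decimation, interior visibility, shortest paths, region averaging."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import distance as ssd

from connectogen import geometry
from connectogen.synthdata import make_fixture_meshes


@pytest.fixture(scope="module")
def sphere():
    return make_fixture_meshes("icosphere", scale=10.0, resolution=3)


@pytest.fixture(scope="module")
def decimated_sphere(sphere):
    return geometry.decimate(sphere, 0.2)


@pytest.fixture(scope="module")
def tube():
    return make_fixture_meshes("bent-tube", scale=10.0, resolution=2)


def floyd_warshall_oracle(L):
    """Plain triple-loop all-pairs shortest paths (vectorized over j only)."""
    D = np.array(L.todense(), dtype=float)
    n = D.shape[0]
    D[D == 0] = np.inf
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def test_decimate_identity_at_full_fraction(sphere):
    out = geometry.decimate(sphere, 1.0)
    assert len(out.vertices) == len(sphere.vertices)


def test_decimate_hits_vertex_target(sphere, decimated_sphere):
    target = round(0.2 * len(sphere.vertices))
    assert abs(len(decimated_sphere.vertices) - target) <= 0.02 * target
    assert decimated_sphere.is_watertight


def test_decimate_preserves_volume():
    m = make_fixture_meshes("icosphere", scale=1.0, resolution=4)
    out = geometry.decimate(m, 0.15)
    assert abs(out.volume - m.volume) / m.volume < 0.03


def test_decimate_too_small_rejected(sphere):
    with pytest.raises(geometry.MeshError, match="at least 4"):
        geometry.decimate(sphere, 0.001)


def test_decimate_requires_closed_surface():
    open_mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]],
        process=False)
    with pytest.raises(geometry.MeshError, match="watertight"):
        geometry.decimate(open_mesh, 0.5)


# ---------------------------------------------------------------------------
# inward offset
# ---------------------------------------------------------------------------

def test_inward_points_sphere_radius(sphere):
    pts = geometry.inward_points(sphere, 0.1)
    radii = np.linalg.norm(pts, axis=1)
    assert np.allclose(radii, 10.0 - 0.1, atol=1e-8)


def test_inward_points_all_inside(tube):
    pts = geometry.inward_points(tube, 0.05)
    assert geometry._contains(tube, pts).all()


def test_inward_points_random_blob_inside():
    rng = np.random.default_rng(4)
    m = make_fixture_meshes("icosphere", scale=5.0, resolution=2)
    V = np.array(m.vertices)
    V *= (1.0 + 0.25 * np.sin(3 * V[:, 0]))[:, None]  # lumpy closed blob
    blob = trimesh.Trimesh(vertices=V, faces=m.faces, process=False)
    pts = geometry.inward_points(blob, 0.05)
    assert geometry._contains(blob, pts).all()


def test_inward_points_rejects_open_mesh():
    open_mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]],
        process=False)
    with pytest.raises(geometry.MeshError, match="watertight"):
        geometry.inward_points(open_mesh, 0.1)


# ---------------------------------------------------------------------------
# visibility and shortest paths
# ---------------------------------------------------------------------------

def test_sphere_visibility_complete(decimated_sphere):
    pts = geometry.inward_points(decimated_sphere, 0.1)
    L = geometry.visibility(decimated_sphere, pts)
    P = len(pts)
    assert L.nnz == P * (P - 1)  # convex: every pair visible
    assert (L != L.T).nnz == 0


def test_sphere_interior_equals_euclidean(decimated_sphere):
    pts = geometry.inward_points(decimated_sphere, 0.1)
    L = geometry.visibility(decimated_sphere, pts)
    vd = geometry.interior_distances(L)
    eu = ssd.squareform(ssd.pdist(pts))
    assert np.allclose(vd, eu, atol=1e-10)


def test_tube_blocks_cross_bend_segments(tube):
    pts = geometry.inward_points(tube, 0.05)
    L = geometry.visibility(tube, pts)
    vd = geometry.interior_distances(L)
    eu = ssd.squareform(ssd.pdist(pts))
    i = int(np.argmax(tube.vertices[:, 0]))
    j = int(np.argmin(tube.vertices[:, 0]))
    assert L[i, j] == 0.0  # direct segment crosses the surface
    assert vd[i, j] > eu[i, j] * 1.1  # detour around the bend
    assert np.all(vd >= eu - 1e-9)  # interior never beats the chord


def test_interior_distances_match_floyd_warshall(tube, decimated_sphere):
    for mesh, depth in ((tube, 0.05), (decimated_sphere, 0.1)):
        pts = geometry.inward_points(mesh, depth)
        assert len(pts) <= 300
        L = geometry.visibility(mesh, pts)
        vd = geometry.interior_distances(L)
        assert np.allclose(vd, floyd_warshall_oracle(L), atol=1e-10)


def test_disconnected_visibility_graph_rejected():
    from scipy import sparse

    L = sparse.csr_matrix(np.array([
        [0, 1.0, 0, 0], [1.0, 0, 0, 0], [0, 0, 0, 2.0], [0, 0, 2.0, 0]]))
    with pytest.raises(geometry.MeshError, match="disconnected"):
        geometry.interior_distances(L)


def test_interior_triangle_inequality(tube):
    pts = geometry.inward_points(tube, 0.05)
    vd = geometry.interior_distances(geometry.visibility(tube, pts))
    rng = np.random.default_rng(0)
    n = len(pts)
    idx = rng.integers(0, n, size=(10_000, 3))
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    assert np.all(vd[i, j] <= vd[i, k] + vd[k, j] + 1e-9)


# ---------------------------------------------------------------------------
# region averaging
# ---------------------------------------------------------------------------

def test_region_distances_single_vertex_regions(rng):
    n = 6
    vd = rng.uniform(1, 10, (n, n))
    vd = (vd + vd.T) / 2
    np.fill_diagonal(vd, 0)
    D = geometry.region_distances(vd, np.arange(n))
    assert np.allclose(D, vd)


def test_region_distances_vertex_permutation_invariant(rng):
    n = 12
    vd = rng.uniform(1, 10, (n, n))
    vd = (vd + vd.T) / 2
    np.fill_diagonal(vd, 0)
    labels = rng.integers(0, 3, n)
    labels[:3] = [0, 1, 2]
    D1 = geometry.region_distances(vd, labels)
    perm = rng.permutation(n)
    D2 = geometry.region_distances(vd[np.ix_(perm, perm)], labels[perm])
    assert np.allclose(D1, D2)


def test_region_refinement_aggregation_identity(rng):
    # coarse region distance equals the count-weighted mean of the fine
    # region distances refining it
    n = 16
    vd = rng.uniform(1, 10, (n, n))
    vd = (vd + vd.T) / 2
    np.fill_diagonal(vd, 0)
    fine = np.arange(n) // 2          # 8 fine regions
    coarse = np.arange(n) // 8        # 2 coarse regions
    Df = geometry.region_distances(vd, fine)
    Dc = geometry.region_distances(vd, coarse)
    # coarse (0,1) block = mean over all fine pairs crossing the split
    fine_in_0 = np.unique(fine[coarse == 0])
    fine_in_1 = np.unique(fine[coarse == 1])
    counts = np.bincount(fine)
    num = sum(Df[a, b] * counts[a] * counts[b]
              for a in fine_in_0 for b in fine_in_1)
    den = sum(counts[a] * counts[b] for a in fine_in_0 for b in fine_in_1)
    assert Dc[0, 1] == pytest.approx(num / den)


def test_region_distances_empty_region_rejected(rng):
    vd = np.zeros((4, 4))
    with pytest.raises(ValueError, match="empty region"):
        geometry.region_distances(vd, np.array([0, 0, 2, 2]))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_pipeline_sphere_matches_chords(sphere):
    labels = np.arange(len(sphere.vertices)) % 8
    D = geometry.interregional_distances(sphere, labels, keep_fraction=0.2,
                                         depth=0.1)
    assert D.shape == (8, 8)
    assert np.all(np.diag(D) == 0)
    assert np.all(D[~np.eye(8, dtype=bool)] > 0)


def test_pipeline_scaling_equivariance(tube):
    labels = np.arange(len(tube.vertices)) % 5
    D1 = geometry.interregional_distances(tube, labels, keep_fraction=0.6,
                                          depth=0.05)
    s = 3.0
    scaled = trimesh.Trimesh(vertices=np.array(tube.vertices) * s,
                             faces=tube.faces, process=False)
    D2 = geometry.interregional_distances(scaled, labels, keep_fraction=0.6,
                                          depth=0.05 * s)
    assert np.allclose(D2, s * D1, rtol=1e-9, atol=1e-9)


def test_assemble_distance_set(rng):
    from conftest import random_distance

    mats = [random_distance(rng, 10) for _ in range(3)]
    dset = geometry.assemble_distance_set(mats)
    assert dset.n_stages == 3
    assert np.array_equal(dset.eval_matrix, mats[-1])
    assert dset.stage_quotas(10) == [3, 3, 4]
    with pytest.raises(ValueError, match="conformable"):
        geometry.assemble_distance_set([mats[0], random_distance(rng, 8)])
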