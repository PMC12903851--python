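"""RMSD matrix, local scaling, eigengap, spectral partitioning, silhouette."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from replaypose.clustering import (
    build_affinity,
    compute_rmsd_matrix,
    laplacian_eigenvalues,
    local_scaling_sigmas,
    pairwise_rmsd,
    rank_eigengaps,
    select_best_clustering,
    select_candidate_ks,
    silhouette,
    spectral_cluster,
)
from replaypose.errors import ValidationError
from replaypose.synthetic import BlobEnsembleSpec, make_blob_ensemble


# -- independent oracles ----------------------------------------------------

def quaternion_superposed_rmsd(a, b):
    """Independent superposition oracle: optimal RMSD via the quaternion
    (Kearsley) eigenvalue method, all atoms."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    xm, ym, zm = (a - b).T
    xp, yp, zp = (a + b).T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    K[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    K[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    K[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    K[0, 1] = K[1, 0] = np.sum(yp * zm - ym * zp)
    K[0, 2] = K[2, 0] = np.sum(xm * zp - xp * zm)
    K[0, 3] = K[3, 0] = np.sum(xp * ym - xm * yp)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xp * yp)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xp * zp)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(K)
    return np.sqrt(max(lam[0], 0.0) / a.shape[0])


def brute_force_silhouette(d, labels):
    """Plain O(n^2) loop implementation of the silhouette score."""
    n = len(labels)
    labels = np.asarray(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(d[i, j] for j in same) / len(same)
        b = np.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(d[i, j] for j in other) / len(other))
        m = max(a, b)
        scores.append(0.0 if m == 0 else (b - a) / m)
    return float(np.mean(scores))


def block_affinity(block_sizes):
    n = sum(block_sizes)
    a = np.zeros((n, n))
    start = 0
    for size in block_sizes:
        a[start:start + size, start:start + size] = 1.0
        start += size
    return a


# -- RMSD -------------------------------------------------------------------

class TestRmsd:
    def test_identical_states_have_zero_rmsd(self, small_toy_buffer):
        d = compute_rmsd_matrix(small_toy_buffer)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_single_atom_3_4_5_triangle(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[3.0, 4.0, 0.0]])
        assert pairwise_rmsd(a, b) == pytest.approx(5.0)

    def test_superposition_matches_quaternion_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.random((4, 3)) * 4
            # random rigid motion + noise
            theta = rng.uniform(0, np.pi)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            K = np.cross(np.eye(3), axis)
            R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
            b = (a + 0.1 * rng.standard_normal(a.shape)) @ R.T + rng.standard_normal(3)
            ours = pairwise_rmsd(a, b, align_indices=np.arange(4))
            oracle = quaternion_superposed_rmsd(a, b)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_toy_states_use_euclidean_distance(self):
        from replaypose.propagation import SystemState
        from replaypose.replay import BufferEntry, ReplayBuffer

        buf = ReplayBuffer()
        for x in ([0.0, 0.0], [3.0, 4.0]):
            buf.append(BufferEntry(
                state=SystemState(coords=np.array(x)), averaged_energy=0.0,
                origin_pose="p", mc_step=0,
            ))
        d = compute_rmsd_matrix(buf)
        assert d[0, 1] == pytest.approx(5.0)


# -- local scaling and affinity ---------------------------------------------

class TestLocalScaling:
    def test_line_of_integers_hand_enumeration(self):
        # 1-D points 0..11, k_nn = 2: the 2nd nearest neighbor of point 0 is
        # at distance 2
        pts = np.arange(12.0)[:, None]
        d = squareform(pdist(pts))
        sig = local_scaling_sigmas(d, k_nn=2)
        assert sig[0] == pytest.approx(2.0)
        assert sig[5] == pytest.approx(1.0)  # interior point: neighbors at 1,1

    def test_coincident_points_floored(self):
        d = np.zeros((12, 12))
        sig = local_scaling_sigmas(d, k_nn=10)
        assert np.all(sig == 1e-8)

    def test_too_few_points_rejected(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValidationError):
            local_scaling_sigmas(d, k_nn=10)


class TestAffinity:
    def test_zero_distance_gives_unit_affinity(self):
        d = np.array([[0.0, 0.0], [0.0, 0.0]])
        a = build_affinity(d, np.array([1.0, 1.0]))
        assert np.all(a.values == 1.0)

    def test_distance_equal_to_scale_product_gives_exp_minus_one(self):
        d = np.array([[0.0, np.sqrt(6.0)], [np.sqrt(6.0), 0.0]])
        a = build_affinity(d, np.array([2.0, 3.0]))
        assert a.values[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_three_by_three_hand_worked(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        sig = np.array([1.0, 2.0, 0.5])
        a = build_affinity(d, sig).values
        expected = np.array([
            [1.0, np.exp(-1.0 / 2.0), np.exp(-4.0 / 0.5)],
            [np.exp(-1.0 / 2.0), 1.0, np.exp(-9.0 / 1.0)],
            [np.exp(-4.0 / 0.5), np.exp(-9.0 / 1.0), 1.0],
        ])
        assert np.abs(a - expected).max() <= 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_symmetry_unit_diagonal_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        pts = rng.random((n, 3)) * 10
        d = squareform(pdist(pts))
        a = build_affinity(d, local_scaling_sigmas(d, k_nn=2)).values
        assert np.allclose(a, a.T)
        assert np.all(np.diag(a) == 1.0)
        assert np.all(a > 0) and np.all(a <= 1.0)


# -- spectrum and model selection -------------------------------------------

class TestEigengap:
    def test_laplacian_spectrum_bounded_in_zero_two(self):
        rng = np.random.default_rng(4)
        pts = rng.random((30, 2))
        d = squareform(pdist(pts))
        lam = laplacian_eigenvalues(build_affinity(d, local_scaling_sigmas(d, 5)))
        assert lam.min() >= -1e-10 and lam.max() <= 2 + 1e-10

    @pytest.mark.parametrize("blocks", [1, 2, 3, 4, 5, 6])
    def test_zero_eigenvalue_multiplicity_counts_components(self, blocks):
        a = block_affinity([7] * blocks)
        lam = laplacian_eigenvalues(a)
        assert int(np.sum(lam < 1e-10)) == blocks
        assert rank_eigengaps(lam, k_min=1)[0] == blocks

    def test_exact_three_block_affinity_ranks_k3_first(self):
        a = block_affinity([5, 6, 7])
        assert select_candidate_ks(a)[0] == 3

    def test_candidates_capped_at_default_k_max(self):
        rng = np.random.default_rng(1)
        pts = rng.random((60, 2))
        d = squareform(pdist(pts))
        ks = select_candidate_ks(build_affinity(d, local_scaling_sigmas(d, 10)))
        assert all(2 <= k <= 25 for k in ks)

    def test_two_point_dataset_forces_k2(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert select_candidate_ks(a) == [2]

    def test_structureless_data_warns_on_k1_gap(self):
        a = block_affinity([12])
        with pytest.warns(UserWarning, match="k=1"):
            select_candidate_ks(a)


class TestSpectralCluster:
    def test_two_block_affinity_recovers_blocks(self):
        a = block_affinity([6, 9])
        labels = spectral_cluster(a, 2, seed=0)
        truth = np.array([0] * 6 + [1] * 9)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        a = block_affinity([4])
        assert sorted(spectral_cluster(a, 4, seed=0)) == [0, 1, 2, 3]

    def test_permuting_points_permutes_partition(self):
        pts, _ = make_blob_ensemble(BlobEnsembleSpec(k=3, points_per_cluster=8, seed=2))
        d = squareform(pdist(pts))
        a = build_affinity(d, local_scaling_sigmas(d, k_nn=4)).values
        labels = spectral_cluster(a, 3, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pts.shape[0])
        labels_p = spectral_cluster(a[np.ix_(perm, perm)], 3, seed=5)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_k_out_of_range_rejected(self):
        a = block_affinity([4])
        with pytest.raises(ValidationError):
            spectral_cluster(a, 5, seed=0)


class TestSilhouette:
    def test_two_pairs_hand_computed(self):
        # two clusters of two points; within distance 1, between 10:
        # every point has a=1, b=10 -> s = 9/10
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        assert silhouette(d, [0, 0, 1, 1]) == pytest.approx(0.9, abs=1e-12)

    def test_coincident_points_contribute_zero(self):
        d = np.zeros((4, 4))
        assert silhouette(d, [0, 0, 1, 1]) == 0.0

    def test_single_cluster_is_undefined(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            silhouette(d, [0, 0, 0])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((50, 3))
        labels = rng.integers(0, rng.integers(2, 6), size=50)
        if np.unique(labels).size < 2:
            labels[0] = labels[0] + 1
        d = squareform(pdist(pts))
        assert silhouette(d, labels) == pytest.approx(
            brute_force_silhouette(d, labels), abs=1e-12
        )


class TestModelSelection:
    def test_three_separable_blobs_recovered_exactly(self):
        pts, truth = make_blob_ensemble(BlobEnsembleSpec(k=3, points_per_cluster=20, seed=7))
        d = squareform(pdist(pts))
        res = select_best_clustering(d, seed=7)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_returned_silhouette_is_argmax_over_trials(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.random((15, 2)), rng.random((15, 2))])  # inseparable
        d = squareform(pdist(pts))
        res = select_best_clustering(d, seed=1)
        assert res.silhouette >= max(t["silhouette"] for t in res.trials) - 1e-15

    def test_defaults_are_25_repeats_up_to_25_clusters(self):
        import inspect

        sig = inspect.signature(select_best_clustering)
        assert sig.parameters["n_repeats"].default == 25
        assert sig.parameters["k_max"].default == 25
        sig2 = inspect.signature(local_scaling_sigmas)
        assert sig2.parameters["k_nn"].default == 10
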