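"""Length-weighted density-peak clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mdsegclust import (
    Segment,
    assign_clusters,
    cluster_segments,
    compute_cutoff,
    compute_delta,
    frames_from_segments,
    halo_flags,
    local_density,
    point_mode_cluster,
    select_centroids,
)

from oracles import naive_cutoff, naive_delta, naive_rho, resolve_labels_recursive


def random_metricish(rng, n):
    """Symmetric zero-diagonal matrix from random points (a true metric)."""
    pts = rng.normal(0, 3, (n, int(rng.integers(1, 4))))
    return cdist(pts, pts)


class TestCutoff:
    def test_all_equal_distances(self):
        n = 11
        D = np.full((n, n), 4.0)
        np.fill_diagonal(D, 0.0)
        assert compute_cutoff(D) == pytest.approx(4.0)

    def test_k_is_rounded_log_n(self, rng):
        # N = 20 → k = round(ln 20) = 3: third-nearest neighbor distances
        pts = rng.normal(size=(20, 2))
        D = cdist(pts, pts)
        k3 = np.sort(D + np.diag(np.full(20, np.inf)), axis=1)[:, 2]
        assert compute_cutoff(D) == pytest.approx(k3.mean())

    def test_matches_naive_on_random_matrices(self, rng):
        for n in [2, 3, 6, 25, 60]:
            D = random_metricish(rng, n)
            assert compute_cutoff(D) == pytest.approx(naive_cutoff(D))

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_cutoff(np.zeros((5, 5)))


class TestDensity:
    def test_two_elements(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        rho = local_density(D, d_c=1.5)
        expect = np.exp(-((2.0 / 1.5) ** 2))
        np.testing.assert_allclose(rho, [expect, expect])

    def test_weight_linearity(self, rng):
        D = random_metricish(rng, 8)
        w = np.ones(8)
        rho1 = local_density(D, 1.0, w)
        w2 = w.copy()
        w2[3] = 2.0
        rho2 = local_density(D, 1.0, w2)
        contrib = np.exp(-(D[:, 3] ** 2))
        contrib[3] = 0.0
        np.testing.assert_allclose(rho2, rho1 + contrib)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            n = int(rng.integers(2, 40))
            D = random_metricish(rng, n)
            w = rng.integers(1, 10, n).astype(float)
            d_c = compute_cutoff(D)
            np.testing.assert_allclose(
                local_density(D, d_c, w), naive_rho(D, d_c, w), rtol=1e-12
            )


class TestDelta:
    def test_two_elements(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        rho = np.array([5.0, 1.0])
        delta, nneigh = compute_delta(D, rho)
        assert delta[1] == 3.0 and nneigh[1] == 0
        # global peak: row max, self sentinel
        assert delta[0] == 3.0 and nneigh[0] == 0

    def test_matches_naive_including_ties(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 50))
            D = random_metricish(rng, n)
            rho = rng.integers(0, 4, n).astype(float)  # force exact ties
            delta, nneigh = compute_delta(D, rho)
            d0, n0 = naive_delta(D, rho)
            np.testing.assert_allclose(delta, d0)
            np.testing.assert_array_equal(nneigh, n0)


class TestCentroids:
    def test_two_blobs_auto_selects_two(self, two_blob_distance_matrix):
        D, _ = two_blob_distance_matrix
        state = cluster_segments(D)
        assert state.n_clusters == 2
        # one centroid per blob
        assert (state.centroids < 20).sum() == 1

    def test_manual_single_centroid_swallows_all(self, two_blob_distance_matrix):
        D, _ = two_blob_distance_matrix
        state = cluster_segments(D, centroid_mode="manual", manual_ids=[0])
        assert state.n_clusters == 1
        assert np.all(state.labels == 0)

    def test_all_gamma_equal_returns_one(self):
        rho = np.full(6, 2.0)
        delta = np.full(6, 3.0)
        assert select_centroids(rho, delta, "auto").size == 1

    def test_manual_validation(self):
        rho = delta = np.ones(4)
        with pytest.raises(ValueError):
            select_centroids(rho, delta, "manual", manual_ids=[])
        with pytest.raises(ValueError):
            select_centroids(rho, delta, "manual", manual_ids=[1, 1])
        with pytest.raises(ValueError):
            select_centroids(rho, delta, "manual", manual_ids=[9])

    def test_threshold_mode_rectangular(self):
        rho = np.array([5.0, 1.0, 4.0, 0.5])
        delta = np.array([2.0, 2.0, 3.0, 0.1])
        ids = select_centroids(rho, delta, "threshold", rho_min=2.0, delta_min=1.0)
        np.testing.assert_array_equal(ids, [0, 2])


class TestAssignment:
    def test_centroids_keep_own_labels(self, two_blob_distance_matrix):
        D, _ = two_blob_distance_matrix
        state = cluster_segments(D)
        for k, c in enumerate(state.centroids):
            assert state.labels[c] == k

    def test_chain_assignment(self):
        # chain a(ρ=1) → b(ρ=2) → c(ρ=3), c is the centroid
        rho = np.array([1.0, 2.0, 3.0])
        nneigh = np.array([1, 2, 2])
        labels = assign_clusters(rho, nneigh, centroids=np.array([2]))
        np.testing.assert_array_equal(labels, [0, 0, 0])

    def test_matches_recursive_resolution(self, rng):
        from mdsegclust.density_peak import _redirect_orphan_peak

        for _ in range(5):
            n = int(rng.integers(5, 120))
            D = random_metricish(rng, n)
            d_c = compute_cutoff(D)
            rho = local_density(D, d_c)
            delta, nneigh = compute_delta(D, rho)
            cents = select_centroids(rho, delta, "auto")
            chain = _redirect_orphan_peak(nneigh, cents, lambda i: D[i, cents])
            labels = assign_clusters(rho, chain, cents)
            np.testing.assert_array_equal(
                labels, resolve_labels_recursive(chain, cents)
            )


class TestHalo:
    def test_single_cluster_no_halo(self, rng):
        D = random_metricish(rng, 10)
        labels = np.zeros(10, dtype=int)
        rho = local_density(D, 1.0)
        assert not halo_flags(D, rho, labels, d_c=1.0).any()

    def test_disabled_all_core(self, two_blob_distance_matrix):
        D, _ = two_blob_distance_matrix
        state = cluster_segments(D, halo=False)
        assert not state.halo.any()

    def test_hand_built_two_cluster_instance(self):
        # clusters {0,1,2} and {3,4}; only the 1↔3 pair sits within d_c,
        # so 1 and 3 are the border elements.  Cluster 0's border density
        # is ρ₁ = 1.0 ⇒ element 2 (ρ = 0.5) is halo; cluster 1's border
        # density is ρ₃ = 3.0 ⇒ element 4 (ρ = 2.0) is halo.
        rho = np.array([3.0, 1.0, 0.5, 3.0, 2.0])
        labels = np.array([0, 0, 0, 1, 1])
        D = np.full((5, 5), 5.0)
        np.fill_diagonal(D, 0.0)
        D[1, 3] = D[3, 1] = 0.5
        halo = halo_flags(D, rho, labels, d_c=1.0)
        np.testing.assert_array_equal(halo, [False, False, True, False, True])

    def test_core_plus_halo_conserves(self, two_blob_distance_matrix):
        D, _ = two_blob_distance_matrix
        state = cluster_segments(D, halo=True)
        assert state.halo.size == D.shape[0]


class TestFrames:
    def test_broadcast_and_conservation(self):
        segs = [
            Segment(0, 0, 30, np.array([0.0])),
            Segment(1, 30, 45, np.array([0.0])),
            Segment(2, 45, 100, np.array([0.0])),
        ]
        labels = np.array([3, 1, 3])
        halo = np.array([False, True, False])
        fl, fh = frames_from_segments(labels, halo, segs)
        assert fl.size == 100
        assert (fl == 3).sum() == 85 and (fl == 1).sum() == 15
        assert fh.sum() == 15

    def test_single_segment_uniform(self):
        segs = [Segment(0, 0, 12, np.array([0.0]))]
        fl, _ = frames_from_segments(np.array([3]), np.array([False]), segs)
        assert np.all(fl == 3)


class TestPointMode:
    def test_reduction_equals_segment_mode(self, rng):
        pts = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(7, 1, (25, 2))])
        st_point = point_mode_cluster(pts)
        st_seg = cluster_segments(cdist(pts, pts), np.ones(50))
        assert st_point.d_c == pytest.approx(st_seg.d_c)
        np.testing.assert_allclose(st_point.rho, st_seg.rho)
        np.testing.assert_array_equal(st_point.labels, st_seg.labels)

    def test_two_blobs_ground_truth(self, rng):
        pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(9, 1, (40, 2))])
        st = point_mode_cluster(pts, block=16)  # force multi-block path
        assert st.n_clusters == 2
        truth = np.repeat([0, 1], 40)
        # membership matches up to label swap except possibly near the midplane
        agree = max(
            (st.labels == truth).mean(), (st.labels == 1 - truth).mean()
        )
        assert agree > 0.95

    def test_percentile_rule_on_equal_distances(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [1.5, 3.0 * np.sqrt(3) / 2]])
        st = point_mode_cluster(pts, d_c_rule="percentile")
        assert st.d_c == pytest.approx(3.0)

    def test_label_permutation_invariance(self, rng):
        pts = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(8, 1, (15, 2))])
        st = point_mode_cluster(pts)
        perm = rng.permutation(30)
        st_p = point_mode_cluster(pts[perm])
        # same partition, labels possibly renamed
        a, b = st.labels[np.argsort(np.arange(30))], st_p.labels[np.argsort(perm)]
        assert len(set(zip(a.tolist(), b.tolist()))) == len(set(a.tolist()))
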