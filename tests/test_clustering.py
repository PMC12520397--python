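import numpy as np
import pytest

from pigmentsep.clustering import (
    assign_labels,
    cluster,
    init_centers,
    init_labels,
    sample_feature_points,
    update_centers,
)


class TestInitCenters:
    def test_hundred_samples_four_windows_of_25(self):
        Z = np.random.default_rng(0).normal(size=(100, 2))
        centers = init_centers(Z, 4)
        for i in range(4):
            np.testing.assert_allclose(centers[i], Z[25 * i : 25 * (i + 1)].mean(axis=0))

    def test_single_center_is_global_mean(self):
        Z = np.random.default_rng(1).normal(size=(37, 2))
        np.testing.assert_allclose(init_centers(Z, 1)[0], Z.mean(axis=0))

    def test_k_equals_n_centers_are_samples(self):
        Z = np.random.default_rng(2).normal(size=(9, 2))
        np.testing.assert_allclose(init_centers(Z, 9), Z)

    def test_tail_joins_last_window(self):
        Z = np.arange(20, dtype=float).reshape(10, 2)
        centers = init_centers(Z, 3)  # windows 0-2, 3-5, 6-9
        np.testing.assert_allclose(centers[2], Z[6:].mean(axis=0))
        labels = init_labels(10, 3)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1, 2, 2, 2, 2])

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            init_centers(np.zeros((3, 2)), 4)


class TestAssign:
    def test_wide_window_equals_global_nearest(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(50, 2))
        centers = rng.normal(size=(5, 2))
        labels = init_labels(50, 5)
        got = assign_labels(Z, centers, labels, r=5)
        d2 = ((Z[:, None, :] - centers[None]) ** 2).sum(-1)
        np.testing.assert_array_equal(got, np.argmin(d2, axis=1))

    def test_sample_on_its_center_keeps_label(self):
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]])
        Z = centers.copy()
        labels = np.array([0, 1, 2])
        np.testing.assert_array_equal(assign_labels(Z, centers, labels, r=1), labels)

    def test_one_dimensional_toy(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0]])
        Z = np.array([[1.0, 0.0], [6.0, 0.0], [9.0, 0.0]])
        labels = np.zeros(3, dtype=np.intp)
        np.testing.assert_array_equal(assign_labels(Z, centers, labels, r=1), [0, 1, 1])

    def test_tie_goes_to_lower_center_index(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        Z = np.array([[1.0, 0.0]])  # equidistant
        assert assign_labels(Z, centers, np.array([1]), r=1)[0] == 0


class TestUpdate:
    def test_two_point_mean(self):
        Z = np.array([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_allclose(update_centers(Z, np.array([0, 0]), 1)[0], [1.0, 1.0])

    def test_empty_cluster_keeps_previous_center(self):
        Z = np.array([[1.0, 1.0], [3.0, 3.0]])
        prev = np.array([[0.0, 0.0], [9.0, 9.0]])
        new = update_centers(Z, np.array([0, 0]), 2, prev)
        np.testing.assert_allclose(new[0], [2.0, 2.0])
        np.testing.assert_allclose(new[1], [9.0, 9.0])


class TestCluster:
    def test_two_separated_blobs_recover_blob_means(self):
        rng = np.random.default_rng(5)
        a = rng.normal([0, 0], 0.1, size=(50, 2))
        b = rng.normal([5, 5], 0.1, size=(50, 2))
        Z = np.vstack([a, b])
        state = cluster(Z, k=2, r=1, max_iter=50)
        assert state.converged
        assert np.linalg.norm(state.centers[0] - a.mean(axis=0)) < 0.05
        assert np.linalg.norm(state.centers[1] - b.mean(axis=0)) < 0.05

    def test_converged_centers_are_member_means(self):
        Z = np.random.default_rng(6).normal(size=(500, 2))
        state = cluster(Z, k=20, r=2, max_iter=100)
        re_updated = update_centers(Z, state.labels, state.k, state.centers)
        np.testing.assert_allclose(re_updated, state.centers, atol=1e-12)

    def test_local_optimality_within_search_window(self):
        Z = np.random.default_rng(7).normal(size=(400, 2))
        state = cluster(Z, k=16, r=2, max_iter=100)
        again = assign_labels(Z, state.centers, state.labels, state.r)
        assert np.mean(again != state.labels) < 0.01

    def test_deterministic(self):
        Z = np.random.default_rng(8).normal(size=(300, 2))
        s1 = cluster(Z, k=10, r=2)
        s2 = cluster(Z, k=10, r=2)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        np.testing.assert_array_equal(s1.centers, s2.centers)
        assert s1.iteration == s2.iteration

    def test_exhausted_iteration_budget_warns(self):
        Z = np.random.default_rng(9).normal(size=(200, 2))
        with pytest.warns(UserWarning, match="did not reach"):
            state = cluster(Z, k=8, r=1, max_iter=0)
        assert not state.converged


class TestFeatureSampling:
    def _state(self, Z, labels, k):
        from pigmentsep.clustering import ClusterState

        return ClusterState(
            centers=update_centers(Z, labels, k),
            labels=labels, k=k, r=2, iteration=1, changed_fraction=0.0, converged=True,
        )

    def test_exact_m_members_keeps_everything(self):
        Z = np.random.default_rng(10).normal(size=(12, 2))
        labels = np.repeat(np.arange(4), 3)
        fs = sample_feature_points(Z, self._state(Z, labels, 4), m=3, seed=0)
        np.testing.assert_allclose(np.sort(fs.points, axis=0), np.sort(Z, axis=0))

    def test_small_cluster_keeps_all_its_points(self):
        Z = np.random.default_rng(11).normal(size=(5, 2))
        labels = np.array([0, 0, 0, 0, 1])  # cluster 1 has a single member
        fs = sample_feature_points(Z, self._state(Z, labels, 2), m=3, seed=0)
        assert 4 in fs.source_indices

    def test_count_with_twelve_hundred_full_clusters(self):
        Z = np.random.default_rng(12).normal(size=(12_000, 2))
        labels = np.repeat(np.arange(1200), 10)
        fs = sample_feature_points(Z, self._state(Z, labels, 1200), m=3, seed=0)
        assert len(fs.points) == 3600

    def test_seeded_determinism_and_bound(self):
        Z = np.random.default_rng(13).normal(size=(200, 2))
        state = cluster(Z, k=20, r=2)
        a = sample_feature_points(Z, state, m=3, seed=42)
        b = sample_feature_points(Z, state, m=3, seed=42)
        np.testing.assert_array_equal(a.source_indices, b.source_indices)
        assert len(a.points) <= 20 * 3

    def test_singleton_clusters_degenerate_to_identity(self):
        # k = n with m = 1: every sample is its own cluster, nothing is lost
        Z = np.random.default_rng(14).normal(size=(50, 2))
        state = cluster(Z, k=50, r=2, max_iter=50)
        fs = sample_feature_points(Z, state, m=1, seed=0)
        np.testing.assert_allclose(np.sort(fs.points, axis=0), np.sort(Z, axis=0))

    def test_invalid_m_rejected(self):
        Z = np.zeros((4, 2))
        state = cluster(Z + np.random.default_rng(0).normal(size=(4, 2)), k=2, r=1)
        with pytest.raises(ValueError):
            sample_feature_points(Z, state, m=0)
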