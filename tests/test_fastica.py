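import numpy as np
import pytest

from helpers import angle_gap_deg, grid_search_angle, paired_cosines, unmix_angle
from pigmentsep.fastica import (
    DegenerateInputError,
    WhitenedData,
    center,
    coefficient_matrix,
    fastica_unmix,
    whiten,
)


def _uniform_sources(n, seed):
    rng = np.random.default_rng(seed)
    return rng.uniform(-np.sqrt(3), np.sqrt(3), size=(n, 2))


class TestCenter:
    def test_hand_arithmetic(self):
        Xc, mean = center(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(mean, [2.0, 3.0])
        np.testing.assert_allclose(Xc, [[-1.0, -1.0], [1.0, 1.0]])

    def test_zero_mean_input_unchanged(self):
        X = np.array([[1.0, -2.0], [-1.0, 2.0]])
        Xc, mean = center(X)
        np.testing.assert_allclose(mean, 0.0, atol=1e-15)
        np.testing.assert_allclose(Xc, X)

    def test_constant_column_becomes_zero(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        Xc, _ = center(X)
        np.testing.assert_allclose(Xc[:, 0], 0.0, atol=1e-15)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            center(np.ones((1, 2)))


class TestWhiten:
    def test_whitened_covariance_is_identity(self, rng):
        X = rng.normal(size=(5000, 2)) @ np.array([[2.0, 0.5], [0.0, 1.0]])
        Xc, _ = center(X)
        wh = whiten(Xc)
        cov = (wh.Z.T @ wh.Z) / len(wh.Z)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-8)

    def test_whitening_and_dewhitening_are_inverse(self, rng):
        Xc, _ = center(rng.normal(size=(500, 2)) * [3.0, 0.7])
        wh = whiten(Xc)
        np.testing.assert_allclose(wh.whitening_matrix @ wh.dewhitening_matrix, np.eye(2),
                                   atol=1e-10)

    def test_exact_diagonal_covariance(self):
        # four points with sample covariance exactly diag(4, 1)
        X = np.array([[np.sqrt(8), 0], [-np.sqrt(8), 0], [0, np.sqrt(2)], [0, -np.sqrt(2)]])
        wh = whiten(X)
        scales = sorted(np.abs(wh.whitening_matrix).max(axis=1))
        np.testing.assert_allclose(scales, [0.5, 1.0], atol=1e-12)

    def test_near_singular_covariance_rejected(self, rng):
        t = rng.normal(size=400)
        X = np.column_stack([t, t * 2.0])  # rank one
        with pytest.raises(DegenerateInputError):
            whiten(center(X)[0])


class TestUnmix:
    def test_identity_mixing_recovers_signed_permutation(self):
        # Cartesian product of two symmetric 1-D grids: empirical cross-moments
        # factorize exactly, so the source axes are exact fixed points
        g = np.linspace(-np.sqrt(3), np.sqrt(3), 101)
        Z = np.array([[x, y] for x in g for y in g])
        W, converged, _ = fastica_unmix(Z, tol=1e-10, seed=0)
        assert converged
        A = np.abs(W)
        perm = np.eye(2) if A[0, 0] > A[0, 1] else np.eye(2)[::-1]
        np.testing.assert_allclose(A, perm, atol=1e-3)

    def test_forced_single_iteration_fails(self):
        Z = _uniform_sources(2000, 4)
        _, converged, iters = fastica_unmix(whiten(center(Z)[0]).Z, tol=0.0, max_iter=1, seed=0)
        assert not converged
        assert all(i == 1 for i in iters)

    def test_seeded_reproducibility(self):
        Z = whiten(center(_uniform_sources(5000, 5))[0]).Z
        W1, c1, _ = fastica_unmix(Z, seed=11)
        W2, c2, _ = fastica_unmix(Z, seed=11)
        assert c1 == c2
        np.testing.assert_array_equal(W1, W2)

    def test_rows_orthonormal(self):
        Z = whiten(center(_uniform_sources(5000, 6))[0]).Z
        W, _, _ = fastica_unmix(Z, seed=1)
        np.testing.assert_allclose(W @ W.T, np.eye(2), atol=1e-8)

    @pytest.mark.parametrize("mix_angle", [0.35, 1.1])
    def test_matches_negentropy_grid_search_oracle(self, mix_angle):
        S = _uniform_sources(20_000, 7)
        R = np.array([[np.cos(mix_angle), -np.sin(mix_angle)],
                      [np.sin(mix_angle), np.cos(mix_angle)]])
        Z = whiten(center(S @ R.T)[0]).Z
        W, converged, _ = fastica_unmix(Z, seed=2)
        assert converged
        gap = angle_gap_deg(unmix_angle(W), grid_search_angle(Z))
        assert gap < 1.0

    def test_agrees_with_sklearn_deflation(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        S = _uniform_sources(10_000, 8)
        R = np.array([[np.cos(0.6), -np.sin(0.6)], [np.sin(0.6), np.cos(0.6)]])
        Z = whiten(center(S @ R.T)[0]).Z
        W, converged, _ = fastica_unmix(Z, seed=3)
        assert converged
        ica = sklearn.FastICA(algorithm="deflation", fun="logcosh", whiten=False,
                              tol=1e-6, max_iter=200, random_state=0)
        ica.fit(Z)
        gap = angle_gap_deg(unmix_angle(W), unmix_angle(ica.components_))
        assert gap < 1.0


class TestCoefficientMatrix:
    def _identity_whitening(self):
        return WhitenedData(Z=np.eye(2), whitening_matrix=np.eye(2),
                            dewhitening_matrix=np.eye(2), mean_vector=np.zeros(2))

    def test_identity_everything_gives_identity(self):
        np.testing.assert_allclose(
            coefficient_matrix(np.eye(2), self._identity_whitening()), np.eye(2)
        )

    def test_columns_unit_norm_and_nonnegative(self, rng):
        Xc, _ = center(rng.normal(size=(2000, 2)) @ [[1.5, 0.3], [0.2, 0.8]])
        wh = whiten(Xc)
        W, _, _ = fastica_unmix(wh.Z, seed=4)
        V = coefficient_matrix(W, wh)
        np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-12)
        assert np.all(V >= 0)

    def test_singular_w_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            coefficient_matrix(np.zeros((2, 2)), self._identity_whitening())

    def test_recovers_true_coefficients_from_scene(self, strong_scene, strong_image):
        from pigmentsep.optical_density import channel_differences

        X = channel_differences(strong_image).data
        wh = whiten(center(X)[0])
        W, converged, _ = fastica_unmix(wh.Z, seed=5)
        assert converged
        V = coefficient_matrix(W, wh)
        cos_m, cos_h = paired_cosines(V, strong_scene.v_true)
        assert cos_m >= 0.95 and cos_h >= 0.95
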