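import numpy as np
import pytest

from emophys import kpca


def dense_kpca_oracle(X, sigma, X_new=None):
    """From-first-principles kernel PCA: explicit loops and J-matrix centering.

    Independent of the implementation under test: Gram entries via the
    kernel formula elementwise, centering through the literal
    ``(I - J) K (I - J)`` product with ``J = 1/N``, eigendecomposition of the
    centered matrix, Scholkopf normalisation, explicit cross-kernel
    projection for new points.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d2 = np.sum((X[i] - X[j]) ** 2)
            K[i, j] = np.exp(-d2 / (2 * sigma**2))
    J = np.full((n, n), 1.0 / n)
    Kc = (np.eye(n) - J) @ K @ (np.eye(n) - J)
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > 1e-10 * w[0]
    w, V = w[keep], V[:, keep]
    alphas = V / np.sqrt(w)
    if X_new is None:
        return w, alphas * w[None, :]
    m = X_new.shape[0]
    Kx = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            Kx[i, j] = np.exp(-np.sum((X_new[i] - X[j]) ** 2) / (2 * sigma**2))
    Kxc = Kx - Kx.mean(axis=1)[:, None] - K.mean(axis=0)[None, :] + K.mean()
    return w, Kxc @ alphas


def assert_equal_up_to_sign(A, B, atol):
    assert A.shape == B.shape
    for k in range(A.shape[1]):
        diff = min(np.max(np.abs(A[:, k] - B[:, k])),
                   np.max(np.abs(A[:, k] + B[:, k])))
        assert diff < atol, f"component {k}: {diff}"


class TestKernel:
    def test_zero_distance_is_one(self):
        assert kpca.rbf_kernel([1.0, 2.0], [1.0, 2.0], sigma=0.5) == 1.0

    def test_analytic_value_at_two_sigma_squared(self):
        # ||x-y||^2 = 2 sigma^2  ->  exp(-1)
        x, y = np.array([0.0]), np.array([2.0])
        assert kpca.rbf_kernel(x, y, sigma=np.sqrt(2.0)) == pytest.approx(
            np.exp(-1), rel=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            x, y = rng.standard_normal(4), rng.standard_normal(4)
            assert kpca.rbf_kernel(x, y, 1.3) == pytest.approx(
                kpca.rbf_kernel(y, x, 1.3), rel=1e-15)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kpca.rbf_kernel([1.0], [1.0, 2.0], 1.0)


class TestGram:
    def test_identical_rows_give_all_ones(self):
        K = kpca.gram_matrix(np.ones((2, 3)), sigma=1.0)
        np.testing.assert_allclose(K, np.ones((2, 2)))

    def test_unit_diagonal_and_psd(self, rng):
        K = kpca.gram_matrix(rng.standard_normal((15, 4)), sigma=2.0)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_centering_identities(self, rng):
        K = kpca.gram_matrix(rng.standard_normal((12, 3)), sigma=1.5)
        Kc = kpca.center_gram(K)
        np.testing.assert_allclose(Kc.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Kc.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(kpca.center_gram(Kc), Kc, atol=1e-10)

    def test_constant_dataset_centers_to_zero(self):
        K = kpca.gram_matrix(np.ones((4, 2)), sigma=1.0)
        np.testing.assert_allclose(kpca.center_gram(K), 0.0, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            kpca.center_gram(np.ones((3, 4)))


class TestFitTransform:
    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((rng.integers(10, 21), 4))
            sigma = float(rng.uniform(0.8, 3.0))
            model, Z = kpca.fit_transform(X, sigma=sigma, standardize=False)
            _, Z_oracle = dense_kpca_oracle(X, sigma)
            assert_equal_up_to_sign(Z, Z_oracle, atol=1e-8)

    def test_out_of_sample_matches_oracle(self, rng):
        X = rng.standard_normal((14, 3))
        X_new = rng.standard_normal((5, 3))
        model = kpca.fit(X, sigma=1.7, standardize=False)
        _, Z_oracle = dense_kpca_oracle(X, 1.7, X_new)
        assert_equal_up_to_sign(kpca.transform(model, X_new), Z_oracle, 1e-8)

    def test_training_projections_centered_and_uncorrelated(self, rng):
        X = rng.standard_normal((20, 5))
        model = kpca.fit(X, sigma=2.0)
        Z = kpca.transform(model, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        C = Z.T @ Z
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)

    def test_transform_of_training_rows_equals_fit_projection(self, rng):
        X = rng.standard_normal((12, 3))
        model, Z_fit = kpca.fit_transform(X, sigma=1.2)
        np.testing.assert_allclose(kpca.transform(model, X), Z_fit, atol=1e-9)

    def test_duplicated_dataset_preserves_geometry(self, rng):
        """Doubling every point leaves the leading projected shape intact."""
        X = rng.standard_normal((6, 2))
        X2 = np.vstack([X, X])
        _, Z1 = kpca.fit_transform(X, sigma=1.5, standardize=False)
        _, Z2 = kpca.fit_transform(X2, sigma=1.5, standardize=False)
        a = Z1[:, 0] / np.linalg.norm(Z1[:, 0])
        b = Z2[:6, 0] / np.linalg.norm(Z2[:6, 0])
        assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-6

    def test_large_sigma_limit_is_linear_pca(self, rng):
        """As sigma -> inf, sigma-scaled projections approach PCA scores."""
        X = rng.standard_normal((15, 4))
        sigma = 1e4
        _, Z = kpca.fit_transform(X, sigma=sigma, standardize=False)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(w)[::-1][:4]
        scores = V[:, order] * np.sqrt(w[order])[None, :]
        assert_equal_up_to_sign(sigma * Z[:, :4], scores,
                                atol=1e-3 * np.abs(scores).max())

    def test_agrees_with_sklearn_kernel_pca(self, rng):
        """Independent library cross-check on the same kernel and centering."""
        from sklearn.decomposition import KernelPCA
        X = rng.standard_normal((18, 5))
        sigma = 1.9
        _, Z = kpca.fit_transform(X, sigma=sigma, standardize=False)
        ref = KernelPCA(n_components=5, kernel="rbf",
                        gamma=1.0 / (2 * sigma**2)).fit_transform(X)
        assert_equal_up_to_sign(Z[:, :5], ref, atol=1e-8)

    def test_eigenvalues_descending_nonnegative(self, rng):
        model = kpca.fit(rng.standard_normal((20, 3)), sigma=1.0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues > -1e-8)

    def test_component_clipping_and_degenerate_data(self):
        with pytest.warns(UserWarning):
            model = kpca.fit(np.random.default_rng(0).standard_normal((5, 2)),
                             sigma=1.0, n_components=10)
        assert model.n_components <= 5
        with pytest.raises(ValueError):
            kpca.fit(np.ones((4, 2)), sigma=1.0)

    def test_deterministic_sign_convention(self, rng):
        X = rng.standard_normal((10, 3))
        m1 = kpca.fit(X, sigma=1.0)
        m2 = kpca.fit(X, sigma=1.0)
        np.testing.assert_array_equal(m1.alphas, m2.alphas)
        for k in range(m1.n_components):
            col = m1.alphas[:, k]
            nz = col[np.abs(col) > 1e-12]
            assert nz[0] > 0
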