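"""Kernel PCA with an RBF kernel, written out from first principles.

Samples are mapped implicitly into the kernel-induced feature space via
``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))``; the Gram matrix is centered in
feature space (``K~ = K - 1K - K1 + 1K1`` with ``1`` the matrix of entries
``1/N``), eigendecomposed, and each eigenvector ``alpha_k`` normalised so
that ``lambda_k (alpha_k . alpha_k) = 1`` — the Scholkopf convention making
the projection directions unit vectors in feature space. A point projects
onto component ``k`` as ``sum_i alpha_k[i] k~(x, x_i)`` with the cross-kernel
centered using the training row means and grand mean only.

Because kernel-space centering does not remove feature-scale effects, input
features are standardised (training mean/std) before the kernel by default.
The bandwidth defaults to ``gamma = 1/(2 sigma^2) = 1/(d var(X))`` computed
on the (standardised) training matrix; a median-distance heuristic is also
available. All decompositions are deterministic: eigenvalues sorted
descending and each alpha's first non-negligible entry made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

EIGENVALUE_RTOL = 1e-10


def rbf_kernel(x, y, sigma: float) -> float:
    """exp(-||x-y||^2 / (2 sigma^2)); 1 at zero distance, symmetric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimension")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def gram_matrix(X, sigma: float) -> np.ndarray:
    """N x N RBF Gram matrix; unit diagonal, symmetric, PSD."""
    X = np.asarray(X, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = cdist(X, X, metric="sqeuclidean")
    K = np.exp(-d2 / (2.0 * sigma**2))
    return (K + K.T) / 2.0  # enforce exact symmetry


def center_gram(K: np.ndarray) -> np.ndarray:
    """Feature-space centering of a square Gram matrix (row/col sums vanish)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    row = K.mean(axis=0, keepdims=True)
    grand = K.mean()
    return K - row - row.T + grand


def center_cross(K_new: np.ndarray, train_row_means: np.ndarray,
                 train_grand_mean: float) -> np.ndarray:
    """Center an M x N cross-kernel using training statistics only."""
    K_new = np.asarray(K_new, dtype=float)
    return (K_new - K_new.mean(axis=1, keepdims=True)
            - train_row_means[None, :] + train_grand_mean)


def _sigma_from_gamma_default(X: np.ndarray) -> float:
    # gamma = 1 / (d * var(X)) over all entries -> sigma = sqrt(1 / (2 gamma))
    var = float(X.var())
    if var <= 0:
        raise ValueError("degenerate data: zero variance")
    return float(np.sqrt(X.shape[1] * var / 2.0))


def _sigma_median_heuristic(X: np.ndarray) -> float:
    d2 = cdist(X, X, metric="sqeuclidean")
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        raise ValueError("degenerate data: zero median pairwise distance")
    return float(np.sqrt(med / 2.0))


@dataclass
class KPCAModel:
    """Fitted kernel PCA state sufficient for out-of-sample projection."""

    X_train: np.ndarray          # standardized training matrix, N x d
    sigma: float
    eigenvalues: np.ndarray      # descending, length n_components
    alphas: np.ndarray           # N x n_components, lambda_k (a_k . a_k) = 1
    row_means: np.ndarray        # training Gram row means
    grand_mean: float
    feat_mean: np.ndarray        # standardization statistics (original scale)
    feat_std: np.ndarray
    standardize: bool

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def to_dict(self) -> dict:
        return {
            "kind": "kpca",
            "X_train": self.X_train.tolist(),
            "sigma": self.sigma,
            "eigenvalues": self.eigenvalues.tolist(),
            "alphas": self.alphas.tolist(),
            "row_means": self.row_means.tolist(),
            "grand_mean": self.grand_mean,
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KPCAModel":
        return cls(
            X_train=np.asarray(d["X_train"], dtype=float),
            sigma=float(d["sigma"]),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            row_means=np.asarray(d["row_means"], dtype=float),
            grand_mean=float(d["grand_mean"]),
            feat_mean=np.asarray(d["feat_mean"], dtype=float),
            feat_std=np.asarray(d["feat_std"], dtype=float),
            standardize=bool(d["standardize"]),
        )


def _fix_signs(alphas: np.ndarray) -> np.ndarray:
    for k in range(alphas.shape[1]):
        col = alphas[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            alphas[:, k] = -col
    return alphas


def fit(X, sigma: float | None = None, n_components: int | None = None,
        standardize: bool = True, sigma_mode: str = "scale") -> KPCAModel:
    """Fit kernel PCA on the rows of X.

    ``n_components`` defaults to N (one component per sample — the maximum);
    components with eigenvalues below ``1e-10 x lambda_max`` are discarded.
    ``sigma_mode`` selects the bandwidth rule when ``sigma`` is None:
    "scale" (``gamma = 1/(d var)``) or "median" (median pairwise distance).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    n = X.shape[0]
    if standardize:
        feat_mean = X.mean(axis=0)
        feat_std = X.std(axis=0, ddof=0)
        feat_std = np.where(feat_std > 1e-12, feat_std, 1.0)
        Xs = (X - feat_mean) / feat_std
    else:
        feat_mean = np.zeros(X.shape[1])
        feat_std = np.ones(X.shape[1])
        Xs = X.copy()
    if sigma is None:
        sigma = (_sigma_median_heuristic(Xs) if sigma_mode == "median"
                 else _sigma_from_gamma_default(Xs))
    if n_components is None:
        n_components = n
    elif n_components > n:
        import warnings
        warnings.warn(f"n_components={n_components} > N={n}; clipped to N")
        n_components = n
    K = gram_matrix(Xs, sigma)
    row_means = K.mean(axis=0)
    grand_mean = float(K.mean())
    Kc = center_gram(K)
    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = EIGENVALUE_RTOL * max(eigvals[0], 0.0)
    keep = eigvals > tol
    if not np.any(keep):
        raise ValueError("degenerate data: all kernel eigenvalues vanish")
    keep &= np.arange(n) < n_components
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    alphas = _fix_signs(eigvecs / np.sqrt(eigvals)[None, :])
    return KPCAModel(X_train=Xs, sigma=float(sigma), eigenvalues=eigvals,
                     alphas=alphas, row_means=row_means, grand_mean=grand_mean,
                     feat_mean=feat_mean, feat_std=feat_std,
                     standardize=standardize)


def transform(model: KPCAModel, X_new) -> np.ndarray:
    """Project new points; rows x n_components, Scholkopf normalisation."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    Xs = (X_new - model.feat_mean) / model.feat_std
    d2 = cdist(Xs, model.X_train, metric="sqeuclidean")
    K_new = np.exp(-d2 / (2.0 * model.sigma**2))
    Kc = center_cross(K_new, model.row_means, model.grand_mean)
    return Kc @ model.alphas


def fit_transform(X, sigma: float | None = None, n_components: int | None = None,
                  standardize: bool = True) -> tuple[KPCAModel, np.ndarray]:
    model = fit(X, sigma=sigma, n_components=n_components, standardize=standardize)
    # training projections come directly from the eigendecomposition:
    # K~ alpha_k = lambda_k v_k / sqrt(lambda_k) = sqrt(lambda_k) v_k
    return model, model.alphas * model.eigenvalues[None, :]
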