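"""Multivariate models: PCA, NIPALS PLS-DA, Mahalanobis prediction, VIP.

The PLS-DA implementation is NIPALS PLS2 on the feature matrix X and a
column-centred dummy class matrix Y (one column per class, including the
two-class case). Class prediction projects new samples onto the latent
scores via the rotation W (P'W)^-1 and assigns the class whose
training-score mean is nearest in Mahalanobis distance under the pooled,
ridge-regularised within-class score covariance — the distance that
accounts for correlations among components.

Deterministic sign conventions (the largest-magnitude element of each
weight/loading column is positive) make fits bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .exceptions import InvariantError

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray  # p x K, orthonormal columns
    scores: np.ndarray  # n x K
    explained_variance_ratio: np.ndarray  # K
    mean: np.ndarray  # p, column means used for centering


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Principal axes of the column-centred matrix by SVD.

    X normally arrives Pareto-scaled (hence centred); centering is
    re-applied defensively. Sign convention: the largest-magnitude
    element of each loading column is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise InvariantError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise InvariantError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    K = n_components
    loadings = Vt[:K].T.copy()
    scores = U[:, :K] * s[:K]
    for k in range(K):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    evr = (s[:K] ** 2) / total_var if total_var > 0 else np.zeros(K)
    return PCAModel(loadings, scores, evr, mean)


# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    n_components: int
    weights: np.ndarray  # W, p x K, unit-norm columns
    x_loadings: np.ndarray  # P, p x K
    y_loadings: np.ndarray  # Q, C x K
    scores: np.ndarray  # T, n x K (training scores)
    class_labels: list = field(default_factory=list)
    x_mean: np.ndarray = None
    y_mean: np.ndarray = None
    class_score_means: dict = field(default_factory=dict)  # label -> K-vector
    score_covariance: np.ndarray = None  # pooled within-class, ridge-regularised
    covariance_ridge: float = 0.0

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1 so that T_new = (X_new - x_mean) R."""
        return self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)


def _dummy_matrix(y: Sequence, class_labels: list) -> np.ndarray:
    index = {c: j for j, c in enumerate(class_labels)}
    Y = np.zeros((len(y), len(class_labels)))
    for i, label in enumerate(y):
        Y[i, index[label]] = 1.0
    return Y


def fit_plsda(X: np.ndarray, y: Sequence, n_components: int) -> PLSDAModel:
    """NIPALS PLS2 discriminant model.

    Per component: iterate w <- X'u/||X'u||, t <- Xw, q <- Y't/(t't),
    u <- Yq until t stabilises (||dt|| < 1e-10 relative, max 500
    iterations), then deflate X by t p' and Y by t q'. Every class needs
    at least 2 training samples (the pooled score covariance needs
    within-class degrees of freedom).
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n, p = X.shape
    if len(y) != n:
        raise InvariantError("label length does not match X rows")
    class_labels = sorted(set(y), key=str)
    if len(class_labels) < 2:
        raise InvariantError("PLS-DA needs at least 2 classes")
    counts = {c: y.count(c) for c in class_labels}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise InvariantError(f"classes with < 2 training samples: {small}")
    if not 1 <= n_components <= min(n - 1, p):
        raise InvariantError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )

    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    Y = _dummy_matrix(y, class_labels)
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean

    K = n_components
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    Q = np.zeros((len(class_labels), K))
    T = np.zeros((n, K))
    for a in range(K):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = Yd[:, 0].copy()
        t_old = None
        for _ in range(NIPALS_MAX_ITER):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise InvariantError(
                    f"component {a + 1}: X carries no remaining covariance with Y"
                )
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise InvariantError(f"component {a + 1}: degenerate score vector")
            q = Yd.T @ t / tt
            u = Yd @ q
            if t_old is not None and np.linalg.norm(t - t_old) < NIPALS_TOL * max(
                1.0, np.linalg.norm(t)
            ):
                break
            t_old = t
        else:
            raise InvariantError(f"NIPALS did not converge for component {a + 1}")
        # deterministic sign: largest |w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, q = -w, -t, -q
        tt = float(t @ t)
        p_vec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_vec)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t

    # training-score class statistics for Mahalanobis prediction
    means = {}
    pooled = np.zeros((K, K))
    for c in class_labels:
        idx = [i for i, label in enumerate(y) if label == c]
        Tc = T[idx]
        mu = Tc.mean(axis=0)
        means[c] = mu
        pooled += (Tc - mu).T @ (Tc - mu)
    dof = n - len(class_labels)
    pooled = pooled / max(dof, 1)
    trace = float(np.trace(pooled))
    ridge = 1e-6 * trace / K if trace > 0 else 1e-8
    cov = pooled + ridge * np.eye(K)

    return PLSDAModel(
        n_components=K,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        class_labels=class_labels,
        x_mean=x_mean,
        y_mean=y_mean,
        class_score_means=means,
        score_covariance=cov,
        covariance_ridge=ridge,
    )


def project(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Latent scores of new samples: T_new = (X_new - x_mean) W (P'W)^-1."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.weights.shape[0]:
        raise InvariantError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.weights.shape[0]}"
        )
    return (X_new - model.x_mean) @ model.rotation


def predict_plsda(model: PLSDAModel, X_new: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Predict class labels by minimum Mahalanobis distance in score space.

    Returns (labels, distances) where distances is n x n_classes (columns
    ordered as ``model.class_labels``) for audit.
    """
    from scipy.linalg import solve_triangular

    T_new = project(model, X_new)
    cov = model.score_covariance
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise InvariantError("singular regularised score covariance") from exc
    dists = np.empty((T_new.shape[0], len(model.class_labels)))
    for j, c in enumerate(model.class_labels):
        diff = (T_new - model.class_score_means[c]).T  # K x n
        z = solve_triangular(chol, diff, lower=True)
        dists[:, j] = np.sqrt(np.sum(z**2, axis=0))
    labels = np.asarray([model.class_labels[j] for j in np.argmin(dists, axis=1)])
    return labels, dists


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with
    SSY_a = ||q_a||^2 t_a't_a, the Y-variance explained by component a.
    Uses the NIPALS weights W (not the rotated weights). Satisfies
    sum_j VIP_j^2 = p exactly.
    """
    W = model.weights
    p, K = W.shape
    ssy = np.array(
        [
            float(model.y_loadings[:, a] @ model.y_loadings[:, a])
            * float(model.scores[:, a] @ model.scores[:, a])
            for a in range(K)
        ]
    )
    total = float(ssy.sum())
    if total <= 0:
        raise InvariantError("model explains no Y variance; VIP undefined")
    return np.sqrt(p * (W**2 @ ssy) / total)
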