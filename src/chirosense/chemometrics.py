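"""Single-block decomposition and regression.

PCA is SVD-based with a deterministic sign convention; PLS2 is classical
NIPALS with X-deflation by t p^T; LASSO is cyclic coordinate descent on
(1/2n)||y - Xb||^2 + lambda*||b||_1 with the intercept handled by centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DegenerateInputError, DimensionError, RankDeficiencyError

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    mean_: np.ndarray
    components_: np.ndarray  # variables x components (columns orthonormal)
    singular_values_: np.ndarray
    explained_variance_ratio_: np.ndarray
    n_components: int


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    """SVD PCA of the column-centered matrix.

    Component signs are fixed so the largest-|loading| entry of each component
    is positive; explained variance ratios come from the squared singular values.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not 0 <= n_components <= min(n - 1, p):
        raise DimensionError(
            f"n_components must be in [0, min(n-1, p)] = [0, {min(n - 1, p)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    V = vt[:n_components].T.copy()
    sv = s[:n_components].copy()
    # deterministic sign: largest-|loading| entry positive
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    evr = (sv**2 / total) if total > 0 else np.zeros_like(sv)
    return PCAModel(
        mean_=mean,
        components_=V,
        singular_values_=sv,
        explained_variance_ratio_=evr,
        n_components=n_components,
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.shape[1] != model.mean_.size:
        raise DimensionError(f"expected {model.mean_.size} variables, got {X.shape[1]}")
    return (X - model.mean_) @ model.components_


def pca_inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, float)
    if scores.shape[1] != model.n_components:
        raise DimensionError(f"expected {model.n_components} score columns, got {scores.shape[1]}")
    return scores @ model.components_.T + model.mean_


def numerical_rank(X: np.ndarray, rtol: float = 1e-8) -> int:
    """Count singular values above rtol * largest (0 for an all-zero matrix)."""
    s = np.linalg.svd(np.asarray(X, float), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


# ---------------------------------------------------------------------------
# OLS / PCR
# ---------------------------------------------------------------------------


def ols_fit(T: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least squares with intercept; returns (k+1) x m coefficients, row 0 = intercept.

    Constant predictor columns are absorbed by the intercept (coefficient 0);
    any remaining rank deficiency raises RankDeficiencyError rather than
    falling back to a silent pseudo-inverse.
    """
    T = np.atleast_2d(np.asarray(T, float))
    Y = np.asarray(Y, float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    n, k = T.shape
    if n <= k:
        raise DimensionError(f"need more samples than predictors (n={n}, k={k})")
    varying = np.ptp(T, axis=0) > 0
    A = np.hstack([np.ones((n, 1)), T[:, varying]])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise RankDeficiencyError("singular normal equations in OLS")
    sol, *_ = np.linalg.lstsq(A, Y2, rcond=None)
    coef = np.zeros((k + 1, Y2.shape[1]))
    coef[0] = sol[0]
    coef[1:][varying] = sol[1:]
    return coef


def ols_predict(coef: np.ndarray, T: np.ndarray) -> np.ndarray:
    T = np.atleast_2d(np.asarray(T, float))
    return coef[0] + T @ coef[1:]


@dataclass
class PCRModel:
    pca: PCAModel
    coef: np.ndarray  # (n_pc + 1) x channels
    n_pc: int


def pcr_fit(X: np.ndarray, Y: np.ndarray, n_pc: int) -> PCRModel:
    """PCA on X, then OLS of Y on the scores (centering frozen from training).

    Components with singular value below 1e-12 * sigma_1 carry no signal
    (requested n_pc above the numerical rank); they get coefficient 0 instead
    of poisoning the normal equations.
    """
    pca = pca_fit(X, n_pc)
    Y2 = np.asarray(Y, float)
    Y2 = Y2[:, None] if Y2.ndim == 1 else Y2
    if n_pc == 0:
        coef = np.vstack([Y2.mean(axis=0)])
        return PCRModel(pca=pca, coef=coef, n_pc=0)
    scores = pca_transform(pca, X)
    sv = pca.singular_values_
    live = sv > 1e-12 * sv[0] if sv[0] > 0 else np.zeros(n_pc, bool)
    coef = np.zeros((n_pc + 1, Y2.shape[1]))
    if not np.any(live):
        coef[0] = Y2.mean(axis=0)
    else:
        sub = ols_fit(scores[:, live], Y2)
        coef[0] = sub[0]
        coef[1:][live] = sub[1:]
    return PCRModel(pca=pca, coef=coef, n_pc=n_pc)


def pcr_predict(model: PCRModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, float)
    if model.n_pc == 0:
        return np.tile(model.coef[0], (X_new.shape[0], 1))
    scores = pca_transform(model.pca, X_new)
    return ols_predict(model.coef, scores)


# ---------------------------------------------------------------------------
# NIPALS PLS2
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # variables x LV weights
    T: np.ndarray  # samples x LV scores (training)
    P: np.ndarray  # variables x LV loadings
    Q: np.ndarray  # channels x LV Y-loadings
    B: np.ndarray  # variables x channels regression coefficients
    n_lv: int


def _dominant_weight(E: np.ndarray, F: np.ndarray, lv_index: int) -> np.ndarray:
    """Unit dominant eigenvector of E^T F F^T E.

    This is the fixed point the NIPALS inner loop iterates towards; it is
    computed exactly through the small m x m eigenproblem of M^T M (M = E^T F)
    because power iteration legitimately stalls when the two leading
    covariance eigenvalues nearly tie.
    """
    M = E.T @ F  # p x m
    G = M.T @ M  # m x m
    norm = np.linalg.norm(M)
    if norm < 1e-12 * max(1.0, np.linalg.norm(E)) or norm == 0:
        raise DegenerateInputError(
            f"Y has no covariance with X at latent variable {lv_index}"
        )
    vals, vecs = np.linalg.eigh(G)
    w = M @ vecs[:, -1]
    nw = np.linalg.norm(w)
    if nw < 1e-14:
        raise DegenerateInputError(
            f"Y has no covariance with X at latent variable {lv_index}"
        )
    w /= nw
    k = int(np.argmax(np.abs(w)))
    return w if w[k] >= 0 else -w


def pls_fit(X: np.ndarray, Y: np.ndarray, n_lv: int) -> PLSModel:
    """NIPALS-style PLS2.

    Per LV: weight w = dominant eigenvector of X^T Y Y^T X (solved exactly),
    t = Xw, p = X^T t / t^T t, q = Y^T t / t^T t, then X <- X - t p^T,
    Y <- Y - t q^T. B = W (P^T W)^{-1} Q^T.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y.copy()
    n, p = X.shape
    m = Y2.shape[1]
    if not 1 <= n_lv <= min(n - 1, p):
        raise DimensionError(f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y2.mean(axis=0)
    E = X - x_mean
    F = Y2 - y_mean
    W = np.zeros((p, n_lv))
    Tm = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    fitted = n_lv
    for a in range(n_lv):
        try:
            w = _dominant_weight(E, F, a + 1)
        except DegenerateInputError:
            if a == 0:
                raise
            fitted = a  # rank exhausted: saturate with fewer LVs
            break
        t = E @ w
        tt = t @ t
        if tt < 1e-14:
            if a == 0:
                raise DegenerateInputError("degenerate X score at latent variable 1")
            fitted = a
            break
        p_vec = E.T @ t / tt
        q_vec = F.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q_vec)
        W[:, a], Tm[:, a], P[:, a], Q[:, a] = w, t, p_vec, q_vec
    W, Tm, P, Q = W[:, :fitted], Tm[:, :fitted], P[:, :fitted], Q[:, :fitted]
    R = W @ np.linalg.inv(P.T @ W)
    B = R @ Q.T
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, W=W, T=Tm, P=P, Q=Q, B=B, n_lv=fitted
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, float)
    if X_new.shape[1] != model.x_mean.size:
        raise DimensionError(f"expected {model.x_mean.size} variables, got {X_new.shape[1]}")
    return (X_new - model.x_mean) @ model.B + model.y_mean


def pls_transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Scores of new samples: t = (X - mean) W (P^T W)^{-1}."""
    X_new = np.asarray(X_new, float)
    R = model.W @ np.linalg.inv(model.P.T @ model.W)
    return (X_new - model.x_mean) @ R


# ---------------------------------------------------------------------------
# LASSO (cyclic coordinate descent)
# ---------------------------------------------------------------------------


@dataclass
class LassoModel:
    coef: np.ndarray
    intercept: float
    lam: float
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


_LASSO_TOL = 1e-8
_LASSO_MAX_SWEEPS = 10_000


def lasso_objective(X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, lam: float) -> float:
    r = y - intercept - X @ coef
    n = X.shape[0]
    return float(0.5 * (r @ r) / n + lam * np.sum(np.abs(coef)))


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = _LASSO_TOL,
    beta0: np.ndarray | None = None,
) -> LassoModel:
    """Coordinate descent for (1/2n)||y - b0 - Xb||^2 + lam*||b||_1.

    X is expected standardized (the precondition of the pipelines); the
    intercept comes from centering and is never penalized. Uses the usual
    active-set strategy (sweep the nonzero set to convergence, then one full
    sweep to check the KKT conditions) and accepts a warm start ``beta0``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    col_ss = (Xc * Xc).sum(axis=0) / n  # per-coordinate curvature
    beta = np.zeros(p) if beta0 is None else np.array(beta0, float)
    resid = yc - Xc @ beta

    def sweep(indices) -> float:
        nonlocal resid
        max_delta = 0.0
        for j in indices:
            if col_ss[j] == 0:
                continue
            old = beta[j]
            rho = (Xc[:, j] @ resid) / n + col_ss[j] * old
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_ss[j]
            if new != old:
                resid += Xc[:, j] * (old - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - old))
        return max_delta

    sweeps = 0
    all_idx = range(p)
    while True:
        if sweeps >= _LASSO_MAX_SWEEPS:
            raise ConvergenceError("LASSO coordinate descent hit the sweep limit")
        delta_full = sweep(all_idx)
        sweeps += 1
        if delta_full < tol:
            break
        active = np.nonzero(beta)[0]
        while active.size:
            if sweeps >= _LASSO_MAX_SWEEPS:
                raise ConvergenceError("LASSO coordinate descent hit the sweep limit")
            if sweep(active) < tol:
                break
            sweeps += 1
    intercept = float(y_mean - x_mean @ beta)
    return LassoModel(coef=beta, intercept=intercept, lam=lam, selected=np.nonzero(beta)[0])


def lasso_predict(model: LassoModel, X_new: np.ndarray) -> np.ndarray:
    return model.intercept + np.asarray(X_new, float) @ model.coef


def lasso_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda with an all-zero solution: max |X_c^T y_c| / n."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / X.shape[0])


def lasso_select(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Union of selected variable indices across all response channels."""
    Y = np.asarray(Y, float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    selected: set[int] = set()
    for c in range(Y2.shape[1]):
        model = lasso_fit(X, Y2[:, c], lam)
        selected.update(model.selected.tolist())
    return np.array(sorted(selected), dtype=int)


def lasso_lambda_grid(X: np.ndarray, Y: np.ndarray, n_points: int = 20) -> np.ndarray:
    """Log-spaced grid 10^{-4..1} x lambda_max (max over channels)."""
    Y = np.asarray(Y, float)
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    lam_max = max(lasso_lambda_max(X, Y2[:, c]) for c in range(Y2.shape[1]))
    return lam_max * np.logspace(-4, 1, n_points)
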