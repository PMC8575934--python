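import numpy as np
import pytest

from chirosense import chemometrics as cm
from chirosense.errors import (
    DegenerateInputError,
    DimensionError,
    RankDeficiencyError,
)
from chirosense.preprocessing import concatenate


def _normal_equation_oracle(T, Y):
    """Textbook (A^T A)^-1 A^T Y with explicit intercept column."""
    A = np.hstack([np.ones((T.shape[0], 1)), T])
    return np.linalg.inv(A.T @ A) @ A.T @ Y


class TestPCA:
    def test_rank_one_evr(self, rng):
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 6))
        X = u @ v
        model = cm.pca_fit(X, 1)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(15, 10))
        model = cm.pca_fit(X, 5)
        V = model.components_
        assert np.max(np.abs(V.T @ V - np.eye(5))) < 1e-8

    def test_sign_convention(self, rng):
        X = rng.normal(size=(12, 6))
        model = cm.pca_fit(X, 4)
        for j in range(4):
            k = np.argmax(np.abs(model.components_[:, j]))
            assert model.components_[k, j] > 0

    def test_evr_non_increasing_and_sums_below_one(self, rng):
        X = rng.normal(size=(20, 12))
        model = cm.pca_fit(X, 6)
        evr = model.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-12

    def test_full_rank_lossless(self, rng):
        X = rng.normal(size=(8, 5))
        model = cm.pca_fit(X, 5)
        back = cm.pca_inverse_transform(model, cm.pca_transform(model, X))
        assert np.max(np.abs(back - X)) < 1e-8

    def test_zero_scores_give_means(self, rng):
        X = rng.normal(size=(9, 4))
        model = cm.pca_fit(X, 2)
        back = cm.pca_inverse_transform(model, np.zeros((3, 2)))
        assert np.allclose(back, X.mean(axis=0))

    def test_n_components_too_large(self, rng):
        with pytest.raises(DimensionError):
            cm.pca_fit(rng.normal(size=(5, 10)), 5)

    def test_reconstruction_error_monotone(self, rng):
        X = rng.normal(size=(15, 10))
        errs = []
        for k in range(1, 8):
            m = cm.pca_fit(X, k)
            back = cm.pca_inverse_transform(m, cm.pca_transform(m, X))
            errs.append(np.linalg.norm(X - back))
        assert np.all(np.diff(errs) <= 1e-10)

    def test_quaternary_four_components_capture_variance(self, quaternary_noiseless):
        X, _ = concatenate(quaternary_noiseless.blocks)
        model = cm.pca_fit(X, 4)
        assert model.explained_variance_ratio_.sum() > 0.9999
        assert cm.numerical_rank(X - X.mean(axis=0)) == 4

    def test_quaternary_reconstruction(self, quaternary_noiseless):
        X, _ = concatenate(quaternary_noiseless.blocks)
        model = cm.pca_fit(X, 4)
        back = cm.pca_inverse_transform(model, cm.pca_transform(model, X))
        rel = np.linalg.norm(X - back) / np.linalg.norm(X)
        assert rel < 1e-6


class TestOLS:
    def test_exact_linear(self, rng):
        T = rng.normal(size=(12, 3))
        B = rng.normal(size=(3, 2))
        Y = T @ B + 1.5
        coef = cm.ols_fit(T, Y)
        assert np.max(np.abs(cm.ols_predict(coef, T) - Y)) < 1e-10

    def test_constant_column_gives_channel_means(self, rng):
        T = np.full((10, 1), 3.0)
        Y = rng.normal(size=(10, 2))
        coef = cm.ols_fit(T, Y)
        assert np.allclose(coef[0], Y.mean(axis=0))
        assert np.allclose(coef[1], 0)

    def test_matches_normal_equation_oracle(self, rng):
        T = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 3))
        coef = cm.ols_fit(T, Y)
        oracle = _normal_equation_oracle(T, Y)
        assert np.max(np.abs(coef - oracle)) < 1e-10

    def test_singular_raises(self, rng):
        t = rng.normal(size=(10, 1))
        T = np.hstack([t, 2 * t])
        with pytest.raises(RankDeficiencyError):
            cm.ols_fit(T, rng.normal(size=(10, 1)))

    def test_too_few_samples(self, rng):
        with pytest.raises(DimensionError):
            cm.ols_fit(rng.normal(size=(3, 3)), rng.normal(size=(3, 1)))


class TestPCR:
    def test_noiseless_quaternary_identifiable(self):
        from chirosense.synthetic import simulate_design

        ds = simulate_design("quaternary", 8, 4, seed=9)
        train = ds.subset(range(8))
        test = ds.subset(range(8, 12))
        Xtr, _ = concatenate(train.blocks)
        Xte, _ = concatenate(test.blocks)
        model = cm.pcr_fit(Xtr, train.Y, 4)
        pred = cm.pcr_predict(model, Xte)
        assert np.max(np.abs(pred - test.Y)) < 1e-6

    def test_zero_components_predicts_means(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 2))
        model = cm.pcr_fit(X, Y, 0)
        pred = cm.pcr_predict(model, rng.normal(size=(3, 6)))
        assert np.allclose(pred, Y.mean(axis=0))

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 2))
        pcr = cm.pcr_fit(X, Y, 5)
        ols = cm.ols_fit(X, Y)
        Xn = rng.normal(size=(4, 5))
        assert np.max(np.abs(cm.pcr_predict(pcr, Xn) - cm.ols_predict(ols, Xn))) < 1e-8


class TestPLS:
    def test_full_rank_single_channel_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        pls = cm.pls_fit(X, y, 5)
        ols = cm.ols_fit(X, y)
        Xn = rng.normal(size=(6, 5))
        assert np.max(np.abs(cm.pls_predict(pls, Xn).ravel() - cm.ols_predict(ols, Xn).ravel())) < 1e-8

    def test_zero_covariance_raises(self):
        X = np.vstack([np.eye(4), -np.eye(4)])
        y = np.ones(8)  # zero variance after centering -> no covariance
        with pytest.raises(DegenerateInputError):
            cm.pls_fit(X, y, 1)

    def test_matches_reference_implementation(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 50))
        B = rng.normal(size=(50, 3))
        Y = X @ B * 0.2 + rng.normal(size=(20, 3)) * 0.05
        mine = cm.pls_fit(X, Y, 4)
        ref = PLSRegression(n_components=4, scale=False, tol=1e-13, max_iter=50000).fit(X, Y)
        Xn = rng.normal(size=(5, 50))
        assert np.max(np.abs(cm.pls_predict(mine, Xn) - ref.predict(Xn))) < 1e-6

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(15, 30))
        Y = rng.normal(size=(15, 2))
        model = cm.pls_fit(X, Y, 5)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(G))

    def test_training_r2_non_decreasing(self, rng):
        X = rng.normal(size=(15, 12))
        Y = rng.normal(size=(15, 2))
        sse = []
        for k in range(1, 8):
            model = cm.pls_fit(X, Y, k)
            sse.append(np.sum((cm.pls_predict(model, X) - Y) ** 2))
        assert np.all(np.diff(sse) <= 1e-8)

    def test_b_reproduces_training_fit(self, rng):
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 2))
        model = cm.pls_fit(X, Y, 3)
        # predictions via B equal T Q^T path on training data
        via_scores = model.T @ model.Q.T + model.y_mean
        assert np.max(np.abs(cm.pls_predict(model, X) - via_scores)) < 1e-8


def _lasso_cd_oracle(X, y, lam, n_iter=200000, tol=1e-12):
    """Independent plain coordinate descent at tighter tolerance."""
    n, p = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    beta = np.zeros(p)
    z = (Xc**2).sum(axis=0) / n
    for _ in range(n_iter):
        delta = 0.0
        for j in range(p):
            if z[j] == 0:
                continue
            r = yc - Xc @ beta + Xc[:, j] * beta[j]
            rho = Xc[:, j] @ r / n
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / z[j]
            delta = max(delta, abs(new - beta[j]))
            beta[j] = new
        if delta < tol:
            break
    return beta, ym - xm @ beta


class TestLasso:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = cm.lasso_fit(X, y, 0.0)
        ols = cm.ols_fit(X, y)
        assert np.max(np.abs(model.coef - ols[1:, 0])) < 1e-8

    def test_lambda_max_gives_null_model(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        lam = cm.lasso_lambda_max(X, y)
        model = cm.lasso_fit(X, y, lam * (1 + 1e-12))
        assert np.all(model.coef == 0)
        assert model.intercept == pytest.approx(y.mean())

    def test_objective_matches_oracle(self, rng):
        X = rng.normal(size=(20, 15))
        beta_true = np.zeros(15)
        beta_true[:3] = [2.0, -1.5, 1.0]
        y = X @ beta_true + rng.normal(size=20) * 0.1
        lam = 0.05
        model = cm.lasso_fit(X, y, lam)
        beta_o, b0_o = _lasso_cd_oracle(X, y, lam)
        obj_mine = cm.lasso_objective(X, y, model.coef, model.intercept, lam)
        obj_oracle = cm.lasso_objective(X, y, beta_o, b0_o, lam)
        assert obj_mine <= obj_oracle + 1e-8

    def test_path_sparsity_monotone(self, rng):
        X = rng.normal(size=(25, 10))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=25) * 0.2
        lam_max = cm.lasso_lambda_max(X, y)
        counts = []
        for lam in lam_max * np.logspace(-3, 0, 8):
            counts.append(len(cm.lasso_fit(X, y, lam).selected))
        assert np.all(np.diff(counts) <= 0)

    def test_select_union_over_channels(self, rng):
        X = rng.normal(size=(30, 6))
        Y = np.column_stack([X[:, 0], X[:, 5]])
        sel = cm.lasso_select(X, Y, 0.05)
        assert 0 in sel and 5 in sel

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            cm.lasso_fit(rng.normal(size=(5, 2)), rng.normal(size=5), -1.0)
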