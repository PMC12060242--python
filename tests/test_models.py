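import numpy as np
import pytest

from ensemble_gp.errors import InvalidParameterError, SchemaError
from ensemble_gp.models import (BayesBParams, GATParams, RFParams, RKHSParams,
                                RRBlupParams, SVRParams, fit_bayesb, fit_gat,
                                fit_rf, fit_rkhs, fit_rrblup, fit_svr,
                                gaussian_kernel, predict)
from ensemble_gp.synthetic_data import TraitArchitecture, simulate_phenotypes

from conftest import single_qtl_data


@pytest.fixture(scope="module")
def qtl_data():
    X, y, mm = single_qtl_data(400, qtl_index=30, beta=2.0, h2=0.9, seed=100)
    return X, y, mm


@pytest.fixture(scope="module")
def small_xy():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(60, 25)).astype(float)
    y = X[:, 3] - 0.5 * X[:, 11] + rng.normal(0, 0.5, size=60)
    return X, y


class TestRRBlup:
    def test_constant_y(self, small_xy):
        X, _ = small_xy
        with pytest.warns(UserWarning):
            m = fit_rrblup(X, np.full(len(X), 7.0), seed=1)
        assert np.allclose(predict(m, X), 7.0)
        assert np.allclose(m.state.beta, 0.0)

    def test_finds_causal_marker(self, qtl_data):
        X, y, _ = qtl_data
        m = fit_rrblup(X, y, seed=1)
        top = int(np.argmax(np.abs(m.state.beta)))
        assert abs(top - 30) <= 2

    def test_fixed_lambda_matches_ridge_oracle(self, small_xy):
        X, y = small_xy
        lam = 3.7
        m = fit_rrblup(X, y, RRBlupParams(method="fixed", lambda_=lam), seed=0)
        # independent oracle: augmented ridge normal equations
        n, p = X.shape
        A = np.zeros((p + 1, p + 1))
        A[0, 0] = n
        A[0, 1:] = X.sum(axis=0)
        A[1:, 0] = X.sum(axis=0)
        A[1:, 1:] = X.T @ X + lam * np.eye(p)
        rhs = np.concatenate([[y.sum()], X.T @ y])
        sol = np.linalg.solve(A, rhs)
        assert abs(m.state.mu - sol[0]) < 1e-6
        assert np.max(np.abs(m.state.beta - sol[1:])) < 1e-6

    def test_predict_is_affine_formula(self, small_xy):
        X, y = small_xy
        m = fit_rrblup(X, y, seed=0)
        manual = m.state.mu + X @ m.state.beta
        assert np.max(np.abs(predict(m, X) - manual)) < 1e-10

    def test_mcmc_mode_close_to_reml(self, small_xy):
        X, y = small_xy
        reml = fit_rrblup(X, y, seed=0)
        mcmc = fit_rrblup(X, y, RRBlupParams(method="mcmc", n_iter=1500,
                                             burn_in=500), seed=0)
        r = np.corrcoef(predict(reml, X), predict(mcmc, X))[0, 1]
        assert r > 0.98

    def test_mcmc_deterministic(self, small_xy):
        X, y = small_xy
        h = RRBlupParams(method="mcmc", n_iter=300, burn_in=100)
        a = fit_rrblup(X, y, h, seed=5)
        b = fit_rrblup(X, y, h, seed=5)
        assert np.array_equal(a.state.beta, b.state.beta)

    def test_env_fixed_effect_recovered(self, small_xy):
        X, y = small_xy
        env = np.tile([0.0, 1.0], 30)
        Xe = np.column_stack([X, env])
        ye = y + 4.0 * env
        m = fit_rrblup(Xe, ye, RRBlupParams(fixed_cols=(X.shape[1],)), seed=0)
        assert m.state.fixed_coefs[0] == pytest.approx(4.0, abs=0.5)


class TestBayesB:
    def test_constant_y(self, small_xy):
        X, _ = small_xy
        with pytest.warns(UserWarning):
            m = fit_bayesb(X, np.full(len(X), 2.0), seed=1)
        assert np.allclose(m.state.beta, 0.0)

    def test_inclusion_enriched_at_causal_markers(self):
        X, y, mm = single_qtl_data(400, qtl_index=50, beta=2.0, h2=0.8,
                                   seed=200, n_chrom=3, markers_per_chrom=100)
        rng = np.random.default_rng(0)
        extra = rng.choice([i for i in range(300) if abs(i - 50) > 5], 2,
                           replace=False)
        y = y + X[:, extra[0]] - X[:, extra[1]]  # 3 causal markers total
        h = BayesBParams(n_iter=1000, burn_in=300)
        m = fit_bayesb(X, y, h, seed=3)
        incl = m.state.extras["inclusion"]
        causal = [50, int(extra[0]), int(extra[1])]
        null = [j for j in range(300)
                if min(abs(j - c) for c in causal) > 5]
        assert incl[causal].mean() > incl[null].mean()

    def test_deterministic(self, small_xy):
        X, y = small_xy
        h = BayesBParams(n_iter=300, burn_in=100)
        a = fit_bayesb(X, y, h, seed=9)
        b = fit_bayesb(X, y, h, seed=9)
        assert np.array_equal(a.state.beta, b.state.beta)

    def test_bad_iteration_counts(self, small_xy):
        X, y = small_xy
        with pytest.raises(InvalidParameterError):
            fit_bayesb(X, y, BayesBParams(n_iter=100, burn_in=100), seed=0)


class TestRKHS:
    def test_tiny_bandwidth_predicts_mean(self, small_xy):
        X, y = small_xy
        m = fit_rkhs(X, y, RKHSParams(bandwidth=1e-10), seed=0)
        assert np.allclose(predict(m, X), y.mean(), atol=1e-3 * np.std(y))

    def test_kernel_symmetric_psd(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, size=(40, 15)).astype(float)
        K = gaussian_kernel(Z, Z, 0.7)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_bad_bandwidth(self, small_xy):
        X, y = small_xy
        with pytest.raises(InvalidParameterError):
            fit_rkhs(X, y, RKHSParams(bandwidth=-1.0), seed=0)

    def test_interpolates_smooth_signal(self, qtl_data):
        X, y, _ = qtl_data
        m = fit_rkhs(X[:300], y[:300], seed=0)
        r = np.corrcoef(predict(m, X[300:]), y[300:])[0, 1]
        assert r > 0.5


class TestRF:
    def test_constant_y_exact(self, small_xy):
        X, _ = small_xy
        m = fit_rf(X, np.full(len(X), 3.0), RFParams(n_trees=20), seed=0)
        assert np.allclose(predict(m, X), 3.0)

    def test_deterministic(self, small_xy):
        X, y = small_xy
        a = fit_rf(X, y, RFParams(n_trees=30), seed=4)
        b = fit_rf(X, y, RFParams(n_trees=30), seed=4)
        assert np.array_equal(predict(a, X), predict(b, X))

    def test_causal_marker_top_importance_majority(self):
        hits = 0
        for rep in range(20):
            X, y, _ = single_qtl_data(250, qtl_index=20, beta=2.0, h2=0.85,
                                      seed=300 + 10 * rep, n_chrom=2,
                                      markers_per_chrom=30)
            m = fit_rf(X, y, RFParams(n_trees=100), seed=rep)
            imp = m.state.estimator.feature_importances_
            # linked neighbours share signal; credit hits within 2 positions
            if abs(int(np.argmax(imp)) - 20) <= 2:
                hits += 1
        assert hits >= 16


class TestSVR:
    def test_constant_y_within_tube(self, small_xy):
        X, _ = small_xy
        m = fit_svr(X, np.full(len(X), 5.0), SVRParams(epsilon=0.2), seed=0)
        assert np.all(np.abs(predict(m, X) - 5.0) <= 0.2 + 1e-9)

    def test_bad_penalty(self, small_xy):
        X, y = small_xy
        with pytest.raises(InvalidParameterError):
            fit_svr(X, y, SVRParams(penalty=0.0), seed=0)

    def test_duplicate_point_inside_tube_no_change(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.1, 1.0, 2.2, 2.9, 4.1])
        h = SVRParams(penalty=10.0, epsilon=0.5, gamma=0.5)
        m = fit_svr(X, y, h, seed=0)
        grid = np.linspace(-0.5, 4.5, 21)[:, None]
        base = predict(m, grid)
        resid = np.abs(predict(m, X) - y)
        inside = int(np.argmin(resid))
        assert resid[inside] < 0.5 - 0.05  # strictly inside the tube
        X2 = np.vstack([X, X[inside]])
        y2 = np.append(y, y[inside])
        m2 = fit_svr(X2, y2, h, seed=0)
        assert np.max(np.abs(predict(m2, grid) - base)) < 1e-4

    def test_agrees_with_qp_oracle(self):
        from scipy.optimize import minimize

        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.9, 2.1, 2.7, 4.2])
        C, eps, gamma = 2.0, 0.1, 0.5
        K = np.exp(-gamma * (X - X.T) ** 2)
        n = len(y)

        def dual(z):
            d = z[:n] - z[n:]
            return 0.5 * d @ K @ d + eps * z.sum() - y @ d

        cons = ({"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])},)
        res = minimize(dual, np.zeros(2 * n), bounds=[(0, C)] * 2 * n,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        d = res.x[:n] - res.x[n:]
        # intercept from a free support vector's KKT condition
        free = np.where((res.x[:n] > 1e-6) & (res.x[:n] < C - 1e-6))[0]
        if len(free):
            b = y[free[0]] - K[free[0]] @ d - eps
        else:
            free = np.where((res.x[n:] > 1e-6) & (res.x[n:] < C - 1e-6))[0]
            b = y[free[0]] - K[free[0]] @ d + eps
        m = fit_svr(X, y, SVRParams(penalty=C, epsilon=eps, gamma=gamma),
                    seed=0)
        grid = np.linspace(0, 4, 17)[:, None]
        Kg = np.exp(-gamma * (grid - X.T) ** 2)
        oracle = Kg @ d + b
        assert np.max(np.abs(predict(m, grid) - oracle)) < 1e-4


class TestGAT:
    def test_attention_rows_are_probability_vectors(self, small_xy):
        X, y = small_xy
        m = fit_gat(X, y, GATParams(epochs=3), seed=0)
        for alpha in m.state.attention(X[:7]):
            assert np.all(alpha >= 0)
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic(self, small_xy):
        X, y = small_xy
        a = fit_gat(X, y, GATParams(epochs=3), seed=2)
        b = fit_gat(X, y, GATParams(epochs=3), seed=2)
        assert np.array_equal(predict(a, X), predict(b, X))

    def test_strong_single_qtl_correlation(self):
        X, y, _ = single_qtl_data(400, qtl_index=30, beta=2.0, h2=0.95,
                                  seed=400)
        m = fit_gat(X[:320], y[:320], GATParams(epochs=20), seed=0)
        r = np.corrcoef(predict(m, X[320:]), y[320:])[0, 1]
        assert r > 0.5

    def test_bad_epochs(self, small_xy):
        X, y = small_xy
        with pytest.raises(InvalidParameterError):
            fit_gat(X, y, GATParams(epochs=0), seed=0)

    def test_weight_gradients_match_finite_differences(self):
        from ensemble_gp.models.gat import GATState, _Layer

        rng = np.random.default_rng(0)
        p, B = 6, 4
        X = rng.normal(size=(B, p))
        y = rng.normal(size=B)
        layers = [_Layer(rng, p, 0, 3, 0.01, False),
                  _Layer(rng, p, 3, 3, 0.01, False),
                  _Layer(rng, p, 3, 1, 0.01, True)]
        st = GATState(layers, 0.0, 1.0)

        def loss():
            return np.mean((st.forward(X) - y) ** 2)

        out, _, caches = st.forward(X, with_cache=True)
        grads, _ = st.backward(2 * (out - y) / B, caches)
        eps = 1e-6
        for li, layer in enumerate(layers):
            for k, P in layer.params().items():
                it = np.nditer(P, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = P[idx]
                    P[idx] = orig + eps
                    lp = loss()
                    P[idx] = orig - eps
                    lm = loss()
                    P[idx] = orig
                    assert abs((lp - lm) / (2 * eps)
                               - grads[li][k][idx]) < 1e-7

    def test_input_gradients_match_finite_differences(self):
        from ensemble_gp.models.gat import GATState, _Layer

        rng = np.random.default_rng(1)
        p, B = 5, 3
        X = rng.normal(size=(B, p))
        layers = [_Layer(rng, p, 0, 3, 0.01, False),
                  _Layer(rng, p, 3, 1, 0.01, True)]
        st = GATState(layers, 0.0, 1.0)
        gX = st._input_gradient(X)
        eps = 1e-6
        for b in range(B):
            for j in range(p):
                orig = X[b, j]
                X[b, j] = orig + eps
                fp = st.forward(X)[b]
                X[b, j] = orig - eps
                fm = st.forward(X)[b]
                X[b, j] = orig
                assert abs((fp - fm) / (2 * eps) - gX[b, j]) < 1e-7


class TestPredictContract:
    def test_row_permutation_equivariance(self, small_xy):
        X, y = small_xy
        m = fit_rkhs(X, y, seed=0)
        perm = np.random.default_rng(2).permutation(len(X))
        assert np.allclose(predict(m, X[perm]), predict(m, X)[perm])

    def test_column_mismatch_rejected(self, small_xy):
        X, y = small_xy
        m = fit_rrblup(X, y, seed=0)
        with pytest.raises(SchemaError):
            predict(m, X[:, :-1])

    def test_training_predictions_reproducible(self, small_xy):
        X, y = small_xy
        m = fit_rf(X, y, RFParams(n_trees=20), seed=1)
        assert np.array_equal(predict(m, X), predict(m, X))


@pytest.mark.slow
def test_classical_beats_ml_on_additive_traits():
    """Majority vote over 20 replicates of a purely additive trait."""
    from ensemble_gp.preprocess import concat_environments
    from ensemble_gp.synthetic_data import (assign_trait_architecture,
                                            simulate_marker_map,
                                            simulate_phenotypes,
                                            simulate_ril_population)

    wins = {("rrblup", k): 0 for k in ("rf", "svr", "gat")}
    wins.update({("bayesb", k): 0 for k in ("rf", "svr", "gat")})
    for rep in range(20):
        mm = simulate_marker_map(2, 40, 400_000, 120.0, seed=500 + rep)
        geno = simulate_ril_population(mm, 150, seed=600 + rep)
        arch = assign_trait_architecture(mm, 4, 0, 1.0, (0.0, 0.5), 0.8,
                                         seed=700 + rep)
        pheno = simulate_phenotypes(geno, arch, seed=800 + rep)
        ft = concat_environments(pheno, geno)
        rng = np.random.default_rng(rep)
        perm = rng.permutation(len(ft))
        tr, te = perm[:240], perm[240:]
        Xtr, ytr, Xte, yte = ft.X[tr], ft.y[tr], ft.X[te], ft.y[te]
        test_mse = {}
        fc = (ft.X.shape[1] - 1,)
        fits = {
            "rrblup": fit_rrblup(Xtr, ytr, RRBlupParams(fixed_cols=fc), seed=rep),
            "bayesb": fit_bayesb(Xtr, ytr,
                                 BayesBParams(n_iter=600, burn_in=200,
                                              fixed_cols=fc), seed=rep),
            "rf": fit_rf(Xtr, ytr, RFParams(n_trees=100), seed=rep),
            "svr": fit_svr(Xtr, ytr, seed=rep),
            "gat": fit_gat(Xtr, ytr, GATParams(epochs=15), seed=rep),
        }
        for k, m in fits.items():
            test_mse[k] = float(np.mean((predict(m, Xte) - yte) ** 2))
        for classical in ("rrblup", "bayesb"):
            for ml in ("rf", "svr", "gat"):
                if test_mse[classical] <= test_mse[ml]:
                    wins[(classical, ml)] += 1
    for pair, w in wins.items():
        assert w > 10, f"{pair} won only {w}/20 replicates"
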