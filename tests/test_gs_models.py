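"""Marker-effect models: ridge algebra, GRR influence diagonal, Bayes-B."""

import numpy as np
import pytest
import scipy.optimize

from treegs.gs_models import (
    GenotypeMatrix,
    RidgeLambdaError,
    estimate_ridge_lambda,
    fit_bayesb,
    fit_grr,
    fit_rrblup,
    grr_hat_diagonal,
    predict,
    preprocess_genotypes,
)


class TestPreprocess:
    def test_monomorphic_and_low_call_rate_dropped(self):
        Z = np.array([
            [0, 2, 1.0, np.nan],
            [0, 1, 0.0, np.nan],
            [0, 0, np.nan, 1.0],
        ])
        g = preprocess_genotypes(Z, call_rate_threshold=0.5)
        # column 0 monomorphic, column 3 call rate 1/3 -> dropped
        assert g.markers == ["m1", "m2"]

    def test_missing_imputed_to_marker_mean(self):
        Z = np.column_stack([
            [0.0, 1.0, 2.0, np.nan, 2.0, 1.0],
            [1.0, 1.0, 0.0, 2.0, 0.0, 1.0],
        ])
        g = preprocess_genotypes(Z, call_rate_threshold=0.5)
        assert g.Z[3, 0] == pytest.approx(1.2)

    def test_clean_input_passes_through(self, rng):
        Z = rng.integers(0, 3, (20, 15)).astype(float)
        g = preprocess_genotypes(Z)
        keep = [j for j in range(15) if len(set(Z[:, j])) > 1]
        assert np.allclose(g.Z, Z[:, keep])

    def test_all_missing_individual_dropped(self):
        Z = np.array([[0, 1.0], [np.nan, np.nan], [2, 1.0], [1, 0.0]])
        with pytest.warns(UserWarning, match="all-missing"):
            g = preprocess_genotypes(Z, call_rate_threshold=0.5)
        assert len(g.ids) == 3


class TestRRBLUP:
    def test_two_point_closed_form(self):
        """n=2, p=1, y=(1,-1), z=(1,-1), lam=2 -> g = z'y/(z'z+lam) = 0.5."""
        model = fit_rrblup(np.array([1.0, -1.0]), np.array([[1.0], [-1.0]]), lam=2.0)
        assert model.effects[0] == pytest.approx(0.5)

    def test_matches_generic_penalised_least_squares(self, rng):
        """Ridge solution equals a quadratic-penalty minimiser found by a
        generic optimiser, to 1e-8."""
        n, p, lam = 25, 8, 1.7
        Z = rng.integers(0, 3, (n, p)).astype(float)
        y = rng.normal(size=n)
        model = fit_rrblup(y, Z, lam=lam)
        Zc, yc = Z - Z.mean(0), y - y.mean()

        def objective(g):
            r = yc - Zc @ g
            return r @ r + lam * g @ g

        res = scipy.optimize.minimize(
            objective, np.zeros(p), method="trust-exact",
            jac=lambda g: 2 * Zc.T @ (Zc @ g - yc) + 2 * lam * g,
            hess=lambda g: 2 * (Zc.T @ Zc + lam * np.eye(p)),
            options={"gtol": 1e-12},
        )
        assert np.abs(model.effects - res.x).max() < 1e-8

    def test_huge_lambda_shrinks_to_intercept(self, rng):
        Z = rng.integers(0, 3, (30, 50)).astype(float)
        y = rng.normal(5.0, 1.0, 30)
        model = fit_rrblup(y, Z, lam=1e12)
        gebv = predict(model, Z)
        assert np.abs(model.effects).max() < 1e-8
        assert np.allclose(gebv, y.mean(), atol=1e-6)

    def test_duplicated_rows_equal_doubled_lambda(self, rng):
        n, p = 20, 12
        Z = rng.integers(0, 3, (n, p)).astype(float)
        y = rng.normal(size=n)
        lam = 2.3
        g1 = fit_rrblup(y, Z, lam=2 * lam).effects
        g2 = fit_rrblup(np.tile(y, 2), np.tile(Z, (2, 1)), lam=4 * lam).effects
        assert np.abs(g1 - g2).max() < 1e-10

    def test_dual_equals_primal(self, rng):
        n, p = 15, 40   # p > n triggers the dual route
        Z = rng.integers(0, 3, (n, p)).astype(float)
        y = rng.normal(size=n)
        lam = 3.1
        g_dual = fit_rrblup(y, Z, lam=lam).effects
        Zc, yc = Z - Z.mean(0), y - y.mean()
        g_primal = np.linalg.solve(Zc.T @ Zc + lam * np.eye(p), Zc.T @ yc)
        assert np.abs(g_dual - g_primal).max() < 1e-10

    def test_kernel_blup_equivalence(self, rng):
        """GEBVs from the marker-effect form equal BLUPs from the n x n
        kernel system with K = Zc Zc' at matched variance ratio."""
        n, p = 100, 2000
        Z = rng.binomial(2, rng.uniform(0.1, 0.5, p), (n, p)).astype(float)
        y = rng.normal(size=n)
        lam = 7.3
        model = fit_rrblup(y, Z, lam=lam)
        gebv_marker = predict(model, Z)
        Zc, yc = Z - Z.mean(0), y - y.mean()
        K = Zc @ Zc.T
        gebv_kernel = y.mean() + K @ np.linalg.solve(K + lam * np.eye(n), yc)
        assert np.abs(gebv_marker - gebv_kernel).max() < 1e-6

    def test_shift_invariance_moves_intercept_only(self, rng):
        Z = rng.integers(0, 3, (25, 10)).astype(float)
        y = rng.normal(size=25)
        m1 = fit_rrblup(y, Z, lam=2.0)
        m2 = fit_rrblup(y + 100.0, Z, lam=2.0)
        assert np.allclose(m1.effects, m2.effects)
        assert m2.mu - m1.mu == pytest.approx(100.0)

    def test_marker_permutation_invariance(self, rng):
        Z = rng.integers(0, 3, (30, 12)).astype(float)
        y = rng.normal(size=30)
        perm = rng.permutation(12)
        g = fit_rrblup(y, Z, lam=1.0).effects
        g_perm = fit_rrblup(y, Z[:, perm], lam=1.0).effects
        assert np.allclose(g_perm, g[perm])

    def test_rejects_bad_inputs(self, rng):
        Z = rng.integers(0, 3, (12, 5)).astype(float)
        with pytest.raises(ValueError):
            fit_rrblup(np.ones(12), Z, lam=-1.0)
        with pytest.raises(ValueError):
            fit_rrblup(np.ones(0), Z[:0], lam=1.0)


class TestLambdaEstimation:
    def test_recovers_variance_ratio(self, rng):
        """REML lambda within 25% of truth as a 10-rep mean (n=500, p=1000)."""
        n, p = 500, 1000
        Z = rng.binomial(2, rng.uniform(0.1, 0.5, p), (n, p)).astype(float)
        Zc = Z - Z.mean(0)
        s2g, s2e = 0.002, 1.0
        est = []
        for _ in range(10):
            g = rng.normal(0, np.sqrt(s2g), p)
            y = 3 + Zc @ g + rng.normal(0, np.sqrt(s2e), n)
            est.append(estimate_ridge_lambda(y, Z))
        assert np.mean(est) == pytest.approx(s2e / s2g, rel=0.25)

    def test_pure_noise_detected_as_no_genomic_signal(self, rng):
        """A response with no genomic signal either drives lambda far above
        the signal case or pins the genomic variance at its zero boundary
        (reported as an error advising a fixed lambda)."""
        n, p = 120, 300
        Z = rng.binomial(2, 0.3, (n, p)).astype(float)
        y_signal = (Z - Z.mean(0)) @ rng.normal(0, 0.1, p)
        lam_signal = estimate_ridge_lambda(y_signal + rng.normal(0, 0.2, n), Z)
        try:
            lam_noise = estimate_ridge_lambda(rng.normal(size=n), Z)
        except RidgeLambdaError:
            lam_noise = np.inf
        assert lam_noise > 100 * lam_signal

    def test_noise_free_signal_gives_near_zero_lambda(self, rng):
        n, p = 60, 10
        Z = rng.binomial(2, 0.4, (n, p)).astype(float)
        y = (Z - Z.mean(0)) @ rng.normal(0, 1, p)
        assert estimate_ridge_lambda(y, Z) < 1e-6

    def test_requires_enough_observations(self, rng):
        Z = rng.integers(0, 3, (8, 4)).astype(float)
        with pytest.raises(ValueError):
            estimate_ridge_lambda(np.ones(8), Z)


class TestGRR:
    def test_hat_diagonal_matches_brute_force(self, rng):
        """Dual-form h_kk equals diag of T(T'T)^-1 T' rows n+k (n=30, p=60)."""
        n, p = 30, 60
        Z = rng.integers(0, 3, (n, p)).astype(float)
        lam = 2.5
        T = np.zeros((n + p, 1 + p))
        T[:n, 0] = 1.0
        T[:n, 1:] = Z
        T[n:, 1:] = lam * np.eye(p)
        H = T @ np.linalg.solve(T.T @ T, T.T)
        h_brute = np.diag(H)[n:]
        h_fast = grr_hat_diagonal(Z - Z.mean(0), lam)
        assert np.abs(h_brute - h_fast).max() < 1e-8

    def test_orthonormal_columns_keep_homogeneous_shrinkage(self):
        """With orthonormal (centered) columns and equal step-1 effects every
        marker gets the same lambda_k, so GRR shrinks all effects equally —
        the per-marker step reproduces the homogeneous structure."""
        n, p = 16, 4
        rng = np.random.default_rng(5)
        M = rng.normal(size=(n, p))
        M -= M.mean(0)
        Q, _ = np.linalg.qr(M)
        Zc = Q[:, :p]
        # response built so every marker has an identical projection
        y = Zc @ np.ones(p)
        model = fit_grr(y, Zc + 1.0, lam_init=2.0, sigma_e2=0.5)
        lam_k = np.asarray(model.lambda_)
        assert np.allclose(lam_k, lam_k[0])
        assert np.allclose(model.effects, model.effects[0])

    def test_large_effect_marker_gets_less_shrinkage(self, rng):
        n, p = 200, 80
        Z = rng.binomial(2, 0.4, (n, p)).astype(float)
        beta = np.zeros(p)
        beta[7] = 2.0
        y = (Z - Z.mean(0)) @ beta + rng.normal(0, 0.5, n)
        model = fit_grr(y, Z)
        lam_k = np.asarray(model.lambda_)
        assert lam_k[7] < np.median(lam_k)

    def test_vanishing_effects_capped_not_inf(self, rng):
        n, p = 40, 10
        Z = rng.binomial(2, 0.4, (n, p)).astype(float)
        y = rng.normal(size=n)
        y[:] = y.mean()  # zero-variance response -> zero effects
        model = fit_grr(y + rng.normal(0, 1e-8, n), Z, lam_init=1.0, sigma_e2=1.0)
        assert np.all(np.isfinite(np.asarray(model.lambda_)))


@pytest.fixture(scope="module")
def sparse_trait():
    rng = np.random.default_rng(42)
    n, p, nq = 300, 400, 10
    Z = rng.binomial(2, rng.uniform(0.1, 0.5, p), (n, p)).astype(float)
    qtl = rng.choice(p, nq, replace=False)
    beta = rng.normal(0, 1, nq)
    tbv = (Z[:, qtl] - Z[:, qtl].mean(0)) @ beta
    tbv /= tbv.std()
    y = tbv + rng.normal(0, 1, n)
    return Z, y, qtl, tbv


class TestBayesB:
    def test_seeded_chains_identical(self, sparse_trait):
        Z, y, _, _ = sparse_trait
        m1 = fit_bayesb(y, Z, iters=600, burn_in=200, thin=4, seed=9)
        m2 = fit_bayesb(y, Z, iters=600, burn_in=200, thin=4, seed=9)
        assert np.array_equal(m1.effects, m2.effects)
        assert np.array_equal(m1.inclusion_prob, m2.inclusion_prob)
        assert m1.mu == m2.mu

    def test_pi_near_one_returns_intercept_only(self, sparse_trait):
        Z, y, _, _ = sparse_trait
        model = fit_bayesb(y, Z, pi=1 - 1e-9, iters=400, burn_in=100, thin=2, seed=1)
        gebv = predict(model, Z)
        assert np.abs(model.effects).max() < 1e-6
        assert np.allclose(gebv, gebv[0], atol=1e-4)

    def test_tiny_pi_approaches_rrblup_ranking(self, sparse_trait):
        """With essentially no spike and a tight variance prior, Bayes-B
        posterior means line up with a ridge fit (rank corr > 0.99)."""
        from scipy.stats import spearmanr

        Z, y, _, _ = sparse_trait
        model = fit_bayesb(y, Z, pi=1e-6, iters=3000, burn_in=1000, thin=2,
                           seed=3, nu=400.0)
        lam = model.sigma_e2 / (model.metadata["S"] * 400.0 / 398.0)
        ridge = fit_rrblup(y, Z, lam=lam)
        rho = spearmanr(predict(model, Z), predict(ridge, Z)).statistic
        assert rho > 0.99

    def test_qtl_enriched_over_null_markers(self, sparse_trait):
        """Posterior inclusion concentrates on causal markers when the
        mixture prior reflects a sparse architecture."""
        Z, y, qtl, _ = sparse_trait
        model = fit_bayesb(y, Z, pi=0.9, iters=3000, burn_in=1000, thin=4, seed=2)
        null = np.setdiff1d(np.arange(Z.shape[1]), qtl)
        assert model.inclusion_prob[qtl].mean() >= 2 * model.inclusion_prob[null].mean()

    def test_rejects_bad_arguments(self, sparse_trait):
        Z, y, _, _ = sparse_trait
        with pytest.raises(ValueError):
            fit_bayesb(y, Z, pi=0.0)
        with pytest.raises(ValueError):
            fit_bayesb(y, Z, iters=100, burn_in=200)
        with pytest.raises(ValueError):
            fit_bayesb(np.r_[y[:-1], np.nan], Z)


class TestPredict:
    def test_training_rows_give_fitted_values(self, rng):
        Z = rng.integers(0, 3, (20, 6)).astype(float)
        y = rng.normal(size=20)
        model = fit_rrblup(y, Z, lam=1.0)
        Zc = Z - Z.mean(0)
        assert np.allclose(predict(model, Z), model.mu + Zc @ model.effects)

    def test_mean_genotype_individual_predicts_mu(self, rng):
        Z = rng.integers(0, 3, (20, 6)).astype(float)
        model = fit_rrblup(rng.normal(size=20), Z, lam=1.0)
        assert predict(model, Z.mean(0)[None, :])[0] == pytest.approx(model.mu)

    def test_marker_mismatch_raises_with_names(self, rng):
        Z = rng.integers(0, 3, (15, 5)).astype(float)
        g = preprocess_genotypes(Z)
        model = fit_rrblup(rng.normal(size=15), g, lam=1.0)
        other = GenotypeMatrix(ids=g.ids, markers=[f"x{j}" for j in range(len(g.markers))],
                               Z=g.Z, maf=g.maf, col_means=g.col_means)
        with pytest.raises(ValueError, match="marker mismatch"):
            predict(model, other)
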