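import numpy as np
import pytest

from conftest import make_instance
from flashlmm.lmmfit import (
    BoundaryError,
    FitterConfig,
    dense_profile_loglik,
    dense_reference_fit,
    fit_all,
    fit_gene,
    gls_quadratics,
    lambda_max,
    profile_loglik,
    score_and_information,
)
from flashlmm.sstats import compute_sstats

TIGHT = FitterConfig(tol_loglik=1e-14, tol_grad=1e-10)


class TestLambdaMax:
    def test_identity(self):
        assert lambda_max(np.eye(4)) == pytest.approx(1.0)

    def test_block_sizes(self):
        # subject blocks of sizes (3, 2): ZᵀZ = diag(3, 2)
        assert lambda_max(np.diag([3.0, 2.0])) == pytest.approx(3.0)

    def test_matches_dense_eig_of_ZZt(self, rng):
        Z = rng.normal(size=(30, 5))
        lm = lambda_max(Z.T @ Z)
        dense = np.linalg.eigvalsh(Z @ Z.T).max()
        assert lm == pytest.approx(dense, rel=1e-10)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            lambda_max(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestGlsQuadratics:
    def test_gamma_zero_is_identity_weighting(self, small_instance):
        _, _, _, _, ss = small_instance
        quad = gls_quadratics(ss, [0.0], 0)
        np.testing.assert_allclose(quad["XHiX"], ss.XX, atol=1e-12)
        assert quad["yHiy"] == pytest.approx(ss.Ynorm[0])
        assert quad["logdetH"] == 0.0

    @pytest.mark.parametrize("gamma", [[0.7], [0.05], [-0.005]])
    def test_woodbury_against_dense_H(self, gamma, rng):
        # the implementer's contract: verify the inverse identity
        # H⁻¹ = I − Z(I + ΓA)⁻¹ΓZᵀ numerically against dense H
        n, p, q = 30, 2, 3
        X = rng.normal(size=(n, p))
        Z = rng.normal(size=(n, q))
        Y = rng.normal(size=(1, n))
        ss = compute_sstats(X, Z, Y)
        quad = gls_quadratics(ss, gamma, 0)
        H = np.eye(n) + gamma[0] * Z @ Z.T
        Hi = np.linalg.inv(H)
        y = Y[0]
        assert np.abs(quad["XHiX"] - X.T @ Hi @ X).max() <= 1e-10
        assert np.abs(quad["XHiy"] - X.T @ Hi @ y).max() <= 1e-10
        assert abs(quad["yHiy"] - y @ Hi @ y) <= 1e-10
        assert np.abs(quad["ZHiZ"] - Z.T @ Hi @ Z).max() <= 1e-10
        assert np.abs(quad["ZHiX"] - Z.T @ Hi @ X).max() <= 1e-10
        assert np.abs(quad["ZHiy"] - Z.T @ Hi @ y).max() <= 1e-10

    def test_sylvester_determinant_identity(self, rng):
        # log|H| from dense Cholesky equals log|I_q + ΓA|
        from scipy.linalg import cho_factor

        n, q = 40, 4
        Z = rng.normal(size=(n, q))
        X = np.ones((n, 1))
        Y = rng.normal(size=(1, n))
        ss = compute_sstats(X, Z, Y, partition=(2, 2))
        gamma = [0.4, 0.1]
        quad = gls_quadratics(ss, gamma, 0)
        H = np.eye(n) + 0.4 * Z[:, :2] @ Z[:, :2].T + 0.1 * Z[:, 2:] @ Z[:, 2:].T
        c, _ = cho_factor(H, lower=True)
        dense_logdet = 2.0 * np.sum(np.log(np.diag(c)))
        assert abs(quad["logdetH"] - dense_logdet) <= 1e-10

    def test_boundary_violation_raises(self, small_instance):
        _, _, _, _, ss = small_instance
        lam = lambda_max(ss.ZZ)
        with pytest.raises(BoundaryError):
            gls_quadratics(ss, [-1.0 / lam * (1 + 1e-9)], 0)


class TestProfileLoglik:
    def test_gamma_zero_equals_ols(self, small_instance):
        _, _, _, _, ss = small_instance
        out = profile_loglik(ss, [0.0], 1, "reml")
        beta_ols = np.linalg.solve(ss.XX, ss.XY[:, 1])
        np.testing.assert_allclose(out["beta_hat"], beta_ols, atol=1e-12)

    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_matches_dense_evaluation(self, method, rng):
        X, Z, Y, partition, ss = make_instance(rng, n=60, n_subjects=5, m=2)
        for gamma in ([0.3], [1.5]):
            a = profile_loglik(ss, gamma, 0, method)
            b = dense_profile_loglik(X, Z, Y[0], gamma, partition, method)
            assert abs(a["loglik"] - b["loglik"]) <= 1e-10 * max(1, abs(b["loglik"]))
            assert a["sigma2_hat"] == pytest.approx(b["sigma2_hat"], abs=1e-12)
            np.testing.assert_allclose(a["beta_hat"], b["beta_hat"], atol=1e-10)

    def test_balanced_oneway_anova_closed_form(self, rng):
        S, c = 6, 25
        n = S * c
        subj = np.repeat(np.arange(S), c)
        Z = np.eye(S)[subj]
        X = np.ones((n, 1))
        y = 1.0 + np.sqrt(0.6) * rng.normal(size=S)[subj] + rng.normal(size=n)
        ss = compute_sstats(X, Z, y[None, :])
        fit = fit_gene(ss, 0, TIGHT)
        groups = y.reshape(S, c)
        gm = groups.mean(axis=1)
        msw = ((groups - gm[:, None]) ** 2).sum() / (n - S)
        msb = c * ((gm - gm.mean()) ** 2).sum() / (S - 1)
        assert msb > msw, "draw produced MSB <= MSW; closed form inapplicable"
        assert fit.sigma2 == pytest.approx(msw, abs=1e-8)
        assert fit.theta[0] == pytest.approx((msb - msw) / c, abs=1e-8)


class TestScoreAndInformation:
    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_finite_difference_oracle(self, method, rng):
        _, _, _, _, ss = make_instance(rng, n=100, n_subjects=6, m=2)
        gamma = np.array([0.4])
        si = score_and_information(ss, gamma, 0, method)
        eps = 1e-6
        fd = (
            profile_loglik(ss, gamma + eps, 0, method)["loglik"]
            - profile_loglik(ss, gamma - eps, 0, method)["loglik"]
        ) / (2 * eps)
        assert si["score"][0] == pytest.approx(fd, rel=1e-5)

    def test_two_component_finite_difference(self, rng):
        n = 90
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        s1 = rng.integers(5, size=n)
        s2 = rng.integers(4, size=n)
        Z = np.column_stack([np.eye(5)[s1], np.eye(4)[s2]])
        Y = rng.normal(size=(1, n)) + rng.normal(size=5)[s1]
        ss = compute_sstats(X, Z, Y, partition=(5, 4))
        gamma = np.array([0.3, 0.1])
        si = score_and_information(ss, gamma, 0, "reml")
        eps = 1e-6
        for k in range(2):
            gp, gm = gamma.copy(), gamma.copy()
            gp[k] += eps
            gm[k] -= eps
            fd = (
                profile_loglik(ss, gp, 0, "reml")["loglik"]
                - profile_loglik(ss, gm, 0, "reml")["loglik"]
            ) / (2 * eps)
            assert si["score"][k] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        np.testing.assert_allclose(si["info"], si["info"].T)

    def test_score_near_zero_at_converged_optimum(self, rng):
        _, _, _, _, ss = make_instance(rng, n=150, n_subjects=8, m=1)
        fit = fit_gene(ss, 0, TIGHT)
        assert fit.converged
        si = score_and_information(ss, fit.gamma, 0, "reml")
        assert np.max(np.abs(si["score"])) <= 1e-4


class TestSpectralFastPath:
    """K = 1 evaluations go through the cached eigenbasis of ZᵀZ; they
    must agree with the generic block algebra to rounding error."""

    def test_quadratics_agree(self, rng):
        _, _, _, _, ss = make_instance(rng, n=120, n_subjects=7, m=2)
        from flashlmm.lmmfit import _quad_k1

        for gamma in (0.6, -0.01, 3.0):
            a = _quad_k1(ss, gamma, 1)
            b = gls_quadratics(ss, [gamma], 1)
            for key in ("XHiX", "XHiy", "yHiy", "logdetH"):
                np.testing.assert_allclose(
                    np.asarray(a[key]), np.asarray(b[key]), rtol=1e-10, atol=1e-10
                )

    def test_score_agrees_with_generic_blocks(self, rng):
        _, _, _, _, ss = make_instance(rng, n=120, n_subjects=7, m=1)
        gamma = np.array([0.5])
        si = score_and_information(ss, gamma, 0, "reml")
        quad = gls_quadratics(ss, gamma, 0)
        XHiX_inv = np.linalg.inv(quad["XHiX"])
        beta = XHiX_inv @ quad["XHiy"]
        sigma2 = (quad["yHiy"] - quad["XHiy"] @ beta) / (ss.n - ss.p)
        u = quad["ZHiy"] - quad["ZHiX"] @ beta
        ZPZ = quad["ZHiZ"] - quad["ZHiX"] @ XHiX_inv @ quad["ZHiX"].T
        score = -0.5 * (np.trace(ZPZ) - (u @ u) / sigma2)
        info = 0.5 * np.sum(ZPZ**2)
        assert si["score"][0] == pytest.approx(score, rel=1e-10)
        assert si["info"][0, 0] == pytest.approx(info, rel=1e-10)


class TestFitGene:
    def test_agrees_with_dense_reference(self, rng):
        X, Z, Y, partition, ss = make_instance(
            rng, n=400, n_subjects=10, m=3, sigma_subject2=0.4
        )
        for g in range(3):
            f = fit_gene(ss, g, TIGHT)
            d = dense_reference_fit(X, Z, Y[g], TIGHT, partition)
            assert f.converged
            np.testing.assert_allclose(f.beta, d.beta, atol=1e-6)
            assert f.sigma2 == pytest.approx(d.sigma2, abs=1e-6)
            np.testing.assert_allclose(f.theta, d.theta, atol=1e-6)

    def test_null_genes_give_negative_thetas_without_error(self, rng):
        # no subject effect: θ̂ fluctuates around 0, both signs occur
        X, Z, Y, partition, ss = make_instance(
            rng, n=300, n_subjects=10, m=40, sigma_subject2=0.0
        )
        fits = fit_all(ss, TIGHT)
        thetas = np.array([f.theta[0] for f in fits])
        assert all(f.converged for f in fits)
        assert np.any(thetas < 0) and np.any(thetas > 0)

    def test_zero_variance_gene_flagged(self, rng):
        n = 30
        X = np.ones((n, 1))
        Z = np.eye(3)[rng.integers(3, size=n)]
        Y = np.zeros((1, n))
        ss = compute_sstats(X, Z, Y)
        fit = fit_gene(ss, 0)
        assert not fit.converged
        assert np.isnan(fit.sigma2)
        assert "zero" in fit.message

    def test_monotone_ascent(self, rng):
        _, _, _, _, ss = make_instance(rng, n=200, n_subjects=8, m=5)
        for g in range(5):
            fit = fit_gene(ss, g)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-12)

    def test_se_theta_finite_and_positive(self, rng):
        _, _, _, _, ss = make_instance(rng, n=200, n_subjects=10, m=2)
        fit = fit_gene(ss, 0, TIGHT)
        assert np.isfinite(fit.se_theta).all()
        assert (fit.se_theta > 0).all()


class TestFitAll:
    def test_single_gene_reduces_to_fit_gene(self, rng):
        _, _, _, _, ss = make_instance(rng, n=80, m=1)
        a = fit_all(ss, TIGHT)[0]
        b = fit_gene(ss, 0, TIGHT)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_gene_order_invariance(self, rng):
        import dataclasses

        _, _, _, _, ss = make_instance(rng, n=80, m=4)
        perm = [2, 0, 3, 1]
        ss_perm = dataclasses.replace(
            ss,
            XY=ss.XY[:, perm],
            ZY=ss.ZY[:, perm],
            Ynorm=ss.Ynorm[perm],
            gene_ids=[ss.gene_ids[i] for i in perm],
        )
        fits = fit_all(ss, TIGHT)
        fits_perm = fit_all(ss_perm, TIGHT)
        for j, i in enumerate(perm):
            # memory layout can flip the last ulp in BLAS reductions
            assert fits_perm[j].loglik == pytest.approx(fits[i].loglik, rel=1e-12)
            np.testing.assert_allclose(fits_perm[j].beta, fits[i].beta, rtol=1e-12)


class TestDenseReference:
    def test_no_random_part_is_ols(self, rng):
        n, p = 50, 3
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = dense_reference_fit(X, None, y, FitterConfig(method="ml"))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)
        resid = y - X @ beta_ols
        assert fit.sigma2 == pytest.approx(resid @ resid / n, abs=1e-12)

    def test_n_cap_enforced(self, rng):
        X = np.ones((10, 1))
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="dense_oracle_max_n"):
            dense_reference_fit(X, np.eye(10), y, FitterConfig(dense_oracle_max_n=5))

    def test_multi_component_agreement(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        s1 = rng.integers(6, size=n)
        s2 = rng.integers(4, size=n)
        Z = np.column_stack([np.eye(6)[s1], np.eye(4)[s2]])
        partition = (6, 4)
        y = (
            rng.normal(size=n)
            + np.sqrt(0.5) * rng.normal(size=6)[s1]
            + np.sqrt(0.3) * rng.normal(size=4)[s2]
        )
        ss = compute_sstats(X, Z, y[None, :], partition=partition)
        f = fit_gene(ss, 0, TIGHT)
        d = dense_reference_fit(X, Z, y, TIGHT, partition)
        assert f.loglik == pytest.approx(d.loglik, abs=1e-7)
        np.testing.assert_allclose(f.theta, d.theta, atol=1e-5)


def test_reml_ml_asymptotically_close(rng):
    # large n: ML and REML estimates of θ converge to each other and truth
    n, S = 20_000, 25
    subj = rng.integers(S, size=n)
    Z = np.eye(S)[subj]
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    theta_true = 0.5
    m = 20
    U = rng.normal(0, np.sqrt(theta_true), size=(m, S))
    Y = U[:, subj] + rng.normal(size=(m, n))
    ss = compute_sstats(X, Z, Y)
    t_ml = np.array([f.theta[0] for f in fit_all(ss, FitterConfig(method="ml"))])
    t_reml = np.array([f.theta[0] for f in fit_all(ss, FitterConfig(method="reml"))])
    assert np.abs(t_ml - t_reml).max() < 0.05
    mc_se = theta_true * np.sqrt(2.0 / (S - 1)) / np.sqrt(m)
    assert abs(t_reml.mean() - theta_true) < 3 * mc_se
    assert abs(t_ml.mean() - theta_true) < 3 * mc_se
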