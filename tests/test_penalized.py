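"""Penalized solvers against closed forms, grid search and generic optimizers."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fetalens.penalized import (
    PenaltySpec,
    fit_penalized_linear,
    fit_penalized_logistic,
    fit_positive_logistic,
    penalty_threshold,
)


def _grid_minimizer(z, lam, family, a=3.7, gamma=3.0, v=1.0):
    """Brute-force univariate minimizer of 0.5 v b^2 - z b + P(|b|; lam)."""
    b = np.linspace(-8, 8, 400_001)
    ab = np.abs(b)
    if family == "lasso":
        pen = lam * ab
    elif family == "scad":
        pen = np.where(
            ab <= lam,
            lam * ab,
            np.where(
                ab <= a * lam,
                (2 * a * lam * ab - ab**2 - lam**2) / (2 * (a - 1)),
                lam**2 * (a + 1) / 2,
            ),
        )
    else:
        pen = np.where(
            ab <= gamma * lam, lam * ab - ab**2 / (2 * gamma),
            0.5 * gamma * lam**2,
        )
    return b[np.argmin(0.5 * v * b**2 - z * b + pen)]


class TestThresholds:
    def test_lasso_soft_threshold(self):
        assert penalty_threshold(3.0, PenaltySpec("lasso", 1.0)) == pytest.approx(2.0)

    def test_scad_unpenalized_region(self):
        spec = PenaltySpec("scad", 1.0)
        z = spec.a * spec.lam + 0.5
        assert penalty_threshold(z, spec) == pytest.approx(z)
        assert penalty_threshold(-z, spec) == pytest.approx(-z)

    @pytest.mark.parametrize("family", ["lasso", "scad", "mcp"])
    @pytest.mark.parametrize("lam", [0.5, 1.0])
    def test_matches_grid_search(self, family, lam):
        for z in (-4.0, -2.2, -1.5, -0.6, 0.0, 0.4, 1.5, 2.5, 3.4, 5.0):
            got = penalty_threshold(z, PenaltySpec(family, lam))
            want = _grid_minimizer(z, lam, family)
            assert got == pytest.approx(want, abs=5e-5)

    def test_mcp_example_against_grid(self):
        got = penalty_threshold(1.5, PenaltySpec("mcp", 1.0, gamma=3.0))
        want = _grid_minimizer(1.5, 1.0, "mcp")
        assert got == pytest.approx(want, abs=5e-5)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec("scad", 1.0, a=2.0)
        with pytest.raises(ValueError):
            PenaltySpec("mcp", 1.0, gamma=1.0)


def _logistic_data(rng, n=200, p=4, beta=None, intercept=0.3):
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.0, 0.8]) if beta is None else beta
    prob = 1 / (1 + np.exp(-(intercept + X @ beta)))
    return X, (rng.random(n) < prob).astype(float)


class TestPenalizedLogistic:
    def test_full_shrinkage_gives_null_model(self, rng):
        X, y = _logistic_data(rng)
        fit = fit_penalized_logistic(X, y, PenaltySpec("lasso", 10.0))
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept == pytest.approx(
            np.log(y.mean() / (1 - y.mean())), abs=1e-6
        )

    def test_lambda_zero_matches_mle_oracle(self, rng):
        X, y = _logistic_data(rng)
        fit = fit_penalized_logistic(X, y, PenaltySpec("lasso", 0.0))

        def nll_grad(par):
            eta = par[0] + X @ par[1:]
            mu = 1 / (1 + np.exp(-eta))
            nll = np.mean(np.logaddexp(0, eta) - y * eta)
            g = np.concatenate([[np.mean(mu - y)], X.T @ (mu - y) / len(y)])
            return nll, g

        oracle = minimize(nll_grad, np.zeros(X.shape[1] + 1), jac=True,
                          method="BFGS", options={"gtol": 1e-12})
        ours = np.r_[fit.intercept, fit.coefficients]
        assert np.max(np.abs(ours - oracle.x)) < 1e-6

    def test_single_class_rejected(self, rng):
        X, _ = _logistic_data(rng)
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, np.ones(len(X)), "lasso")

    def test_scad_mcp_support_recovery(self):
        # 5 true signals among 35 nulls; SCAD and MCP should find the support
        hits = {"scad": 0, "mcp": 0}
        n_reps = 6
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            n, p = 400, 40
            X = rng.normal(size=(n, p))
            beta = np.zeros(p)
            beta[:5] = 1.2
            prob = 1 / (1 + np.exp(-X @ beta))
            y = (rng.random(n) < prob).astype(float)
            for fam in hits:
                fit = fit_penalized_logistic(X, y, fam, n_folds=5, seed=rep)
                if set(fit.active_set) >= {0, 1, 2, 3, 4} and len(
                    fit.active_set
                ) <= 12:
                    hits[fam] += 1
        for fam, k in hits.items():
            assert k >= int(0.8 * n_reps) - 1, (fam, k)


class TestPenalizedLinear:
    def test_lambda_zero_is_ols(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, 0.0, -2.0] + rng.normal(0, 0.3, 60)
        fit = fit_penalized_linear(X, y, PenaltySpec("lasso", 0.0))
        D = np.column_stack([np.ones(60), X])
        ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(np.r_[fit.intercept, fit.coefficients], ols, atol=1e-8)

    def test_lasso_on_orthonormal_design_soft_thresholds_ols(self, rng):
        n, p = 400, 4
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)  # centered-ish, unit-variance orthonormal columns
        X = X - X.mean(axis=0)
        X = X / X.std(axis=0)
        beta = np.array([2.0, -1.0, 0.1, 0.0])
        y = X @ beta  # noiseless; y centered since X is
        lam = 0.5
        fit = fit_penalized_linear(X, y, PenaltySpec("lasso", lam))
        # with X'X/n ~ I the lasso solution is soft(OLS, lam)
        ols = X.T @ (y - y.mean()) / n / (X**2).mean(axis=0)
        expect = np.sign(ols) * np.maximum(
            np.abs(X.T @ (y - y.mean()) / n) - lam, 0
        ) / (X**2).mean(axis=0)
        assert np.allclose(fit.coefficients, expect, atol=2e-3)

    def test_scad_coordinate_updates_match_grid(self, rng):
        # 2-predictor uncorrelated problem: the solution satisfies the
        # univariate grid oracle coordinate-wise at the fixed point
        n = 500
        X = rng.normal(size=(n, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = 1.5 * X[:, 0] + rng.normal(0, 0.5, n)
        lam = 0.3
        fit = fit_penalized_linear(X, y, PenaltySpec("scad", lam))
        Xs = (X - X.mean(0)) / X.std(0)
        resid = y - fit.intercept - X @ fit.coefficients
        for j in range(2):
            sdj = X[:, j].std()
            beta_std = fit.coefficients[j] * sdj
            vj = (Xs[:, j] ** 2).mean()
            zj = (Xs[:, j] * resid).mean() + vj * beta_std
            want = _grid_minimizer(zj, lam, "scad", v=vj)
            assert beta_std == pytest.approx(want, abs=2e-3)

    def test_objective_nonincreasing_along_warm_path(self, rng):
        # penalized objective at each path point evaluated under its own
        # lambda is no worse than the previous solution's (descent check)
        X = rng.normal(size=(100, 8))
        y = X[:, 0] - X[:, 1] + rng.normal(0, 1, 100)
        fit = fit_penalized_linear(X, y, "lasso", n_folds=3, seed=0)
        Xc = (X - X.mean(0)) / X.std(0)
        lam_path = fit.lambda_path
        path = fit.coef_path
        for k in range(1, len(lam_path)):
            lam = lam_path[k]

            def obj(coef_orig):
                inter = y.mean() - X.mean(0) @ coef_orig
                r = y - inter - X @ coef_orig
                return 0.5 * np.mean(r**2) + lam * np.sum(
                    np.abs(coef_orig * X.std(0))
                )

            assert obj(path[k]) <= obj(path[k - 1]) + 1e-8


class TestNesting:
    def test_scad_mcp_approach_lasso_as_shape_grows(self, rng):
        X = rng.normal(size=(200, 6))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(0, 0.5, 200)
        lam = 0.2
        base = fit_penalized_linear(X, y, PenaltySpec("lasso", lam))
        for fam, kw in (("scad", {"a": 1e6}), ("mcp", {"gamma": 1e6})):
            near = fit_penalized_linear(X, y, PenaltySpec(fam, lam, **kw))
            assert np.allclose(near.coefficients, base.coefficients, atol=1e-4)


class TestPositiveLogistic:
    def test_negative_association_clamped_to_zero(self, rng):
        n = 400
        X = rng.normal(size=(n, 2))
        prob = 1 / (1 + np.exp(-(1.0 * X[:, 0] - 1.5 * X[:, 1])))
        y = (rng.random(n) < prob).astype(float)
        fit = fit_positive_logistic(X, y)
        assert fit.coefficients[1] == 0.0
        assert fit.coefficients[0] > 0.0

    def test_inactive_constraints_match_unconstrained(self, rng):
        n = 500
        X = rng.normal(size=(n, 3))
        prob = 1 / (1 + np.exp(-(0.8 * X[:, 0] + 0.5 * X[:, 1] + 1.2 * X[:, 2])))
        y = (rng.random(n) < prob).astype(float)
        fit = fit_positive_logistic(X, y)
        free = fit_penalized_logistic(X, y, PenaltySpec("lasso", 0.0))
        assert np.allclose(fit.coefficients, free.coefficients, atol=1e-4)

    def test_objective_matches_projected_gradient_oracle(self, rng):
        n = 300
        X = rng.normal(size=(n, 3))
        prob = 1 / (1 + np.exp(-(0.5 * X[:, 0] - 0.7 * X[:, 1] + 0.2 * X[:, 2])))
        y = (rng.random(n) < prob).astype(float)
        fit = fit_positive_logistic(X, y)

        def nll(par):
            eta = par[0] + X @ par[1:]
            return np.mean(np.logaddexp(0, eta) - y * eta)

        # projected gradient descent oracle
        par = np.zeros(4)
        lr = 0.5
        for _ in range(20_000):
            eta = par[0] + X @ par[1:]
            mu = 1 / (1 + np.exp(-eta))
            g = np.concatenate([[np.mean(mu - y)], X.T @ (mu - y) / n])
            par = par - lr * g
            par[1:] = np.maximum(par[1:], 0.0)
        ours = nll(np.r_[fit.intercept, fit.coefficients])
        assert ours <= nll(par) + 1e-6
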