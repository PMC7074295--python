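"""Mixed-effects growth models for predicted birth weight (PBW).

Two subject-level models link the longitudinal response — estimated fetal
weights at the ultrasound visits plus the observed birth weight at delivery
— to gestational age ``t`` (days):

* a three-parameter logistic nonlinear mixed-effects model,
  ``y_ij = phi1_i / (1 + exp[-(t_ij - phi2_i)/phi3_i]) + eps_ij`` with
  ``phi1_i = x_i' beta1 + b1_i``, ``phi2_i = beta2 + b2_i``,
  ``phi3_i = beta3 + b3_i``;
* a quadratic linear mixed-effects model,
  ``y_ij = x_i' beta + theta1 t + theta2 t^2 + b0_i + b1_i t + b2_i t^2 +
  eps_ij``.

In both, ``(b._i) ~ MVN(0, Sigma)`` and the within-subject errors are
heteroscedastic with a power-of-the-mean variance,
``Var(eps_ij) = sigma2 * |mu_ij|^(2 delta)``.

Estimation maximizes the Laplace-approximated marginal likelihood by a
Lindstrom–Bates-style alternation: a penalized (nonlinear) least-squares
step updates the fixed effects and the per-subject random-effect modes, then
the model is linearized about those modes and the variance parameters
(log-Cholesky factor of Sigma/sigma2, and delta) are updated by maximizing
the resulting linear-mixed-model profile likelihood, with sigma2 and the
fixed effects profiled out in closed form.  For the quadratic model the
"linearization" is exact, so the scheme reduces to standard ML for a
heteroscedastic linear mixed model.

Subjects whose birth weight is missing (masked) contribute only their
ultrasound rows to the likelihood but still receive empirical-Bayes modes,
which is how test-set subjects obtain predictions without their labels ever
being read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from fetalens.simulate import COVARIATE_COLUMNS, Cohort

__all__ = [
    "LogisticNLMEFit",
    "QuadraticLMEFit",
    "fit_logistic_nlme",
    "fit_quadratic_lme",
    "predict_weight",
]

_MIN_PHI3 = 1.0
_TIME_SCALE = 100.0  # internal day scaling for the quadratic model


# ---------------------------------------------------------------------------
# data assembly


def _assemble(cohort: Cohort, efw: pd.DataFrame, with_covariates: bool):
    """Stack responses into padded (n, J) arrays.

    Rows are the EFW records plus, for subjects with an unmasked birth
    weight, one birth row (t = birth_ga, y = birth_weight).  Padded slots
    are flagged in the mask and neutralized throughout the fit.
    """
    subs = cohort.subjects.reset_index(drop=True)
    ids = subs["id"].to_numpy()
    efw = efw.sort_values(["id", "t"])
    grouped = {k: g for k, g in efw.groupby("id")}

    rows_t, rows_y = [], []
    for i, sid in enumerate(ids):
        g = grouped.get(sid)
        if g is None or len(g) < 1:
            raise ValueError(f"subject {sid} has no EFW records")
        t = list(g["t"].to_numpy(dtype=float))
        y = list(g["efw"].to_numpy(dtype=float))
        bw = subs["birth_weight"].iloc[i]
        if np.isfinite(bw):
            t.append(float(subs["birth_ga"].iloc[i]))
            y.append(float(bw))
        if len(t) < 2:
            raise ValueError(f"subject {sid} has fewer than 2 usable time points")
        rows_t.append(t)
        rows_y.append(y)

    J = max(len(t) for t in rows_t)
    n = len(ids)
    T = np.zeros((n, J))
    Y = np.zeros((n, J))
    M = np.zeros((n, J), dtype=bool)
    for i, (t, y) in enumerate(zip(rows_t, rows_y)):
        T[i, : len(t)] = t
        Y[i, : len(y)] = y
        M[i, : len(t)] = True

    if with_covariates:
        X = np.column_stack(
            [np.ones(n), subs[COVARIATE_COLUMNS].to_numpy(dtype=float)]
        )
        names = ["intercept"] + list(COVARIATE_COLUMNS)
    else:
        X = np.ones((n, 1))
        names = ["intercept"]
    return ids, T, Y, M, X, names


# ---------------------------------------------------------------------------
# mean-function models


class _LogisticModel:
    """phi1 = X beta1 + b1, phi2 = beta2 + b2, phi3 = beta3 + b3."""

    n_ranef = 3

    def __init__(self, X):
        self.X = X
        self.p = X.shape[1]
        self.q = self.p + 2

    def beta_names(self):
        return [f"beta1_{i}" for i in range(self.p)] + ["beta2", "beta3"]

    def mean_jac(self, beta, b, T, M):
        X = self.X
        phi1 = X @ beta[: self.p] + b[:, 0]
        phi2 = beta[self.p] + b[:, 1]
        phi3 = np.maximum(beta[self.p + 1] + b[:, 2], _MIN_PHI3)
        u = (T - phi2[:, None]) / phi3[:, None]
        u = np.clip(u, -60.0, 60.0)
        pfun = 1.0 / (1.0 + np.exp(-u))
        mu = phi1[:, None] * pfun
        d1 = pfun
        common = phi1[:, None] * pfun * (1.0 - pfun)
        d2 = -common / phi3[:, None]
        d3 = -common * u / phi3[:, None]
        n, J = T.shape
        A = np.zeros((n, J, self.q))
        A[:, :, : self.p] = d1[:, :, None] * X[:, None, :]
        A[:, :, self.p] = d2
        A[:, :, self.p + 1] = d3
        B = np.stack([d1, d2, d3], axis=-1)
        A[~M] = 0.0
        B[~M] = 0.0
        return mu, A, B

    def start_beta(self, T, Y, M):
        n = T.shape[0]
        amp = np.array(
            [1.1 * Y[i, M[i]].max() for i in range(n)]
        )
        phi1_0 = float(np.median(amp))
        # pooled half-max crossing time
        t_all = T[M]
        y_all = Y[M]
        order = np.argsort(t_all)
        t_s, y_s = t_all[order], y_all[order]
        half = phi1_0 / 2.0
        above = np.nonzero(y_s >= half)[0]
        if above.size and above[0] > 0:
            k = above[0]
            t_half = np.interp(
                half, [y_s[k - 1], y_s[k]], [t_s[k - 1], t_s[k]]
            )
        else:
            t_half = float(np.median(t_s))
        # slope near the crossing -> phi3 = phi1 / (4 * slope)
        win = (t_s > t_half - 30) & (t_s < t_half + 30)
        if win.sum() >= 2 and np.ptp(t_s[win]) > 0:
            slope = np.polyfit(t_s[win], y_s[win], 1)[0]
        else:
            slope = phi1_0 / 120.0
        phi3_0 = float(np.clip(phi1_0 / (4.0 * max(slope, 1e-6)), 5.0, 80.0))
        beta = np.zeros(self.q)
        beta[0] = phi1_0
        beta[self.p] = float(np.clip(t_half, t_s.min(), t_s.max()))
        beta[self.p + 1] = phi3_0
        return beta

    def start_ranef_sd(self, beta):
        return np.array([0.15 * abs(beta[0]) + 1.0, 8.0, 3.0])

    def subject_params(self, beta, b):
        phi1 = self.X @ beta[: self.p] + b[:, 0]
        phi2 = beta[self.p] + b[:, 1]
        phi3 = np.maximum(beta[self.p + 1] + b[:, 2], _MIN_PHI3)
        return phi1, phi2, phi3


class _QuadraticModel:
    """mu = X beta + theta1 t' + theta2 t'^2 + b0 + b1 t' + b2 t'^2.

    Time is internally rescaled (t' = t / 100) for conditioning; reported
    coefficients and random effects are transformed back to per-day units.
    """

    n_ranef = 3

    def __init__(self, X):
        self.X = X
        self.p = X.shape[1]
        self.q = self.p + 2

    def beta_names(self):
        return [f"beta_{i}" for i in range(self.p)] + ["theta1", "theta2"]

    def mean_jac(self, beta, b, T, M):
        ts = T / _TIME_SCALE
        Z = np.stack([np.ones_like(ts), ts, ts**2], axis=-1)
        fixed = (self.X @ beta[: self.p])[:, None]
        mu = (
            fixed
            + beta[self.p] * ts
            + beta[self.p + 1] * ts**2
            + np.einsum("ijk,ik->ij", Z, b)
        )
        n, J = T.shape
        A = np.zeros((n, J, self.q))
        A[:, :, : self.p] = np.broadcast_to(
            self.X[:, None, :], (n, J, self.p)
        )
        A[:, :, self.p] = ts
        A[:, :, self.p + 1] = ts**2
        B = Z.copy()
        A[~M] = 0.0
        B[~M] = 0.0
        return mu, A, B

    def start_beta(self, T, Y, M):
        ts = (T / _TIME_SCALE)[M]
        y = Y[M]
        idx = np.repeat(np.arange(T.shape[0]), T.shape[1]).reshape(T.shape)[M]
        D = np.column_stack([self.X[idx], ts, ts**2])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        return coef

    def start_ranef_sd(self, beta):
        return np.array([50.0, 50.0, 25.0])

    def subject_params(self, beta, b):
        return beta, b


# ---------------------------------------------------------------------------
# variance-parameter packing


def _pack(L, delta):
    return np.concatenate([np.log(np.diag(L)), L[np.tril_indices(3, -1)], [delta]])


def _unpack(theta):
    L = np.zeros((3, 3))
    L[np.diag_indices(3)] = np.exp(np.clip(theta[:3], -14.0, 14.0))
    L[np.tril_indices(3, -1)] = theta[3:6]
    return L, float(theta[6])


# ---------------------------------------------------------------------------
# fit container


@dataclass
class GrowthFit:
    """Fitted mixed-effects growth model (see module docstring)."""

    model: str
    with_covariates: bool
    beta: np.ndarray
    beta_names: list
    Sigma: np.ndarray
    delta: float
    sigma2: float
    ranef_modes: pd.DataFrame = field(repr=False)
    loglik: float = np.nan
    loglik_history: list = field(default_factory=list, repr=False)
    converged: bool = False
    n_iter: int = 0
    beta_cov: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _index: dict = field(default_factory=dict, repr=False)

    def beta_se(self):
        return np.sqrt(np.diag(self.beta_cov))

    def _row(self, subject_id):
        try:
            return self._index[subject_id]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} was not in the fit") from None

    def predict(self, subject_id, t):
        """Subject-specific mean weight (g) at gestational age t (days)."""
        i = self._row(subject_id)
        t = np.asarray(t, dtype=float)
        b = self.ranef_modes[["b1", "b2", "b3"]].to_numpy()[i]
        x = self._X[i]
        p = len(x)
        if self.model == "logistic":
            phi1 = x @ self.beta[:p] + b[0]
            phi2 = self.beta[p] + b[1]
            phi3 = max(self.beta[p + 1] + b[2], _MIN_PHI3)
            u = np.clip((t - phi2) / phi3, -60.0, 60.0)
            out = phi1 / (1.0 + np.exp(-u))
        else:
            out = (
                x @ self.beta[:p]
                + (self.beta[p] + b[1]) * t
                + (self.beta[p + 1] + b[2]) * t**2
                + b[0]
            )
        return float(out) if out.ndim == 0 else out

    def predict_grid(self, subject_ids, times):
        """(n_subjects, n_times) predictions for every subject at every time."""
        rows = np.array([self._row(s) for s in subject_ids])
        t = np.asarray(times, dtype=float)[None, :]
        b = self.ranef_modes[["b1", "b2", "b3"]].to_numpy()[rows]
        X = self._X[rows]
        p = X.shape[1]
        if self.model == "logistic":
            phi1 = (X @ self.beta[:p] + b[:, 0])[:, None]
            phi2 = (self.beta[p] + b[:, 1])[:, None]
            phi3 = np.maximum(self.beta[p + 1] + b[:, 2], _MIN_PHI3)[:, None]
            u = np.clip((t - phi2) / phi3, -60.0, 60.0)
            return phi1 / (1.0 + np.exp(-u))
        return (
            (X @ self.beta[:p] + b[:, 0])[:, None]
            + (self.beta[p] + b[:, 1])[:, None] * t
            + (self.beta[p + 1] + b[:, 2])[:, None] * t**2
        )

    def predict_many(self, subject_ids, t):
        """Vectorized ``predict`` over subjects, one time per subject or scalar."""
        rows = np.array([self._row(s) for s in subject_ids])
        t = np.broadcast_to(np.asarray(t, dtype=float), rows.shape).astype(float)
        b = self.ranef_modes[["b1", "b2", "b3"]].to_numpy()[rows]
        X = self._X[rows]
        p = X.shape[1]
        if self.model == "logistic":
            phi1 = X @ self.beta[:p] + b[:, 0]
            phi2 = self.beta[p] + b[:, 1]
            phi3 = np.maximum(self.beta[p + 1] + b[:, 2], _MIN_PHI3)
            u = np.clip((t - phi2) / phi3, -60.0, 60.0)
            return phi1 / (1.0 + np.exp(-u))
        return (
            X @ self.beta[:p]
            + (self.beta[p] + b[:, 1]) * t
            + (self.beta[p + 1] + b[:, 2]) * t**2
            + b[:, 0]
        )


class LogisticNLMEFit(GrowthFit):
    @property
    def beta1(self):
        return self.beta[: len(self.beta) - 2]

    @property
    def beta2(self):
        return float(self.beta[-2])

    @property
    def beta3(self):
        return float(self.beta[-1])


class QuadraticLMEFit(GrowthFit):
    @property
    def theta1(self):
        return float(self.beta[-2])

    @property
    def theta2(self):
        return float(self.beta[-1])


# ---------------------------------------------------------------------------
# core engine


def _pnls_sweep(model, beta, b, T, Y, M, Sigma_inv, sigma2, delta, n_sweeps=3):
    """Penalized (nonlinear) least squares update of (b, beta)."""
    for _ in range(n_sweeps):
        mu, A, B = model.mean_jac(beta, b, T, M)
        w_inv = _weight_inv(mu, M, delta)
        r = np.where(M, Y - mu, 0.0)
        # random-effect modes: (B' W^-1 B / s2 + Sigma^-1) db = B' W^-1 r / s2 - Sigma^-1 b
        BtWB = np.einsum("ijk,ij,ijl->ikl", B, w_inv, B) / sigma2
        BtWr = np.einsum("ijk,ij->ik", B, w_inv * r) / sigma2
        G = BtWB + Sigma_inv[None, :, :]
        g = BtWr - b @ Sigma_inv.T
        db = np.linalg.solve(G, g[..., None])[..., 0]
        b = b + db
        # fixed effects: Gauss-Newton on the weighted residuals
        mu, A, B = model.mean_jac(beta, b, T, M)
        w_inv = _weight_inv(mu, M, delta)
        r = np.where(M, Y - mu, 0.0)
        H = np.einsum("ijk,ij,ijl->kl", A, w_inv, A)
        gb = np.einsum("ijk,ij->k", A, w_inv * r)
        try:
            dbeta = np.linalg.solve(H + 1e-10 * np.eye(len(H)), gb)
        except np.linalg.LinAlgError:
            dbeta = np.linalg.lstsq(H, gb, rcond=None)[0]
        beta = beta + dbeta
    return beta, b


def _weight_inv(mu, M, delta):
    w = np.abs(np.where(M, mu, 1.0))
    w = np.maximum(w, 1e-3)
    return np.where(M, w ** (-2.0 * delta), 0.0)


def _make_lme_nll(model, beta, b, T, Y, M, fix_delta):
    """Build the profiled negative log-likelihood of the linearized model.

    The linearization (mu, Jacobians, pseudo-response) is independent of the
    variance parameters and is precomputed once; the returned callable
    evaluates the profile likelihood for a packed (log-chol, delta) vector,
    returning (nll, beta_gls, sigma2, extras) with extras carrying the
    pieces needed for the Wald covariance.
    """
    mu, A, B = model.mean_jac(beta, b, T, M)
    wstar = np.where(M, Y - mu, 0.0) + np.einsum(
        "ijk,k->ij", A, beta
    ) + np.einsum("ijk,ik->ij", B, b)
    absmu = np.maximum(np.abs(np.where(M, mu, 1.0)), 1e-3)
    log_absmu = np.log(absmu)
    nJ = T.shape[1]
    eye = np.eye(nJ)
    N = int(M.sum())
    rhs0 = np.concatenate([wstar[:, :, None], A], axis=2)

    tril = [(1, 0), (2, 0), (2, 1)]

    def nll_full(theta, want_grad=False):
        L, delta = _unpack(theta)
        if fix_delta is not None:
            delta = fix_delta
        Sigma_star = L @ L.T
        w = np.where(M, np.exp(2.0 * delta * log_absmu), 1.0)
        V = np.einsum("ijk,kl,iml->ijm", B, Sigma_star, B)
        V = V + (w + 1e-9)[:, :, None] * eye[None, :, :]
        try:
            C = np.linalg.cholesky(V)
            Ct = np.transpose(C, (0, 2, 1))
            sol = np.linalg.solve(Ct, np.linalg.solve(C, rhs0))
        except np.linalg.LinAlgError:
            bad = (1e12, None, None, None)
            return bad + (np.zeros(7),) if want_grad else bad
        logdet = 2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
        Viw = sol[:, :, 0]
        ViA = sol[:, :, 1:]
        AtVA = np.einsum("ijk,ijl->kl", A, ViA)
        AtVw = np.einsum("ijk,ij->k", A, Viw)
        try:
            beta_gls = np.linalg.solve(AtVA, AtVw)
        except np.linalg.LinAlgError:
            beta_gls = np.linalg.lstsq(AtVA, AtVw, rcond=None)[0]
        quad = float(np.einsum("ij,ij->", wstar, Viw) - beta_gls @ AtVw)
        quad = max(quad, 1e-12)
        sigma2 = quad / N
        nll = 0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + N)
        if not want_grad:
            return nll, beta_gls, sigma2, (AtVA, delta, Sigma_star)

        # analytic gradient: envelope in beta (GLS) and sigma2 (profiled)
        r = wstar - np.einsum("ijk,k->ij", A, beta_gls)
        u = Viw - np.einsum("ijk,k->ij", ViA, beta_gls)  # V^-1 r
        Ci = np.linalg.solve(C, eye[None, :, :])
        Vinv = np.einsum("ikj,ikl->ijl", Ci, Ci)
        Q = np.einsum("ijk,kl->ijl", B, L)  # B L
        grad = np.zeros(7)
        uB = np.einsum("ij,ijk->ik", u, B)  # (n,3)
        uQ = np.einsum("ij,ijk->ik", u, Q)
        VinvQ = np.einsum("ijl,ilk->ijk", Vinv, Q)
        for idx in range(6):
            if idx < 3:
                a = bval = idx
                scale = L[a, a]  # log-diagonal parametrization
            else:
                a, bval = tril[idx - 3]
                scale = 1.0
            tr = 2.0 * np.einsum("ij,ij->", B[:, :, a], VinvQ[:, :, bval])
            udVu = 2.0 * np.einsum("ik,ik->", uB[:, [a]], uQ[:, [bval]])
            grad[idx] = 0.5 * scale * (tr - (N / quad) * udVu)
        if fix_delta is None:
            ddiag = 2.0 * log_absmu * w * M  # dV_jj / d delta
            tr_d = np.einsum("ijj,ij->", Vinv, ddiag)
            udVu_d = np.einsum("ij,ij->", u**2, ddiag)
            grad[6] = 0.5 * (tr_d - (N / quad) * udVu_d)
        return nll, beta_gls, sigma2, (AtVA, delta, Sigma_star), grad

    return nll_full


def _fit(model_cls, cohort, efw, with_covariates, fix_delta, tol, max_outer,
         warm_start=None, lme_maxiter=60, model_name=""):
    ids, T, Y, M, X, _names = _assemble(cohort, efw, with_covariates)
    model = model_cls(X)
    n = len(ids)

    if warm_start is not None:
        beta = warm_start["beta"].copy()
        theta = warm_start["theta"].copy()
        sigma2 = float(warm_start["sigma2"])
        b = np.zeros((n, 3))
    else:
        beta = model.start_beta(T, Y, M)
        mu0, _, _ = model.mean_jac(beta, np.zeros((n, 3)), T, M)
        delta0 = 0.5 if fix_delta is None else fix_delta
        w0 = np.maximum(np.abs(np.where(M, mu0, 1.0)), 1.0) ** delta0
        sigma2 = float(np.mean(((Y - mu0)[M] / w0[M]) ** 2)) + 1e-6
        sd0 = model.start_ranef_sd(beta) / np.sqrt(sigma2)
        L0 = np.diag(sd0)
        theta = _pack(L0, delta0)
        b = np.zeros((n, 3))

    history = []
    converged = False
    best = None
    prev_ll = -np.inf
    n_outer = 0

    def _lme_update(theta0, beta_c, b_c):
        nll_full = _make_lme_nll(model, beta_c, b_c, T, Y, M, fix_delta)

        def fg(th):
            out = nll_full(th, want_grad=True)
            return out[0], out[4]

        res = minimize(
            fg,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-14, 14)] * 3 + [(-50, 50)] * 3 + [(0.0, 3.0)],
            options={"maxiter": lme_maxiter, "ftol": 1e-12},
        )
        nll, beta_gls, sig2, extras = nll_full(res.x)
        return res.x, -nll, beta_gls, sig2, extras

    best_ll = -np.inf
    stall = 0
    for outer in range(max_outer):
        n_outer = outer + 1
        L, delta = _unpack(theta)
        if fix_delta is not None:
            delta = fix_delta
        Sigma = (L @ L.T) * sigma2
        Sigma_inv = np.linalg.pinv(Sigma + 1e-10 * np.eye(3))
        beta_c, b_c = _pnls_sweep(model, beta, b, T, Y, M, Sigma_inv, sigma2,
                                  delta)
        theta_c, ll, beta_gls, sig2, extras = _lme_update(theta, beta_c, b_c)
        if beta_gls is None or not np.isfinite(ll):
            warnings.warn("variance update failed; keeping previous parameters")
            break
        par_old = np.concatenate([beta, theta, [np.log(sigma2)]])
        b = b_c
        theta = theta_c
        sigma2 = sig2
        beta = beta_gls
        par_new = np.concatenate([beta, theta, [np.log(sigma2)]])
        par_delta = np.max(
            np.abs(par_new - par_old) / (np.abs(par_old) + 1.0)
        )
        # the incumbent is the best profile likelihood seen; the reported
        # history is its (non-decreasing) trajectory
        if ll > best_ll:
            if ll - best_ll < tol * (abs(ll) + 1.0) and np.isfinite(best_ll):
                stall += 1
            else:
                stall = 0
            best_ll = ll
            best = (theta.copy(), sigma2, beta.copy(), extras, b.copy())
        else:
            stall += 1
        history.append(best_ll)
        if stall >= 3 or par_delta < 1e-7:
            converged = True
            break
        prev_ll = ll

    if best is None:
        raise RuntimeError("model fitting failed before completing one iteration")
    theta, sigma2, beta, extras, b = best
    AtVA, delta, Sigma_star = extras
    Sigma = Sigma_star * sigma2
    Sigma_inv = np.linalg.pinv(Sigma + 1e-10 * np.eye(3))
    # final mode update at the converged parameters (beta stays at its GLS value)
    _, b = _refresh_modes(model, beta, b, T, Y, M, Sigma_inv, sigma2, delta)
    beta_cov = sigma2 * np.linalg.pinv(AtVA)

    if not converged:
        warnings.warn(
            f"{model_name}: not converged after {n_outer} iterations "
            f"(loglik {prev_ll:.6g}); returning flagged fit"
        )

    modes = pd.DataFrame({"id": ids, "b1": b[:, 0], "b2": b[:, 1], "b3": b[:, 2]})
    return model, ids, X, beta, Sigma, delta, sigma2, modes, history, converged, \
        n_outer, beta_cov, theta


def _refresh_modes(model, beta, b, T, Y, M, Sigma_inv, sigma2, delta):
    for _ in range(3):
        mu, _, B = model.mean_jac(beta, b, T, M)
        w_inv = _weight_inv(mu, M, delta)
        r = np.where(M, Y - mu, 0.0)
        G = np.einsum("ijk,ij,ijl->ikl", B, w_inv, B) / sigma2 + Sigma_inv[None]
        g = np.einsum("ijk,ij->ik", B, w_inv * r) / sigma2 - b @ Sigma_inv.T
        b = b + np.linalg.solve(G, g[..., None])[..., 0]
    return beta, b


def fit_logistic_nlme(
    cohort: Cohort,
    efw: pd.DataFrame,
    with_covariates: bool = False,
    *,
    fix_delta: float | None = None,
    tol: float = 1e-8,
    max_outer: int = 200,
    warm_start: dict | None = None,
    lme_maxiter: int = 60,
) -> LogisticNLMEFit:
    """Fit the three-parameter logistic NLME to EFW + birth-weight data.

    ``efw`` holds one row per ultrasound visit (columns id, t, efw); birth
    rows are taken from the cohort's unmasked birth weights.  Covariates
    enter the amplitude only.
    """
    (model, ids, X, beta, Sigma, delta, sigma2, modes, history, converged,
     n_outer, beta_cov, theta) = _fit(
        _LogisticModel, cohort, efw, with_covariates, fix_delta, tol,
        max_outer, warm_start, lme_maxiter, model_name="logistic NLME",
    )
    fit = LogisticNLMEFit(
        model="logistic",
        with_covariates=with_covariates,
        beta=beta,
        beta_names=model.beta_names(),
        Sigma=Sigma,
        delta=delta,
        sigma2=sigma2,
        ranef_modes=modes,
        loglik=history[-1] if history else np.nan,
        loglik_history=history,
        converged=converged,
        n_iter=n_outer,
        beta_cov=beta_cov,
        _X=X,
        _index={sid: i for i, sid in enumerate(ids)},
    )
    fit.warm_state = {"beta": beta, "theta": theta, "sigma2": sigma2}
    return fit


def fit_quadratic_lme(
    cohort: Cohort,
    efw: pd.DataFrame,
    with_covariates: bool = False,
    *,
    fix_delta: float | None = None,
    tol: float = 1e-8,
    max_outer: int = 200,
    warm_start: dict | None = None,
    lme_maxiter: int = 60,
) -> QuadraticLMEFit:
    """Fit the quadratic mixed-effects growth model (heteroscedastic errors)."""
    (model, ids, X, beta, Sigma, delta, sigma2, modes, history, converged,
     n_outer, beta_cov, theta) = _fit(
        _QuadraticModel, cohort, efw, with_covariates, fix_delta, tol,
        max_outer, warm_start, lme_maxiter, model_name="quadratic LME",
    )
    # transform time-scaled coefficients, covariance and modes to per-day units
    p = X.shape[1]
    scale = np.ones(p + 2)
    scale[p] = 1.0 / _TIME_SCALE
    scale[p + 1] = 1.0 / _TIME_SCALE**2
    beta_days = beta * scale
    cov_days = beta_cov * np.outer(scale, scale)
    D = np.diag([1.0, 1.0 / _TIME_SCALE, 1.0 / _TIME_SCALE**2])
    Sigma_days = D @ Sigma @ D.T
    modes_days = modes.copy()
    modes_days["b2"] = modes_days["b2"] / _TIME_SCALE
    modes_days["b3"] = modes_days["b3"] / _TIME_SCALE**2
    modes_days = modes_days.rename(columns={"b1": "b1", "b2": "b2", "b3": "b3"})
    modes_days.columns = ["id", "b1", "b2", "b3"]
    fit = QuadraticLMEFit(
        model="quadratic",
        with_covariates=with_covariates,
        beta=beta_days,
        beta_names=model.beta_names(),
        Sigma=Sigma_days,
        delta=delta,
        sigma2=sigma2,
        ranef_modes=modes_days,
        loglik=history[-1] if history else np.nan,
        loglik_history=history,
        converged=converged,
        n_iter=n_outer,
        beta_cov=cov_days,
        _X=X,
        _index={sid: i for i, sid in enumerate(ids)},
    )
    fit.warm_state = {"beta": beta, "theta": theta, "sigma2": sigma2}
    return fit


def predict_weight(fit: GrowthFit, subject_id, t):
    """Predicted weight (g) for a fitted subject at any gestational age t."""
    return fit.predict(subject_id, t)
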