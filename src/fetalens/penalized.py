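"""Penalized and constrained regression solvers for learner selection.

Implements the three coefficient penalties used to prune correlated
first-level learners — LASSO, SCAD (smoothly clipped absolute deviation,
shape ``a``) and MCP (minimax concave penalty, shape ``gamma``) — for both
squared-error and logistic loss, plus a positive-constrained logistic
regression used as a stacking meta-learner.

The solvers are plain coordinate descent on internally standardized columns
with warm starts along a decreasing lambda path; the logistic loss is
handled by outer iteratively-reweighted least squares with a step-halving
safeguard on the penalized deviance.  For weighted subproblems the
nonconvex penalties use adaptive rescaling (the penalty level is scaled by
the coordinate's curvature), which keeps every univariate update
well-defined regardless of the IRLS weights.  Lambda is chosen by
stratified K-fold cross-validation at the deviance (or MSE) minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "penalty_threshold",
    "fit_penalized_logistic",
    "fit_penalized_linear",
    "fit_positive_logistic",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family and shape parameters.

    ``lam`` may be None, in which case the fitting routines select it by
    cross-validation over a log-spaced path.
    """

    family: str  # "lasso", "scad" or "mcp"
    lam: float | None = None
    a: float = 3.7  # SCAD shape
    gamma: float = 3.0  # MCP shape

    def __post_init__(self):
        if self.family not in ("lasso", "scad", "mcp"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.a <= 2:
            raise ValueError("SCAD shape a must exceed 2")
        if self.gamma <= 1:
            raise ValueError("MCP shape gamma must exceed 1")


def _soft(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def penalty_threshold(z, spec: PenaltySpec, v: float = 1.0):
    """Univariate penalized least-squares minimizer.

    Solves ``argmin_b 0.5 v b^2 - z b + P(|b|; lam)`` — with ``v = 1`` this
    is the textbook thresholding operator of each penalty (soft threshold
    for LASSO; SCAD and MCP leave large ``z`` unpenalized).
    """
    lam = spec.lam
    if lam is None:
        raise ValueError("penalty_threshold requires spec.lam")
    z = np.asarray(z, dtype=float)
    if spec.family == "lasso":
        out = _soft(z, lam) / v
    elif spec.family == "scad":
        a = spec.a
        out = np.where(
            np.abs(z) <= lam * (v + 1.0),
            _soft(z, lam) / v,
            np.where(
                np.abs(z) <= lam * a * v,
                ((a - 1.0) * z - np.sign(z) * a * lam) / ((a - 1.0) * v - 1.0),
                z / v,
            ),
        )
    else:  # mcp
        g = spec.gamma
        v_arr = np.asarray(v, dtype=float)
        denom = v_arr - 1.0 / g
        # when the coordinate curvature is below 1/gamma the univariate
        # problem is concave inside the MCP region and the minimizer sits at
        # a region end (hard thresholding)
        inner = np.where(
            denom > 0,
            _soft(z, lam) / np.where(denom > 0, denom, 1.0),
            0.0,
        )
        out = np.where(np.abs(z) <= g * lam * v_arr, inner, z / v_arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class PenalizedFit:
    """A fitted penalized model on the original predictor scale."""

    family: str
    loss: str  # "logistic" or "linear"
    intercept: float
    coefficients: np.ndarray
    chosen_lambda: float
    lambda_path: np.ndarray = field(repr=False)
    cv_curve: np.ndarray | None = field(default=None, repr=False)
    coef_path: np.ndarray | None = field(default=None, repr=False)
    n_folds: int | None = None

    @property
    def active_set(self) -> np.ndarray:
        return np.nonzero(self.coefficients != 0.0)[0]

    def linear_predictor(self, X):
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X):
        eta = np.clip(self.linear_predictor(X), -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X):
        if self.loss == "logistic":
            return (self.predict_proba(X) > 0.5).astype(int)
        return self.linear_predictor(X)


def _standardize(X):
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Xs = np.where(ok, (X - mean) / np.where(ok, sd, 1.0), 0.0)
    return Xs, mean, sd, ok


def _thresh_scalar(z, v, lam, family, a, gamma):
    """Coordinate update with adaptive rescaling (Breheny & Huang).

    The penalty is applied in the curvature-standardized metric (divide the
    subproblem through by ``v``), which coincides with the exact operator
    when ``v = 1`` — the case of standardized columns with unit weights —
    and keeps SCAD/MCP updates continuous for any IRLS curvature.
    """
    zs = z / v
    ls = lam / v
    azs = abs(zs)
    sgn = 1.0 if zs >= 0 else -1.0
    if family == "lasso":
        s = azs - ls
        return sgn * s if s > 0 else 0.0
    if family == "scad":
        if azs <= 2.0 * ls:
            s = azs - ls
            return sgn * s if s > 0 else 0.0
        if azs <= a * ls:
            return ((a - 1.0) * zs - sgn * a * ls) / (a - 2.0)
        return zs
    # mcp
    if azs <= gamma * ls:
        s = azs - ls
        return sgn * s / (1.0 - 1.0 / gamma) if s > 0 else 0.0
    return zs


def _thresh_vec(z, v, lam, family, a, gamma):
    """Vectorized twin of :func:`_thresh_scalar` (z, v are arrays)."""
    zs = z / v
    ls = lam / v
    azs = np.abs(zs)
    if family == "lasso":
        return _soft(zs, ls)
    if family == "scad":
        return np.where(
            azs <= 2.0 * ls,
            _soft(zs, ls),
            np.where(
                azs <= a * ls,
                ((a - 1.0) * zs - np.sign(zs) * a * ls) / (a - 2.0),
                zs,
            ),
        )
    return np.where(azs <= gamma * ls, _soft(zs, ls) / (1.0 - 1.0 / gamma), zs)


_FAM_CODE = {"lasso": 0, "scad": 1, "mcp": 2}


@njit(cache=False, fastmath=False)
def _thresh_jit(z, v, lam, fam, a, g):  # pragma: no cover - numba kernel
    zs = z / v
    ls = lam / v
    azs = abs(zs)
    sgn = 1.0 if zs >= 0 else -1.0
    if fam == 0:
        s = azs - ls
        return sgn * s if s > 0 else 0.0
    if fam == 1:
        if azs <= 2.0 * ls:
            s = azs - ls
            return sgn * s if s > 0 else 0.0
        if azs <= a * ls:
            return ((a - 1.0) * zs - sgn * a * ls) / (a - 2.0)
        return zs
    if azs <= g * ls:
        s = azs - ls
        return sgn * s / (1.0 - 1.0 / g) if s > 0 else 0.0
    return zs


@njit(cache=False)
def _cd_kernel(Xs, z_resid, wn, v, beta, lam, fam, a, g, tol,
               max_cycles):  # pragma: no cover - numba kernel
    n, p = Xs.shape
    for _cycle in range(max_cycles):
        max_change = 0.0
        for j in range(p):
            if v[j] <= 0.0:
                continue
            bj = beta[j]
            zj = v[j] * bj
            for i in range(n):
                zj += wn[i] * Xs[i, j] * z_resid[i]
            new = _thresh_jit(zj, v[j], lam, fam, a, g)
            if new != bj:
                d = new - bj
                for i in range(n):
                    z_resid[i] -= Xs[i, j] * d
                c = abs(d) * np.sqrt(v[j])
                if c > max_change:
                    max_change = c
                beta[j] = new
        if max_change < tol:
            break
        for _inner in range(50):
            mc = 0.0
            for j in range(p):
                if beta[j] == 0.0 or v[j] <= 0.0:
                    continue
                bj = beta[j]
                zj = v[j] * bj
                for i in range(n):
                    zj += wn[i] * Xs[i, j] * z_resid[i]
                new = _thresh_jit(zj, v[j], lam, fam, a, g)
                if new != bj:
                    d = new - bj
                    for i in range(n):
                        z_resid[i] -= Xs[i, j] * d
                    c = abs(d) * np.sqrt(v[j])
                    if c > mc:
                        mc = c
                    beta[j] = new
            if mc < tol:
                break


def _cd_weighted(Xs, z_resid, w, beta, lam, spec, tol=1e-9, max_cycles=100):
    """Coordinate descent for 0.5 mean(w r^2) + penalty(beta).

    Full sweeps alternate with active-set cycles inside a compiled kernel;
    ``z_resid`` is maintained as the current working residual and updated in
    place.  Nonconvex updates use adaptive rescaling (see
    :func:`_thresh_scalar`).
    """
    n, p = Xs.shape
    v = (w[:, None] * Xs**2).mean(axis=0)
    wn = w / n
    Xf = np.asfortranarray(Xs)
    _cd_kernel(Xf, z_resid, wn, v, beta, float(lam),
               _FAM_CODE[spec.family], float(spec.a), float(spec.gamma),
               float(tol), int(max_cycles))
    return beta, z_resid


def _penalty_value(beta, lam, spec):
    b = np.abs(beta)
    if spec.family == "lasso":
        return lam * b.sum()
    if spec.family == "scad":
        a = spec.a
        p1 = np.where(b <= lam, lam * b, 0.0)
        p2 = np.where(
            (b > lam) & (b <= a * lam),
            (2 * a * lam * b - b**2 - lam**2) / (2 * (a - 1)),
            0.0,
        )
        p3 = np.where(b > a * lam, lam**2 * (a + 1) / 2.0, 0.0)
        return (p1 + p2 + p3).sum()
    g = spec.gamma
    p1 = np.where(b <= g * lam, lam * b - b**2 / (2 * g), 0.0)
    p2 = np.where(b > g * lam, 0.5 * g * lam**2, 0.0)
    return (p1 + p2).sum()


def _logistic_nll(eta, y):
    # mean negative log-likelihood, numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def _irls_solve(Xs, y, spec, lam, b0, beta, tol=1e-9, max_irls=12, cd_tol=1e-9):
    """Penalized logistic fit at one lambda from a warm start.

    Outer IRLS with exact CD on each weighted quadratic, safeguarded by
    step-halving on the true penalized deviance so the objective never
    increases.
    """
    obj_prev = _logistic_nll(b0 + Xs @ beta, y) + _penalty_value(beta, lam, spec)
    for _ in range(max_irls):
        eta = b0 + Xs @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        beta_old, b0_old = beta.copy(), b0
        resid = z - b0 - Xs @ beta
        b0 = b0 + float((w * resid).mean() / w.mean())
        resid = z - b0 - Xs @ beta
        beta, resid = _cd_weighted(Xs, resid, w, beta, lam, spec, tol=cd_tol)
        obj = _logistic_nll(b0 + Xs @ beta, y) + _penalty_value(beta, lam, spec)
        shrink = 0
        while obj > obj_prev + 1e-14 and shrink < 12:
            beta = 0.5 * (beta + beta_old)
            b0 = 0.5 * (b0 + b0_old)
            obj = _logistic_nll(b0 + Xs @ beta, y) + _penalty_value(
                beta, lam, spec
            )
            shrink += 1
        if abs(obj_prev - obj) < tol * (abs(obj) + 1.0):
            break
        obj_prev = obj
    return b0, beta


def _fit_path(Xs, y, spec, lambdas, loss, tight=False):
    """Solution path over decreasing lambda with warm starts.

    Nonconvex families (SCAD/MCP) first trace the LASSO path and then polish
    each solution under their own penalty, which mitigates poor local minima
    (the solver keeps the previous-lambda polished solution when it attains
    a lower penalized objective than the lasso-started one).
    """
    n, p = Xs.shape
    path = np.zeros((len(lambdas), p + 1))
    lasso = PenaltySpec("lasso")
    kw = (dict(tol=1e-12, max_irls=300, cd_tol=1e-13) if tight
          else dict(tol=1e-7, max_irls=5, cd_tol=1e-7))
    cd_tol = 1e-13 if tight else 1e-9

    if loss == "logistic":
        b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
        null_nll = _logistic_nll(np.full(n, b0), y)
        beta = np.zeros(p)
        for k, lam in enumerate(lambdas):
            b0, beta = _irls_solve(Xs, y, lasso if spec.family != "lasso"
                                   else spec, lam, b0, beta, **kw)
            path[k] = np.concatenate([[b0], beta])
            # saturation: once the deviance is essentially exhausted the
            # remaining (smaller) lambdas would only refit noise — carry the
            # solution forward, as glmnet does
            if not tight and _logistic_nll(b0 + Xs @ beta, y) < 0.01 * null_nll:
                path[k + 1:] = path[k]
                break
        if spec.family != "lasso":
            prev = None
            last_start = None
            for k, lam in enumerate(lambdas):
                start = path[k].copy()
                if (not tight and prev is not None and last_start is not None
                        and np.array_equal(start, last_start)):
                    # lasso path saturated here; reuse the polished solution
                    path[k] = prev
                    continue
                last_start = start
                bb0, bb = _irls_solve(Xs, y, spec, lam, float(start[0]),
                                      start[1:].copy(), **kw)
                path[k] = np.concatenate([[bb0], bb])
                prev = path[k]
    else:
        b0 = float(y.mean())
        beta = np.zeros(p)
        w = np.ones(n)
        for k, lam in enumerate(lambdas):
            resid = y - b0 - Xs @ beta
            beta, resid = _cd_weighted(
                Xs, resid, w, beta,
                lam, lasso if spec.family != "lasso" else spec, tol=cd_tol,
            )
            b0 = b0 + float(resid.mean())
            path[k] = np.concatenate([[b0], beta])
        if spec.family != "lasso":
            for k, lam in enumerate(lambdas):
                bb0, bb = float(path[k][0]), path[k][1:].copy()
                resid = y - bb0 - Xs @ bb
                bb, resid = _cd_weighted(Xs, resid, w, bb, lam, spec,
                                         tol=cd_tol)
                bb0 = bb0 + float(resid.mean())
                path[k] = np.concatenate([[bb0], bb])
    return path


def _lambda_path(Xs, y, center, n_lambda=100, min_ratio=0.001):
    resid0 = y - center
    lam_max = np.max(np.abs(Xs.T @ resid0)) / len(y)
    lam_max = max(lam_max, 1e-10)
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def _cv_choose(X, y, spec, lambdas, loss, n_folds, seed):
    y = np.asarray(y, dtype=float)
    if loss == "logistic":
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    losses = np.zeros((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(splits):
        Xs, mean, sd, ok = _standardize(X[tr])
        Xv = np.where(ok, (X[va] - mean) / np.where(ok, sd, 1.0), 0.0)
        path = _fit_path(Xs, y[tr], spec, lambdas, loss)
        eta = path[:, 0][None, :] + Xv @ path[:, 1:].T  # (n_va, n_lambda)
        if loss == "logistic":
            losses[f] = 2 * np.mean(
                np.logaddexp(0.0, eta) - y[va][:, None] * eta, axis=0
            )
        else:
            losses[f] = np.mean((y[va][:, None] - eta) ** 2, axis=0)
    curve = losses.mean(axis=0)
    return curve, lambdas[int(np.argmin(curve))]


def _finalize(X, y, spec, lam, lambdas, curve, loss, n_folds):
    Xs, mean, sd, ok = _standardize(X)
    path = _fit_path(Xs, y, spec, lambdas, loss, tight=(len(lambdas) == 1))
    k = int(np.argmin(np.abs(lambdas - lam)))
    b0_s, beta_s = path[k, 0], path[k, 1:]
    coef = np.where(ok, beta_s / np.where(ok, sd, 1.0), 0.0)
    intercept = b0_s - float(mean @ coef)
    # de-standardized coefficient path for inspection
    coef_path = np.where(ok[None, :], path[:, 1:] / np.where(ok, sd, 1.0), 0.0)
    if loss == "logistic" and _logistic_nll(
        intercept + X @ coef, np.asarray(y, float)
    ) < 1e-8:
        warnings.warn(
            "perfect separation on the training data; solution taken at the "
            "requested end of the lambda path"
        )
    return PenalizedFit(
        family=spec.family,
        loss=loss,
        intercept=float(intercept),
        coefficients=coef,
        chosen_lambda=float(lam),
        lambda_path=lambdas,
        cv_curve=curve,
        coef_path=coef_path,
        n_folds=n_folds,
    )


def _prepare(X, y, loss):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    if loss == "logistic":
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("y must contain both classes")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
    return X, y


def fit_penalized_logistic(
    X,
    y,
    spec: PenaltySpec | str = "lasso",
    n_folds: int = 10,
    seed: int | None = None,
    n_lambda: int = 100,
) -> PenalizedFit:
    """Penalized logistic regression along a lambda path with CV selection.

    When ``spec.lam`` is given the model is fitted at that single value
    (``lam=0`` reproduces the unpenalized maximum-likelihood fit); otherwise
    lambda is chosen at the minimum of the stratified K-fold CV deviance.
    """
    if isinstance(spec, str):
        spec = PenaltySpec(spec)
    X, y = _prepare(X, y, "logistic")
    Xs, mean, sd, ok = _standardize(X)
    if spec.lam is not None:
        lambdas = np.array([spec.lam])
        return _finalize(X, y, spec, spec.lam, lambdas, None, "logistic", None)
    lambdas = _lambda_path(Xs, y, y.mean(), n_lambda)
    n_folds = min(n_folds, int(min(np.bincount(y.astype(int)))))
    n_folds = max(n_folds, 2)
    curve, lam = _cv_choose(X, y, spec, lambdas, "logistic", n_folds, seed)
    return _finalize(X, y, spec, lam, lambdas, curve, "logistic", n_folds)


def fit_penalized_linear(
    X,
    y,
    spec: PenaltySpec | str = "lasso",
    n_folds: int = 10,
    seed: int | None = None,
    n_lambda: int = 100,
) -> PenalizedFit:
    """Penalized linear regression (squared-error analogue of the above)."""
    if isinstance(spec, str):
        spec = PenaltySpec(spec)
    X, y = _prepare(X, y, "linear")
    Xs, mean, sd, ok = _standardize(X)
    if spec.lam is not None:
        lambdas = np.array([spec.lam])
        return _finalize(X, y, spec, spec.lam, lambdas, None, "linear", None)
    lambdas = _lambda_path(Xs, y, y.mean(), n_lambda)
    curve, lam = _cv_choose(X, y, spec, lambdas, "linear", n_folds, seed)
    return _finalize(X, y, spec, lam, lambdas, curve, "linear", n_folds)


def fit_positive_logistic(X, y, tol: float = 1e-10):
    """Logistic regression with non-negative slope coefficients.

    The intercept is unconstrained.  Returns a :class:`PenalizedFit` (family
    "positive", no penalty); at the optimum the KKT conditions hold: every
    coordinate has either a zero gradient or a zero coefficient with an
    outward-pointing gradient.
    """
    X, y = _prepare(X, y, "logistic")
    n, p = X.shape

    def nll_grad(par):
        b0, beta = par[0], par[1:]
        eta = np.clip(b0 + X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        nll = np.mean(np.logaddexp(0.0, b0 + X @ beta) - y * (b0 + X @ beta))
        resid = mu - y
        return nll, np.concatenate([[resid.mean()], X.T @ resid / n])

    x0 = np.zeros(p + 1)
    x0[0] = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
    res = minimize(
        nll_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0.0, None)] * p,
        options={"maxiter": 2000, "ftol": tol},
    )
    coef = res.x[1:].copy()
    coef[coef < 1e-10] = 0.0
    return PenalizedFit(
        family="positive",
        loss="logistic",
        intercept=float(res.x[0]),
        coefficients=coef,
        chosen_lambda=0.0,
        lambda_path=np.array([0.0]),
    )
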