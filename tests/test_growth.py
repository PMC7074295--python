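"""Growth-model engine: oracles, limits, equivariance and masking contract."""

import numpy as np
import pandas as pd
import pytest

from fetalens.growth import fit_logistic_nlme, fit_quadratic_lme, predict_weight
from tests.conftest import make_longitudinal_cohort


def _logistic(t, p1, p2, p3):
    return p1 / (1 + np.exp(-(np.asarray(t, float) - p2) / p3))


def _sim_logistic(seed, n=150, sds=(300.0, 3.0, 1.0), delta=0.5, sigma=2.5,
                  beta=(4400.0, 240.0, 28.0)):
    rng = np.random.default_rng(seed)
    b = rng.standard_normal((n, 3)) * np.asarray(sds)
    visit = np.array([17, 25, 33, 37.0]) * 7
    subs, long = [], []
    for i in range(n):
        tv = np.sort(visit + rng.normal(0, 3, 4))
        ga = max(rng.normal(280, 8.34), tv.max() + 2)
        ts = np.append(tv, ga)
        mu = _logistic(ts, beta[0] + b[i, 0], beta[1] + b[i, 1], beta[2] + b[i, 2])
        y = mu + rng.normal(0, 1, 5) * sigma * np.abs(mu) ** delta
        subs.append((i + 1, ga, y[-1]))
        long.extend((i + 1, t, v) for t, v in zip(ts[:-1], y[:-1]))
    return make_longitudinal_cohort(subs, long)


class TestLogisticNLME:
    def test_mean_function_half_amplitude_at_midpoint(self):
        cohort, efw = _sim_logistic(0, n=60)
        fit = fit_logistic_nlme(cohort, efw)
        sid = cohort.subjects["id"].iloc[0]
        i = fit._index[sid]
        b = fit.ranef_modes[["b1", "b2", "b3"]].to_numpy()[i]
        phi1 = fit._X[i] @ fit.beta1 + b[0]
        phi2 = fit.beta2 + b[1]
        assert fit.predict(sid, phi2) == pytest.approx(phi1 / 2, rel=1e-9)

    def test_amplitude_is_late_time_asymptote(self):
        cohort, efw = _sim_logistic(1, n=60)
        fit = fit_logistic_nlme(cohort, efw)
        sid = cohort.subjects["id"].iloc[3]
        i = fit._index[sid]
        phi1 = fit._X[i] @ fit.beta1 + fit.ranef_modes["b1"].iloc[i]
        assert predict_weight(fit, sid, 10_000.0) == pytest.approx(phi1, rel=1e-9)

    def test_pooled_nls_limit(self):
        # no random effects, homoscedastic noise: estimates agree with
        # pooled nonlinear least squares from a generic optimizer
        cohort, efw = _sim_logistic(2, n=120, sds=(0.0, 0.0, 0.0),
                                    delta=0.0, sigma=60.0)
        fit = fit_logistic_nlme(cohort, efw, fix_delta=0.0)

        rows = []
        for _, r in efw.iterrows():
            rows.append((r["t"], r["efw"]))
        for _, s in cohort.subjects.iterrows():
            rows.append((s["birth_ga"], s["birth_weight"]))
        t = np.array([a for a, _ in rows])
        y = np.array([b for _, b in rows])
        from scipy.optimize import minimize

        def sse(par):
            return np.sum((y - _logistic(t, *par)) ** 2)

        oracle = minimize(sse, np.array([4500.0, 235.0, 30.0]),
                          method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10,
                                   "maxiter": 5000})
        assert np.allclose(fit.beta, oracle.x, rtol=5e-3)

    def test_time_shift_equivariance(self):
        cohort, efw = _sim_logistic(3, n=80)
        fit0 = fit_logistic_nlme(cohort, efw)
        shift = 50.0
        subs2 = cohort.subjects.copy()
        subs2["birth_ga"] = subs2["birth_ga"] + shift
        efw2 = efw.copy()
        efw2["t"] = efw2["t"] + shift
        visits2 = cohort.visits.copy()
        visits2["t"] = visits2["t"] + shift
        from fetalens.simulate import Cohort

        fit1 = fit_logistic_nlme(Cohort(subjects=subs2, visits=visits2), efw2)
        assert fit1.beta2 == pytest.approx(fit0.beta2 + shift, abs=0.5)
        sid = cohort.subjects["id"].iloc[0]
        assert fit1.predict(sid, 280.0 + shift) == pytest.approx(
            fit0.predict(sid, 280.0), rel=2e-3
        )

    def test_loglik_history_nondecreasing(self):
        cohort, efw = _sim_logistic(4, n=80)
        fit = fit_logistic_nlme(cohort, efw)
        h = np.asarray(fit.loglik_history)
        assert len(h) >= 1
        assert np.all(np.diff(h) >= -1e-9)

    def test_unknown_subject_raises(self):
        cohort, efw = _sim_logistic(5, n=30)
        fit = fit_logistic_nlme(cohort, efw)
        with pytest.raises(KeyError):
            predict_weight(fit, 99_999, 280.0)

    def test_masked_birth_weights_never_read(self):
        # replacing masked test weights by absurd values must not change the
        # fit: the masked rows contribute nothing to the likelihood
        cohort, efw = _sim_logistic(6, n=80)
        test_ids = cohort.subjects["id"].iloc[-20:].to_numpy()
        masked = cohort.mask_birth_weights(test_ids)
        poisoned = masked.subjects.copy()
        # NaN marks masked; swap in a second cohort where the original
        # weights were garbage before masking
        garbage = cohort.subjects.copy()
        garbage.loc[garbage["id"].isin(test_ids), "birth_weight"] = 9e9
        from fetalens.simulate import Cohort

        masked_garbage = Cohort(
            subjects=garbage, visits=cohort.visits.copy()
        ).mask_birth_weights(test_ids)
        f1 = fit_logistic_nlme(masked, efw)
        f2 = fit_logistic_nlme(masked_garbage, efw)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        # masked subjects still get predictions from their ultrasound rows
        for sid in test_ids[:3]:
            assert np.isfinite(f1.predict(sid, 280.0))

    def test_prediction_correlates_with_truth_and_improves_with_visits(self):
        cohort, efw = _sim_logistic(7, n=120)
        test_ids = cohort.subjects["id"].iloc[-40:].to_numpy()
        masked = cohort.mask_birth_weights(test_ids)
        truth = cohort.subjects.set_index("id").loc[test_ids, "birth_weight"]
        ga = cohort.subjects.set_index("id").loc[test_ids, "birth_ga"]

        def corr_with(n_visits):
            keep = efw.groupby("id").head(n_visits)
            fit = fit_logistic_nlme(masked, keep)
            pred = fit.predict_many(test_ids, ga.to_numpy())
            return np.corrcoef(pred, truth)[0, 1]

        c2, c4 = corr_with(2), corr_with(4)
        assert c2 > 0
        assert c4 > c2

    def test_nonconvergence_is_flagged_not_fatal(self):
        cohort, efw = _sim_logistic(8, n=40)
        with pytest.warns(UserWarning, match="not converged"):
            fit = fit_logistic_nlme(cohort, efw, max_outer=1)
        assert fit.converged is False
        assert np.isfinite(fit.loglik)


class TestQuadraticLME:
    def test_noiseless_exact_recovery(self):
        truth = np.array([914.9, -17.728, 0.09708])
        rng = np.random.default_rng(0)
        subs, long = [], []
        for i in range(12):
            tv = np.sort(np.array([119, 175, 231, 259.0]) + rng.normal(0, 2, 4))
            ga = 280.0 + rng.normal(0, 5)
            ts = np.append(tv, ga)
            mu = truth[0] + truth[1] * ts + truth[2] * ts**2
            subs.append((i + 1, ga, mu[-1]))
            long.extend((i + 1, t, v) for t, v in zip(ts[:-1], mu[:-1]))
        cohort, efw = make_longitudinal_cohort(subs, long)
        fit = fit_quadratic_lme(cohort, efw, fix_delta=0.0)
        assert np.allclose(fit.beta, truth, rtol=1e-6)

    def test_gls_closed_form_oracle_balanced_design(self):
        # 3 subjects x 4 shared times, known variance parameters: the final
        # fixed effects must solve the GLS normal equations at the fitted
        # covariance (internal consistency of the profiled update)
        rng = np.random.default_rng(1)
        times = np.array([120.0, 180.0, 240.0, 275.0])
        truth = np.array([900.0, -17.0, 0.095])
        subs, long = [], []
        for i in range(30):
            b0 = rng.normal(0, 100)
            ga = 281.0 + rng.normal(0, 2)
            ts = np.append(times, ga)
            mu = truth[0] + b0 + truth[1] * ts + truth[2] * ts**2
            y = mu + rng.normal(0, 30, ts.size)
            subs.append((i + 1, ga, y[-1]))
            long.extend((i + 1, t, v) for t, v in zip(ts[:-1], y[:-1]))
        cohort, efw = make_longitudinal_cohort(subs, long)
        fit = fit_quadratic_lme(cohort, efw, fix_delta=0.0)

        # GLS oracle with the fitted Sigma/sigma2 on raw-day design
        Sigma = fit.Sigma
        rows_by = {}
        for _, r in efw.iterrows():
            rows_by.setdefault(int(r["id"]), []).append((r["t"], r["efw"]))
        for _, s in cohort.subjects.iterrows():
            rows_by[int(s["id"])].append((s["birth_ga"], s["birth_weight"]))
        A_acc = np.zeros((3, 3))
        b_acc = np.zeros(3)
        for sid, rows in rows_by.items():
            t = np.array([a for a, _ in rows])
            y = np.array([b for _, b in rows])
            Z = np.column_stack([np.ones_like(t), t, t**2])
            V = Z @ Sigma @ Z.T + fit.sigma2 * np.eye(len(t))
            Vi = np.linalg.inv(V)
            A_acc += Z.T @ Vi @ Z
            b_acc += Z.T @ Vi @ y
        oracle = np.linalg.solve(A_acc, b_acc)
        assert np.allclose(fit.beta, oracle, rtol=1e-4)

    def test_interpolates_noiseless_training_data(self):
        truth = np.array([900.0, -17.0, 0.095])
        rng = np.random.default_rng(2)
        subs, long = [], []
        for i in range(10):
            tv = np.sort(np.array([119, 175, 231, 259.0]) + rng.normal(0, 2, 4))
            ga = 280.0
            ts = np.append(tv, ga)
            b0 = rng.normal(0, 50)
            mu = truth[0] + b0 + truth[1] * ts + truth[2] * ts**2
            subs.append((i + 1, ga, mu[-1]))
            long.extend((i + 1, t, v) for t, v in zip(ts[:-1], mu[:-1]))
        cohort, efw = make_longitudinal_cohort(subs, long)
        fit = fit_quadratic_lme(cohort, efw, fix_delta=0.0)
        for _, r in efw.iloc[:8].iterrows():
            assert fit.predict(int(r["id"]), r["t"]) == pytest.approx(
                r["efw"], rel=1e-4
            )
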