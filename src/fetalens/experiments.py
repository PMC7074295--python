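"""Reusable simulation studies: parameter recovery and ensemble gain.

These are the package's two headline validation experiments.

``recovery_study`` simulates longitudinal responses directly from each
growth model's own equations at known parameters and refits, reporting the
relative bias of every fixed effect and the coverage of 95% Wald
intervals.

``ensemble_gain_study`` runs the full pipeline on scaled-down synthetic
cohorts with a reduced learner grid (two model variants x six formulas) and
compares the held-out Youden index of SCAD-selected voting and stacking
against the best single learner, mirroring the finding that penalized
ensemble selection outperforms any individual model/formula combination.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from fetalens.classify import LearnerDef, build_learner_panel, fit_learner
from fetalens.ensemble import (
    build_leave_one_data,
    cv_votes_from_meta,
    fit_stacking,
    fit_voting,
    predict_ensemble,
)
from fetalens.growth import fit_logistic_nlme, fit_quadratic_lme
from fetalens.metrics import confusion, rates
from fetalens.simulate import Cohort, SimulationConfig, simulate_cohort, stratified_split

__all__ = [
    "LOGISTIC_TRUTH",
    "QUADRATIC_TRUTH",
    "simulate_from_logistic",
    "simulate_from_quadratic",
    "recovery_study",
    "ensemble_gain_study",
]

log = logging.getLogger(__name__)

#: Generating truth for the logistic recovery study — the cohort
#: generator's default dynamics (amplitude ~ birth weight mean / logistic
#: attenuation, midpoint and stretch in days, ranef SDs from the default
#: variance budget).
LOGISTIC_TRUTH = {
    "beta": np.array([4400.0, 240.0, 28.0]),
    "ranef_sd": np.array([470.0, 4.0, 1.5]),
    "corr12": 0.3,
    "delta": 0.5,
    "sigma": 2.5,
}

#: Quadratic-model truth: coefficients interpolating a typical weight curve
#: (180 g at 17 weeks, 2000 g at 33 weeks, 3562 g at term).
QUADRATIC_TRUTH = {
    "beta": np.array([914.9, -17.728, 0.09708]),
    "ranef_sd": np.array([150.0, 1.0, 0.004]),
    "corr12": 0.0,
    "delta": 0.5,
    "sigma": 2.5,
}

_COV_COLS = [
    "maternal_age", "bmi", "smoking_level", "hbp", "cardiac", "diabetes",
    "renal", "other_disease",
]


def _package(rows_subs, rows_long):
    subs = pd.DataFrame(rows_subs, columns=["id", "birth_ga", "birth_weight"])
    for c in _COV_COLS:
        subs[c] = 0.0
    long = pd.DataFrame(rows_long, columns=["id", "t", "efw"])
    visits = pd.DataFrame(
        {"id": long["id"], "t": long["t"], "bpd": 50.0, "mad": 50.0, "fl": 30.0}
    )
    return Cohort(subjects=subs, visits=visits), long


def _visit_times(rng, n):
    base = np.array([17.0, 25.0, 33.0, 37.0]) * 7.0
    tv = np.sort(base[None, :] + rng.normal(0.0, 3.0, size=(n, 4)), axis=1)
    ga = rng.normal(280.0, 8.34, size=n)
    ga = np.maximum(ga, tv.max(axis=1) + 2.0)
    return tv, ga


def simulate_from_logistic(seed, n=500, truth=LOGISTIC_TRUTH):
    """Longitudinal data drawn exactly from the logistic NLME equations."""
    rng = np.random.default_rng(seed)
    b1, b2, b3 = truth["beta"]
    s = truth["ranef_sd"]
    Sigma = np.diag(s**2).astype(float)
    Sigma[0, 1] = Sigma[1, 0] = truth["corr12"] * s[0] * s[1]
    b = rng.multivariate_normal(np.zeros(3), Sigma, size=n)
    phi1, phi2, phi3 = b1 + b[:, 0], b2 + b[:, 1], b3 + b[:, 2]
    tv, ga = _visit_times(rng, n)
    rows_subs, rows_long = [], []
    for i in range(n):
        ts = np.append(tv[i], ga[i])
        mu = phi1[i] / (1.0 + np.exp(-(ts - phi2[i]) / phi3[i]))
        y = mu + rng.normal(0, 1, ts.size) * truth["sigma"] * np.abs(mu) ** truth["delta"]
        rows_subs.append((i + 1, ga[i], y[-1]))
        rows_long.extend((i + 1, t, v) for t, v in zip(ts[:-1], y[:-1]))
    return _package(rows_subs, rows_long)


def simulate_from_quadratic(seed, n=500, truth=QUADRATIC_TRUTH):
    """Longitudinal data drawn exactly from the quadratic LME equations."""
    rng = np.random.default_rng(seed)
    s = truth["ranef_sd"]
    b = rng.standard_normal((n, 3)) * s
    tv, ga = _visit_times(rng, n)
    b0, th1, th2 = truth["beta"]
    rows_subs, rows_long = [], []
    for i in range(n):
        ts = np.append(tv[i], ga[i])
        mu = (b0 + b[i, 0]) + (th1 + b[i, 1]) * ts + (th2 + b[i, 2]) * ts**2
        y = mu + rng.normal(0, 1, ts.size) * truth["sigma"] * np.abs(mu) ** truth["delta"]
        rows_subs.append((i + 1, ga[i], y[-1]))
        rows_long.extend((i + 1, t, v) for t, v in zip(ts[:-1], y[:-1]))
    return _package(rows_subs, rows_long)


def recovery_study(n_reps=20, n_subjects=500, seed=0, models=("logistic", "quadratic")):
    """Bias and Wald-coverage of fixed effects under known truth.

    Returns a dict per model with ``bias_pct`` (mean estimate vs truth, in
    percent) and ``coverage`` (fraction of replicates whose 95% Wald
    interval covers the truth), one entry per fixed effect.
    """
    ss = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    out = {}
    for model in models:
        truth = LOGISTIC_TRUTH if model == "logistic" else QUADRATIC_TRUTH
        sim = simulate_from_logistic if model == "logistic" else simulate_from_quadratic
        fit_fn = fit_logistic_nlme if model == "logistic" else fit_quadratic_lme
        est, cover = [], []
        for r in range(n_reps):
            cohort, efw = sim(int(ss[r]), n=n_subjects)
            fit = fit_fn(cohort, efw)
            est.append(fit.beta)
            se = fit.beta_se()
            cover.append(np.abs(fit.beta - truth["beta"]) <= 1.96 * se)
        est = np.asarray(est)
        out[model] = {
            "truth": truth["beta"].tolist(),
            "mean_estimate": est.mean(axis=0).tolist(),
            "bias_pct": (
                100.0 * (est.mean(axis=0) - truth["beta"]) / truth["beta"]
            ).tolist(),
            "coverage": np.asarray(cover, dtype=float).mean(axis=0).tolist(),
            "n_reps": n_reps,
            "n_subjects": n_subjects,
        }
    return out


#: Reduced learner grid for the scaled-down ensemble study: two model
#: variants and six formulas spanning the bank's functional families.
GAIN_MODELS = ("nlme", "qlme")
GAIN_FORMULAS = (1, 4, 6, 9, 11, 23)

_CV_FIT_KW = {"max_outer": 4}


def _one_gain_replicate(seed, n_subjects, k_folds, selector):
    cfg = SimulationConfig(n_subjects=n_subjects, seed=int(seed))
    cohort = simulate_cohort(cfg)
    truth_macro = cohort.subjects["macrosomia"].to_numpy()
    train_ids, test_ids = stratified_split(
        cohort, 0.7, truth_macro, seed=int(seed) + 1
    )
    masked = cohort.mask_birth_weights(test_ids)
    defs = [LearnerDef(m, f) for m in GAIN_MODELS for f in GAIN_FORMULAS]
    fits = {d.learner_id: fit_learner(masked, d) for d in defs}
    panel = build_learner_panel(masked, fits)
    panel_train = panel.subset(train_ids)
    panel_test = panel.subset(test_ids)
    subs = cohort.subjects
    y_train = subs.loc[subs["id"].isin(set(train_ids)), "macrosomia"].to_numpy()
    y_test = subs.loc[subs["id"].isin(set(test_ids)), "macrosomia"].to_numpy()

    def youden_of(labels):
        return rates(confusion(labels, y_test)).youden

    individual = {
        lid: youden_of(panel_test.macro[lid].to_numpy())
        for lid in panel.learner_ids
    }

    train_cohort = cohort.subset(train_ids)
    meta = build_leave_one_data(
        train_cohort, defs, y_train, target="macrosomia", k=k_folds,
        seed=int(seed) + 3,
        warm_starts={lid: f.warm_state for lid, f in fits.items()},
        fit_kw=_CV_FIT_KW,
    )
    cv_votes = cv_votes_from_meta(meta, "macrosomia")
    voting = fit_voting(
        panel_train, y_train, target="macrosomia", selector=selector,
        seed=int(seed) + 2, selection_votes=cv_votes,
    )
    v_labels, _ = predict_ensemble(voting, panel_test)

    stacking = fit_stacking(
        meta, target="macrosomia", selector=selector, seed=int(seed) + 4
    )
    s_labels, _ = predict_ensemble(stacking, panel_test)

    # comparator: the single learner one would pick without test labels —
    # best cross-validated training Youden
    y_tr = y_train
    cv_yd = {
        lid: rates(confusion(cv_votes[lid].to_numpy(), y_tr)).youden
        for lid in cv_votes.columns
    }
    train_best = max(cv_yd, key=cv_yd.get)
    return {
        "individual": individual,
        "train_selected_best": individual[train_best],
        "voting": youden_of(v_labels),
        "stacking": youden_of(s_labels),
    }


def ensemble_gain_study(
    n_reps=20, n_subjects=300, seed=0, k_folds=10, selector="scad"
):
    """Mean held-out Youden: SCAD-selected ensembles vs the best learner.

    The comparator is the learner with the highest *mean* held-out Youden
    across replicates (the best single choice one could have committed to
    in advance); the per-replicate maximum is also reported for context.
    """
    ss = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 10)
    voting, stacking, per_learner, per_rep_best, train_sel = [], [], [], [], []
    for r in range(n_reps):
        rep = _one_gain_replicate(int(ss[r]), n_subjects, k_folds, selector)
        voting.append(rep["voting"])
        stacking.append(rep["stacking"])
        per_learner.append(rep["individual"])
        per_rep_best.append(max(rep["individual"].values()))
        train_sel.append(rep["train_selected_best"])
        log.info(
            "gain replicate %d: voting %.3f stacking %.3f train-sel %.3f "
            "oracle %.3f",
            r, rep["voting"], rep["stacking"], train_sel[-1], per_rep_best[-1],
        )
    learner_means = pd.DataFrame(per_learner).mean(axis=0)
    return {
        "selector": selector,
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "mean_voting_youden": float(np.mean(voting)),
        "mean_stacking_youden": float(np.mean(stacking)),
        "best_individual_mean_youden": float(np.mean(train_sel)),
        "oracle_learner_mean_youden": float(learner_means.max()),
        "oracle_learner": str(learner_means.idxmax()),
        "mean_per_replicate_oracle_youden": float(np.mean(per_rep_best)),
        "learner_mean_youden": learner_means.to_dict(),
    }
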