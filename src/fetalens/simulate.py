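"""Synthetic longitudinal prenatal cohorts with SGA-study-like structure.

Subjects carry baseline covariates calibrated to the Scandinavian cohort's
published marginals, four ultrasound visits at ~17/25/33/37 gestational
weeks, a gestational age at delivery near 280 days, and a birth weight drawn
from a subject-specific three-parameter logistic growth trajectory

    w_i(t) = phi1_i / (1 + exp[-(t - phi2_i) / phi3_i])

with phi1_i = x_i' beta1 + b1_i (amplitude), phi2_i = beta2 + b2_i
(midpoint), phi3_i = beta3 + b3_i (stretch), random effects
(b1, b2, b3) ~ MVN(0, Sigma), and heteroscedastic measurement error whose
standard deviation is proportional to |w|^delta.  Visit-level biometry
(BPD/MAD/FL, mm) is produced by inverting a designated reference EFW formula
against the true weight while holding the three measures in
gestational-age-dependent reference proportions, then adding multiplicative
measurement noise — one admissible generative choice, since growth studies
publish weight trajectories rather than joint biometry trajectories.

The amplitude intercept and the amplitude random-effect variance are derived
from the configured birth-weight mean and SD by Gauss-Hermite quadrature and
a delta-method variance decomposition, so that the simulated birth-weight
distribution matches the configured moments by construction rather than by
per-run tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq

from fetalens.formulas import get_formula

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "stratified_split",
    "reference_biometry",
    "invert_reference_formula",
    "COVARIATE_COLUMNS",
]

#: Covariates entering the growth models (order is the design-matrix order).
COVARIATE_COLUMNS = [
    "maternal_age",
    "bmi",
    "smoking_level",
    "hbp",
    "cardiac",
    "diabetes",
    "renal",
    "other_disease",
]

# Typical-biometry anchors (mm) by completed gestational week, used only to
# set the BPD:MAD:FL proportions at each age; the common scale factor is
# solved from the subject's true weight.
_ANCHOR_WEEKS = np.array([15.0, 17.0, 20.0, 25.0, 30.0, 33.0, 37.0, 40.0, 43.0])
_ANCHOR_BPD = np.array([32.0, 38.0, 47.0, 62.0, 76.0, 83.0, 91.0, 95.0, 98.0])
_ANCHOR_MAD = np.array([31.0, 36.0, 46.0, 62.0, 79.0, 88.0, 99.0, 106.0, 112.0])
_ANCHOR_FL = np.array([17.0, 23.0, 31.0, 44.0, 56.0, 63.0, 70.0, 75.0, 79.0])

# Published cohort marginals used as default covariate distributions.  The
# smoking split normalizes the published percentages to sum to one
# (49.1 / 16.1 / 25.6 / 9.2).
_DEFAULT_COVARIATE_MARGINALS = {
    "maternal_age": {"dist": "normal", "mean": 28.32, "sd": 4.12},
    "height_cm": {"dist": "normal", "mean": 165.96, "sd": 5.99},
    "weight_kg": {"dist": "normal", "mean": 59.20, "sd": 10.00},
    "parity": {"dist": "choice", "values": [1, 2], "probs": [0.5, 0.5]},
    "smoking_level": {
        "dist": "choice",
        "values": [0, 1, 2, 3],
        "probs": [0.491, 0.161, 0.256, 0.092],
    },
    "hbp": {"dist": "bernoulli", "p": 0.018},
    "cardiac": {"dist": "bernoulli", "p": 0.009},
    "diabetes": {"dist": "bernoulli", "p": 0.003},
    "renal": {"dist": "bernoulli", "p": 0.010},
    "other_disease": {"dist": "bernoulli", "p": 0.154},
}

# Modest covariate effects on the amplitude (grams per unit of the centered
# covariate); the source cohort showed little covariate signal, so the
# defaults keep covariate-attributable variance small.
_DEFAULT_COVARIATE_EFFECTS = {
    "maternal_age": 3.0,
    "bmi": 20.0,
    "smoking_level": -60.0,
    "hbp": -100.0,
    "cardiac": -50.0,
    "diabetes": 300.0,
    "renal": -80.0,
    "other_disease": -30.0,
}

# Means at which covariates are centered inside the trajectory model, so the
# amplitude intercept alone controls the birth-weight location.
_COVARIATE_CENTERS = {
    "maternal_age": 28.32,
    "bmi": 21.55,
    "smoking_level": 0.949,
    "hbp": 0.018,
    "cardiac": 0.009,
    "diabetes": 0.003,
    "renal": 0.010,
    "other_disease": 0.154,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a synthetic cohort.

    ``amplitude_intercept`` and the amplitude variance in ``ranef_cov`` may
    be left as None, in which case they are derived from
    ``birthweight_mean`` / ``birthweight_sd`` (see module docstring).
    """

    n_subjects: int = 1115
    visit_weeks: tuple[float, ...] = (17.0, 25.0, 33.0, 37.0)
    visit_jitter_sd: float = 3.0  # days
    birth_ga_mean: float = 280.0  # days
    birth_ga_sd: float = 8.34  # days
    birthweight_mean: float = 3562.0  # g
    birthweight_sd: float = 478.0  # g
    amplitude_intercept: float | None = None  # g; derived if None
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    midpoint_day: float = 240.0  # beta2
    stretch_days: float = 28.0  # beta3
    ranef_sd: tuple[float | None, float, float] = (None, 4.0, 1.5)
    ranef_corr_12: float = 0.3  # corr(b1, b2)
    ranef_cov: np.ndarray | None = None  # overrides ranef_sd / corr if given
    variance_power: float = 0.5  # delta
    residual_scale: float = 2.5  # sigma, g^(1 - delta)
    biometry_noise_cv: float = 0.025  # multiplicative, per measure
    reference_formula_id: int = 1
    covariate_marginals: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in _DEFAULT_COVARIATE_MARGINALS.items()
        }
    )
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        wk = np.asarray(self.visit_weeks, dtype=float)
        if wk.size and np.any(np.diff(wk) <= 0):
            raise ValueError("visit_weeks must be strictly increasing")
        for name in ("birth_ga_sd", "birthweight_sd", "stretch_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ranef_cov is not None:
            _check_psd(np.asarray(self.ranef_cov, dtype=float))


def _check_psd(sigma: np.ndarray) -> None:
    if sigma.shape != (3, 3):
        raise ValueError("ranef_cov must be 3x3")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("ranef_cov must be symmetric")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ValueError("ranef_cov must be positive semi-definite")


@dataclass
class Cohort:
    """A longitudinal cohort: one row per subject, one row per visit.

    ``subjects`` columns: id, covariates, birth_ga (days), birth_weight (g,
    NaN when masked), macrosomia / lga truth labels, and the true trajectory
    parameters when simulated.  ``visits`` columns: id, t (days), bpd, mad,
    fl (mm).
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self):
        ids = self.subjects["id"]
        if ids.duplicated().any():
            raise ValueError("subject ids must be unique")
        if len(self.visits):
            merged = self.visits.merge(
                self.subjects[["id", "birth_ga"]], on="id", how="left"
            )
            if merged["birth_ga"].isna().any():
                raise ValueError("visit with unknown subject id")
            if (merged["t"] >= merged["birth_ga"]).any():
                raise ValueError("every visit must precede the subject's birth")
            missing = set(ids) - set(self.visits["id"])
            if missing and len(self.subjects):
                raise ValueError(f"subjects without visits: {sorted(missing)[:5]}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def covariate_matrix(self, with_intercept: bool = True) -> np.ndarray:
        X = self.subjects[COVARIATE_COLUMNS].to_numpy(dtype=float)
        if with_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def mask_birth_weights(self, ids) -> "Cohort":
        """Copy of the cohort with the given subjects' birth weights hidden."""
        subjects = self.subjects.copy()
        mask = subjects["id"].isin(list(ids))
        subjects.loc[mask, "birth_weight"] = np.nan
        return Cohort(subjects=subjects, visits=self.visits.copy())

    def subset(self, ids) -> "Cohort":
        keep = set(ids)
        return Cohort(
            subjects=self.subjects[self.subjects["id"].isin(keep)].reset_index(
                drop=True
            ),
            visits=self.visits[self.visits["id"].isin(keep)].reset_index(drop=True),
        )

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)
        self.visits.to_csv(outdir / "visits.csv", index=False)

    @classmethod
    def read_csv(cls, indir) -> "Cohort":
        indir = Path(indir)
        return cls(
            subjects=pd.read_csv(indir / "subjects.csv"),
            visits=pd.read_csv(indir / "visits.csv"),
        )


def _logistic(t, phi1, phi2, phi3):
    return phi1 / (1.0 + np.exp(-(t - phi2) / phi3))


def reference_biometry(t_days):
    """Typical (BPD, MAD, FL) in mm at gestational age ``t_days``."""
    wk = np.asarray(t_days, dtype=float) / 7.0
    return (
        np.interp(wk, _ANCHOR_WEEKS, _ANCHOR_BPD),
        np.interp(wk, _ANCHOR_WEEKS, _ANCHOR_MAD),
        np.interp(wk, _ANCHOR_WEEKS, _ANCHOR_FL),
    )


def invert_reference_formula(weight_g: float, t_days: float, formula_id: int = 1):
    """Biometry triple consistent with ``weight_g`` at age ``t_days``.

    Scales the age-typical (BPD, MAD, FL) proportions by a common factor so
    the reference EFW formula reproduces the target weight exactly.
    """
    spec = get_formula(formula_id)
    bpd, mad, fl = reference_biometry(t_days)

    def gap(log_s):
        s = 10.0**log_s
        return (
            np.log(
                spec.evaluate({"BPD": s * bpd, "MAD": s * mad, "FL": s * fl})
            )
            - np.log(weight_g)
        )

    log_s = brentq(gap, -1.0, 1.0, xtol=1e-12)
    s = 10.0**log_s
    return s * bpd, s * mad, s * fl


def _derived_dynamics(config: SimulationConfig):
    """Amplitude intercept and Sigma implied by the configured moments.

    The expected logistic attenuation E[p(T)] over the birth-age and
    midpoint/stretch random effects is computed by Gauss-Hermite quadrature;
    the amplitude random-effect SD is then solved from a delta-method
    decomposition of the birth-weight variance.  Deterministic given the
    config — no sampling is involved.
    """
    beta2, beta3 = config.midpoint_day, config.stretch_days
    sd_b2, sd_b3 = config.ranef_sd[1], config.ranef_sd[2]

    nodes, wts = hermegauss(15)
    wts = wts / wts.sum()

    def mean_p():
        total = 0.0
        for zT, wT in zip(nodes, wts):
            T = config.birth_ga_mean + config.birth_ga_sd * zT
            for z2, w2 in zip(nodes, wts):
                p2 = beta2 + sd_b2 * z2
                for z3, w3 in zip(nodes, wts):
                    p3 = max(beta3 + sd_b3 * z3, 1e-3)
                    total += wT * w2 * w3 / (1.0 + np.exp(-(T - p2) / p3))
        return total

    p_bar = mean_p()
    if config.amplitude_intercept is not None:
        intercept = config.amplitude_intercept
    else:
        intercept = config.birthweight_mean / p_bar

    if config.ranef_cov is not None:
        sigma = np.asarray(config.ranef_cov, dtype=float)
        return intercept, sigma

    # Delta-method variance budget at the mean birth age.
    T0 = config.birth_ga_mean
    p0 = 1.0 / (1.0 + np.exp(-(T0 - beta2) / beta3))
    slope = intercept * p0 * (1 - p0) / beta3  # dw/dT = -dw/dphi2
    d_phi3 = intercept * p0 * (1 - p0) * (T0 - beta2) / beta3**2
    cov_var = sum(
        (config.covariate_effects.get(k, 0.0) * _marginal_sd(config, k)) ** 2
        for k in COVARIATE_COLUMNS
    )
    resid_var = (
        config.residual_scale**2
        * config.birthweight_mean ** (2 * config.variance_power)
    )
    fixed_var = (
        (slope * config.birth_ga_sd) ** 2
        + (slope * sd_b2) ** 2
        + (d_phi3 * sd_b3) ** 2
        + p0**2 * cov_var
        + resid_var
    )
    sd_b1_cfg = config.ranef_sd[0]
    if sd_b1_cfg is None:
        # Solve p0^2 s1^2 + 2 p0 (dw/dphi2) rho sd_b2 s1 + fixed_var = bw_var
        # for the amplitude SD s1 (dw/dphi2 = -slope).
        a = p0**2
        bq = 2.0 * p0 * (-slope) * config.ranef_corr_12 * sd_b2
        cq = fixed_var - config.birthweight_sd**2
        disc = bq**2 - 4 * a * cq
        sd_b1 = max((-bq + np.sqrt(max(disc, 0.0))) / (2 * a), 0.0)
    else:
        sd_b1 = sd_b1_cfg
    sigma = np.diag([sd_b1**2, sd_b2**2, sd_b3**2]).astype(float)
    sigma[0, 1] = sigma[1, 0] = config.ranef_corr_12 * sd_b1 * sd_b2
    _check_psd(sigma)
    return intercept, sigma


def _marginal_sd(config: SimulationConfig, name: str) -> float:
    m = config.covariate_marginals.get(name)
    if name == "bmi":
        # BMI is derived from weight and height; its SD under the default
        # marginals is close to weight_sd / mean_height_m^2.
        hw = config.covariate_marginals.get("weight_kg", {"sd": 10.0})
        hh = config.covariate_marginals.get("height_cm", {"mean": 165.96})
        return hw["sd"] / (hh["mean"] / 100.0) ** 2
    if m is None:
        return 0.0
    if m["dist"] == "normal":
        return m["sd"]
    if m["dist"] == "bernoulli":
        return float(np.sqrt(m["p"] * (1 - m["p"])))
    if m["dist"] == "choice":
        v = np.asarray(m["values"], float)
        p = np.asarray(m["probs"], float)
        p = p / p.sum()
        mu = (v * p).sum()
        return float(np.sqrt(((v - mu) ** 2 * p).sum()))
    raise ValueError(f"unknown marginal distribution {m['dist']!r}")


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator, n: int):
    cols = {}
    for name, m in config.covariate_marginals.items():
        if m["dist"] == "normal":
            cols[name] = rng.normal(m["mean"], m["sd"], size=n)
        elif m["dist"] == "bernoulli":
            cols[name] = (rng.random(n) < m["p"]).astype(int)
        elif m["dist"] == "choice":
            p = np.asarray(m["probs"], float)
            cols[name] = rng.choice(np.asarray(m["values"]), size=n, p=p / p.sum())
        else:
            raise ValueError(f"unknown marginal distribution {m['dist']!r}")
    df = pd.DataFrame(cols)
    if "height_cm" in df and "weight_kg" in df:
        df["height_cm"] = df["height_cm"].clip(lower=140.0)
        df["weight_kg"] = df["weight_kg"].clip(lower=35.0)
        df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    return df


def _sample_ranef(rng: np.random.Generator, sigma: np.ndarray, n: int):
    eigval, eigvec = np.linalg.eigh(sigma)
    eigval = np.clip(eigval, 0.0, None)
    A = eigvec * np.sqrt(eigval)
    return rng.standard_normal((n, 3)) @ A.T


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> Cohort:
    """Draw a full synthetic cohort under ``config``.

    Returns a :class:`Cohort` whose subjects table carries the true
    trajectory parameters (``true_phi1/2/3``) alongside the observables, so
    downstream recovery and classification tests can compare against truth.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    intercept, sigma = _derived_dynamics(config)

    subjects = _draw_covariates(config, rng, n)
    subjects.insert(0, "id", np.arange(1, n + 1))

    xe = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        if name in subjects:
            xe += eff * (
                subjects[name].to_numpy(dtype=float) - _COVARIATE_CENTERS.get(name, 0.0)
            )

    b = _sample_ranef(rng, sigma, n)
    phi1 = intercept + xe + b[:, 0]
    phi2 = config.midpoint_day + b[:, 1]
    phi3 = np.maximum(config.stretch_days + b[:, 2], 1e-2)

    visit_days = np.asarray(config.visit_weeks, dtype=float) * 7.0
    last_visit = visit_days.max() if visit_days.size else 0.0

    t_visits = np.empty((n, visit_days.size))
    birth_ga = np.empty(n)
    for i in range(n):
        for _attempt in range(200):
            tv = np.sort(visit_days + rng.normal(0.0, config.visit_jitter_sd,
                                                 size=visit_days.size))
            ga = rng.normal(config.birth_ga_mean, config.birth_ga_sd)
            if visit_days.size == 0 or ga > tv.max() + 1.0:
                break
        else:
            raise RuntimeError(
                "could not draw a birth age beyond the last visit; "
                "check visit_weeks against birth_ga_mean/sd"
            )
        t_visits[i] = tv
        birth_ga[i] = ga

    w_birth_true = _logistic(birth_ga, phi1, phi2, phi3)
    noise_sd = config.residual_scale * np.abs(w_birth_true) ** config.variance_power
    birth_weight = w_birth_true + rng.normal(0.0, 1.0, size=n) * noise_sd

    subjects["birth_ga"] = birth_ga
    subjects["birth_weight"] = birth_weight
    subjects["true_phi1"] = phi1
    subjects["true_phi2"] = phi2
    subjects["true_phi3"] = phi3
    subjects["macrosomia"] = (birth_weight > 4000.0).astype(int)
    subjects["lga"] = _true_lga(birth_ga, phi1, phi2, phi3)

    rows = []
    for i in range(n):
        for t in t_visits[i]:
            w_t = float(_logistic(t, phi1[i], phi2[i], phi3[i]))
            bpd, mad, fl = invert_reference_formula(
                w_t, t, config.reference_formula_id
            )
            if config.biometry_noise_cv > 0:
                noise = np.exp(
                    rng.normal(0.0, config.biometry_noise_cv, size=3)
                )
            else:
                noise = np.ones(3)
            rows.append(
                (subjects["id"].iloc[i], t, bpd * noise[0], mad * noise[1],
                 fl * noise[2])
            )
    visits = pd.DataFrame(rows, columns=["id", "t", "bpd", "mad", "fl"])
    if n == 0:
        visits = pd.DataFrame(columns=["id", "t", "bpd", "mad", "fl"])
    return Cohort(subjects=subjects, visits=visits)


def _true_lga(birth_ga, phi1, phi2, phi3) -> np.ndarray:
    """LGA truth by the counterfactual percentile rule on true trajectories.

    Subject i is LGA when their true weight at their own birth age exceeds
    the 90th percentile of all other subjects' true weights evaluated at that
    same age.
    """
    n = len(birth_ga)
    out = np.zeros(n, dtype=int)
    if n < 2:
        return out
    for i in range(n):
        w_all = _logistic(birth_ga[i], phi1, phi2, phi3)
        others = np.delete(w_all, i)
        q90 = np.quantile(others, 0.9)  # linear-interpolation sample quantile
        out[i] = int(w_all[i] > q90)
    return out


def stratified_split(cohort_or_ids, train_frac: float, label, seed: int | None = None):
    """Label-stratified train/test partition of subject ids.

    The total training size is round-half-up of ``train_frac × n``; the
    per-stratum sizes are reconciled to that total by largest remainder.
    Returns ``(train_ids, test_ids)`` as numpy arrays.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    if isinstance(cohort_or_ids, Cohort):
        ids = cohort_or_ids.subjects["id"].to_numpy()
    else:
        ids = np.asarray(cohort_or_ids)
    label = np.asarray(label)
    if label.shape[0] != ids.shape[0]:
        raise ValueError("label must be defined for every subject")
    n = len(ids)
    rng = np.random.default_rng(seed)

    strata: dict = {}
    for lv in pd.unique(label):
        strata[lv] = ids[label == lv]

    small = {lv: g for lv, g in strata.items() if len(g) < 2}
    large = {lv: g for lv, g in strata.items() if len(g) >= 2}
    if small:
        warnings.warn(
            f"strata with fewer than 2 members assigned wholly to train: "
            f"{sorted(map(str, small))}"
        )

    n_large = sum(len(g) for g in large.values())
    target = int(np.floor(train_frac * n + 0.5)) - sum(len(g) for g in small.values())
    target = max(0, min(target, n_large))

    quotas = {lv: train_frac * len(g) for lv, g in large.items()}
    base = {lv: int(np.floor(q)) for lv, q in quotas.items()}
    rem = target - sum(base.values())
    order = sorted(
        large,
        key=lambda lv: (quotas[lv] - base[lv], len(large[lv])),
        reverse=True,
    )
    if rem > 0:
        for lv in order[:rem]:
            base[lv] += 1
    while rem < 0:
        for lv in reversed(order):
            if base[lv] > 0 and rem < 0:
                base[lv] -= 1
                rem += 1

    train, test = [], []
    for lv, g in large.items():
        perm = rng.permutation(g)
        k = min(base[lv], len(g))
        train.append(perm[:k])
        test.append(perm[k:])
    for g in small.values():
        train.append(np.asarray(g))
    train = np.concatenate(train) if train else np.array([], dtype=ids.dtype)
    test = np.concatenate(test) if test else np.array([], dtype=ids.dtype)
    return np.sort(train), np.sort(test)
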