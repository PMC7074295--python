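"""Diagnostic-accuracy metrics with confidence intervals.

Point estimates follow the standard 2x2 definitions: sensitivity
tp/(tp+fn), specificity tn/(tn+fp), predictive values, likelihood ratios
+LR = sens/(1-spec) and -LR = (1-sens)/spec, and Youden's index
J = sensitivity + specificity - 1.  AUC is the Mann-Whitney probability
with ties counted half.

Interval methods (the common defaults, stated explicitly since different
software disagrees): Clopper-Pearson exact binomial intervals for the four
proportions, the log-transform normal interval for likelihood ratios, and
DeLong's covariance estimator for the AUC.  Undefined ratios (zero
denominators) are reported as NaN with a flag rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "rates",
    "metric_cis",
    "roc_auc",
    "evaluate_classifier",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Point estimates, 95% CIs and undefined-value flags."""

    sensitivity: float = np.nan
    specificity: float = np.nan
    ppv: float = np.nan
    npv: float = np.nan
    plr: float = np.nan
    nlr: float = np.nan
    youden: float = np.nan
    auc: float = np.nan
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "auc", "sensitivity", "specificity", "plr", "nlr",
                "ppv", "npv", "youden",
            )
        }
        for k, (lo, hi) in self.ci.items():
            out[f"{k}_lo"], out[f"{k}_hi"] = lo, hi
        out["flags"] = ";".join(self.flags)
        return out


def confusion(labels, truth) -> ConfusionCounts:
    """Exact 2x2 counts of predicted labels against truth."""
    labels = np.asarray(labels).astype(int)
    truth = np.asarray(truth).astype(int)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    if labels.size == 0:
        raise ValueError("empty inputs")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (truth == 1))),
        fp=int(np.sum((labels == 1) & (truth == 0))),
        tn=int(np.sum((labels == 0) & (truth == 0))),
        fn=int(np.sum((labels == 0) & (truth == 1))),
    )


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def rates(c: ConfusionCounts) -> MetricsReport:
    """Point estimates from a confusion table; zero denominators flag NaN."""
    rep = MetricsReport()
    rep.sensitivity = _ratio(c.tp, c.tp + c.fn)
    rep.specificity = _ratio(c.tn, c.tn + c.fp)
    rep.ppv = _ratio(c.tp, c.tp + c.fp)
    rep.npv = _ratio(c.tn, c.tn + c.fn)
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        if np.isnan(getattr(rep, name)):
            rep.flags.append(f"{name}_undefined")
    if not np.isnan(rep.sensitivity) and not np.isnan(rep.specificity):
        rep.youden = rep.sensitivity + rep.specificity - 1.0
        if rep.specificity < 1.0:
            rep.plr = rep.sensitivity / (1.0 - rep.specificity)
        else:
            rep.flags.append("plr_undefined")
        if rep.specificity > 0.0:
            rep.nlr = (1.0 - rep.sensitivity) / rep.specificity
        else:
            rep.flags.append("nlr_undefined")
    return rep


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    if n == 0:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def _lr_ci(c: ConfusionCounts, which: str, level: float = 0.95):
    # log-method interval (Simel et al.)
    z = norm.ppf(0.5 + level / 2)
    if which == "plr":
        num, nden = c.tp, c.tp + c.fn
        dnum, dden = c.fp, c.fp + c.tn
    else:
        num, nden = c.fn, c.tp + c.fn
        dnum, dden = c.tn, c.fp + c.tn
    if min(nden, dden) == 0 or num == 0 or dnum == 0:
        return (np.nan, np.nan)
    lr = (num / nden) / (dnum / dden)
    se = np.sqrt(1 / num - 1 / nden + 1 / dnum - 1 / dden)
    return (float(lr * np.exp(-z * se)), float(lr * np.exp(z * se)))


def metric_cis(c: ConfusionCounts, level: float = 0.95) -> dict:
    """95% intervals: exact binomial for proportions, log-method for LRs."""
    return {
        "sensitivity": _clopper_pearson(c.tp, c.tp + c.fn, level),
        "specificity": _clopper_pearson(c.tn, c.tn + c.fp, level),
        "ppv": _clopper_pearson(c.tp, c.tp + c.fp, level),
        "npv": _clopper_pearson(c.tn, c.tn + c.fn, level),
        "plr": _lr_ci(c, "plr", level),
        "nlr": _lr_ci(c, "nlr", level),
    }


def roc_auc(scores, truth, level: float = 0.95):
    """AUC as the tie-adjusted Mann-Whitney probability, with DeLong CI.

    Returns ``(auc, (lo, hi))``.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes in truth")
    all_r = rankdata(np.concatenate([pos, neg]))
    r_pos = all_r[:m]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    pos_r = rankdata(pos)
    neg_r = rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n  # P(neg < pos_i) with ties half
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def evaluate_classifier(labels, scores, truth) -> MetricsReport:
    """Full report for one classifier: rates, CIs and (if possible) AUC."""
    c = confusion(labels, truth)
    rep = rates(c)
    rep.ci = metric_cis(c)
    truth_arr = np.asarray(truth).astype(int)
    if scores is not None and 0 < truth_arr.sum() < truth_arr.size:
        rep.auc, rep.ci["auc"] = roc_auc(scores, truth)
    else:
        rep.flags.append("auc_undefined")
    return rep
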