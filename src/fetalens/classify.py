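"""Binary classification of large fetuses from predicted birth weights.

Two outcomes are derived from each growth model's subject-specific
predictions (PBWs):

* **macrosomia** — predicted birth weight strictly greater than 4000 g,
  irrespective of gestational age;
* **LGA (large for gestational age)** — the subject's PBW at their own
  delivery time strictly exceeds the 90th percentile of all *other*
  subjects' PBWs evaluated at that same counterfactual delivery time.

A "learner" is one growth-model variant (logistic / quadratic, with or
without maternal covariates) combined with one EFW formula; the full bank
yields 4 x 26 = 104 learners, each contributing one PBW column and the two
derived binary columns to the :class:`LearnerPanel`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from fetalens.formulas import efw_records
from fetalens.growth import GrowthFit, fit_logistic_nlme, fit_quadratic_lme
from fetalens.simulate import Cohort

__all__ = [
    "MACROSOMIA_THRESHOLD_G",
    "LGA_QUANTILE",
    "LearnerDef",
    "LearnerPanel",
    "classify_macrosomia",
    "classify_lga",
    "build_learner_panel",
    "default_learner_defs",
    "fit_learner",
]

log = logging.getLogger(__name__)

MACROSOMIA_THRESHOLD_G = 4000.0
LGA_QUANTILE = 0.9

MODEL_VARIANTS = (
    ("nlme", False),
    ("nlme_cov", True),
    ("qlme", False),
    ("qlme_cov", True),
)


def classify_macrosomia(pbw, threshold: float = MACROSOMIA_THRESHOLD_G):
    """1 iff the predicted birth weight strictly exceeds the threshold."""
    pbw = np.asarray(pbw, dtype=float)
    if not np.all(np.isfinite(pbw)):
        raise ValueError("predicted birth weights must be finite")
    out = (pbw > threshold).astype(int)
    return int(out) if out.ndim == 0 else out


def classify_lga(
    pbw_at_time: Callable,
    subjects: pd.DataFrame,
    index,
    q: float = LGA_QUANTILE,
):
    """LGA call for one subject by the counterfactual percentile rule.

    ``pbw_at_time(subject_id, t_days)`` must return the model's prediction
    for any subject at any time.  Subject ``index`` is positive when their
    own prediction at their delivery time strictly exceeds the linearly
    interpolated ``q``-quantile of all other subjects' predictions at that
    identical time.
    """
    ids = subjects["id"].to_numpy()
    t_i = float(subjects.loc[subjects["id"] == index, "birth_ga"].iloc[0])
    vals = np.array([pbw_at_time(j, t_i) for j in ids], dtype=float)
    own = vals[ids == index][0]
    others = vals[ids != index]
    if others.size < 10:
        warnings.warn(
            f"LGA reference set has only {others.size} subjects; "
            "percentile is unstable"
        )
    return int(own > np.quantile(others, q))


def _lga_column(pred_matrix: np.ndarray, q: float = LGA_QUANTILE):
    """LGA calls and margins from an (n, n) prediction matrix.

    ``pred_matrix[j, i]`` is subject j's PBW at subject i's delivery time;
    column i is the counterfactual population born at time T_i.  The margin
    (own PBW minus the reference percentile) provides a graded score for
    ROC analysis of the binary rule.
    """
    n = pred_matrix.shape[0]
    out = np.zeros(n, dtype=int)
    margin = np.zeros(n)
    for i in range(n):
        col = pred_matrix[:, i]
        others = np.delete(col, i)
        q90 = np.quantile(others, q)
        out[i] = int(col[i] > q90)
        margin[i] = col[i] - q90
    return out, margin


@dataclass(frozen=True)
class LearnerDef:
    """One first-level learner: a model variant paired with an EFW formula."""

    model: str  # "nlme", "nlme_cov", "qlme" or "qlme_cov"
    formula_id: int

    @property
    def with_covariates(self) -> bool:
        return self.model.endswith("_cov")

    @property
    def learner_id(self) -> str:
        return f"{self.model}_f{self.formula_id:02d}"


def default_learner_defs(
    models=("nlme", "nlme_cov", "qlme", "qlme_cov"),
    formula_ids=range(1, 27),
) -> list[LearnerDef]:
    """The full grid of model variants x formulas (104 learners by default)."""
    return [LearnerDef(m, f) for m in models for f in formula_ids]


def fit_learner(
    cohort: Cohort,
    d: LearnerDef,
    efw: pd.DataFrame | None = None,
    warm_start: dict | None = None,
    **fit_kw,
) -> GrowthFit:
    """Fit one learner's growth model on the cohort's unmasked responses."""
    if efw is None:
        efw = efw_records(cohort.visits, d.formula_id)
    if d.model.startswith("nlme"):
        return fit_logistic_nlme(
            cohort, efw, with_covariates=d.with_covariates,
            warm_start=warm_start, **fit_kw,
        )
    return fit_quadratic_lme(
        cohort, efw, with_covariates=d.with_covariates,
        warm_start=warm_start, **fit_kw,
    )


@dataclass
class LearnerPanel:
    """Subjects x learners matrices of PBWs and binary classifications."""

    subject_ids: np.ndarray
    pbw: pd.DataFrame  # one column per learner id, grams
    macro: pd.DataFrame  # binary
    lga: pd.DataFrame  # binary
    lga_margin: pd.DataFrame  # PBW minus the reference 90th percentile, grams
    failed: list

    @property
    def learner_ids(self) -> list:
        return list(self.pbw.columns)

    def subset(self, ids) -> "LearnerPanel":
        keep = np.isin(self.subject_ids, np.asarray(list(ids)))
        return LearnerPanel(
            subject_ids=self.subject_ids[keep],
            pbw=self.pbw.loc[keep].reset_index(drop=True),
            macro=self.macro.loc[keep].reset_index(drop=True),
            lga=self.lga.loc[keep].reset_index(drop=True),
            lga_margin=self.lga_margin.loc[keep].reset_index(drop=True),
            failed=list(self.failed),
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.subject_ids})
        for lid in self.learner_ids:
            out[f"pbw_{lid}"] = self.pbw[lid].to_numpy()
            out[f"macro_{lid}"] = self.macro[lid].to_numpy()
            out[f"lga_{lid}"] = self.lga[lid].to_numpy()
        return out


def build_learner_panel(
    cohort: Cohort,
    fits: Mapping[str, GrowthFit],
    macro_threshold: float = MACROSOMIA_THRESHOLD_G,
    lga_quantile: float = LGA_QUANTILE,
) -> LearnerPanel:
    """Assemble the panel of per-learner PBWs and classifications.

    For each learner the PBW is the model prediction at the subject's own
    delivery time; macrosomia thresholds that PBW and LGA applies the
    counterfactual percentile rule across the panel's subjects.  Learners
    whose fit failed (None) are recorded in ``failed`` and excluded.
    """
    subs = cohort.subjects
    ids = subs["id"].to_numpy()
    birth_ga = subs["birth_ga"].to_numpy(dtype=float)
    pbw_cols, macro_cols, lga_cols, margin_cols, failed = {}, {}, {}, {}, []
    for lid, fit in fits.items():
        if fit is None:
            failed.append(lid)
            log.warning("learner %s flagged missing; excluded from the panel", lid)
            continue
        # full prediction matrix: every subject at every birth time
        pred = fit.predict_grid(ids, birth_ga)
        own = np.diagonal(pred).copy()
        pbw_cols[lid] = own
        macro_cols[lid] = classify_macrosomia(own, macro_threshold)
        lga_cols[lid], margin_cols[lid] = _lga_column(pred, lga_quantile)
    return LearnerPanel(
        subject_ids=ids,
        pbw=pd.DataFrame(pbw_cols),
        macro=pd.DataFrame(macro_cols),
        lga=pd.DataFrame(lga_cols),
        lga_margin=pd.DataFrame(margin_cols),
        failed=failed,
    )
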