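"""End-to-end orchestration: simulate -> EFW -> fit -> classify -> ensemble -> evaluate.

The pipeline reproduces the four-step study protocol on a cohort (simulated
or loaded from CSV):

1. estimated fetal weights from every configured EFW formula;
2. one mixed-effects growth model per learner, fitted jointly on the
   training subjects' full records plus the test subjects' ultrasound rows
   with test birth weights masked — test labels are never visible to any
   fitting step;
3. per-learner macrosomia and LGA classifications at each subject's own
   delivery time;
4. voting and stacking ensembles with optional LASSO/SCAD/MCP selection,
   trained on the training subset and evaluated on the held-out test
   subset.

Outputs are flat CSV/JSON tables shaped like per-learner and per-ensemble
metric reports, with the seed and configuration echoed alongside.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fetalens.classify import (
    LearnerDef,
    LearnerPanel,
    build_learner_panel,
    default_learner_defs,
    fit_learner,
)
from fetalens.ensemble import (
    EnsembleModel,
    build_leave_one_data,
    cv_votes_from_meta,
    fit_stacking,
    fit_voting,
    predict_ensemble,
)
from fetalens.metrics import evaluate_classifier
from fetalens.simulate import Cohort, SimulationConfig, simulate_cohort, stratified_split

__all__ = ["PipelineConfig", "PipelineResult", "run_full_pipeline", "evaluate_all"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one full run (defaults mirror the full study layout)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    formula_ids: tuple = tuple(range(1, 27))
    model_variants: tuple = ("nlme", "nlme_cov", "qlme", "qlme_cov")
    train_frac: float = 0.7
    cv_folds: int = 10
    ensemble_selectors: tuple = ("none", "lasso", "scad", "mcp")
    run_voting: bool = True
    run_stacking: bool = True
    targets: tuple = ("macrosomia", "lga")
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        from fetalens.formulas import list_formulas

        known = {s.id for s in list_formulas()}
        bad = set(self.formula_ids) - known
        if bad:
            raise ValueError(f"unknown formula ids: {sorted(bad)}")


@dataclass
class PipelineResult:
    cohort: Cohort
    train_ids: np.ndarray
    test_ids: np.ndarray
    panel: LearnerPanel
    learner_metrics: pd.DataFrame
    ensemble_metrics: pd.DataFrame
    ensembles: dict
    config: PipelineConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.learner_metrics.to_csv(outdir / "learner_metrics.csv", index=False)
        self.ensemble_metrics.to_csv(outdir / "ensemble_metrics.csv", index=False)
        self.panel.to_frame().to_csv(outdir / "panel.csv", index=False)
        models = {name: m.to_dict() for name, m in self.ensembles.items()}
        cfg = asdict(replace(self.config, simulation=None))
        cfg["simulation"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.config.simulation).items()
            if k != "covariate_marginals"
        }
        (outdir / "ensembles.json").write_text(
            json.dumps({"models": models, "config": cfg}, indent=2, default=str)
        )


def _truth_labels(cohort: Cohort) -> pd.DataFrame:
    """Per-subject outcome truth; derives missing columns from birth weight."""
    subs = cohort.subjects
    out = pd.DataFrame({"id": subs["id"].to_numpy()})
    if "macrosomia" in subs:
        out["macrosomia"] = subs["macrosomia"].to_numpy(dtype=int)
    else:
        out["macrosomia"] = (subs["birth_weight"] > 4000.0).astype(int).to_numpy()
    if "lga" in subs:
        out["lga"] = subs["lga"].to_numpy(dtype=int)
    else:
        # empirical percentile-for-gestational-age on observed birth weights
        # (±7-day window around each subject's delivery age)
        ga = subs["birth_ga"].to_numpy(dtype=float)
        bw = subs["birth_weight"].to_numpy(dtype=float)
        lga = np.zeros(len(ga), dtype=int)
        for i in range(len(ga)):
            win = np.abs(ga - ga[i]) <= 7.0
            win[i] = False
            ref = bw[win] if win.sum() >= 10 else np.delete(bw, i)
            lga[i] = int(bw[i] > np.quantile(ref, 0.9))
        out["lga"] = lga
    return out


def run_full_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Execute all stages; see the module docstring for the protocol."""
    t_start = time.time()
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    if cohort is None:
        sim = replace(config.simulation, seed=int(rng_seeds[0]))
        cohort = simulate_cohort(sim)
        log.info("simulated cohort of %d subjects", cohort.n_subjects)

    truth = _truth_labels(cohort)
    # composite stratum keeps both outcome prevalences balanced in the split
    composite = truth["macrosomia"].to_numpy() * 2 + truth["lga"].to_numpy()
    train_ids, test_ids = stratified_split(
        cohort, config.train_frac, composite, seed=int(rng_seeds[1])
    )
    log.info("split: %d train / %d test", len(train_ids), len(test_ids))

    masked = cohort.mask_birth_weights(test_ids)
    defs = [
        LearnerDef(m, f)
        for m in config.model_variants
        for f in config.formula_ids
    ]
    fits = {}
    for d in defs:
        t0 = time.time()
        try:
            fits[d.learner_id] = fit_learner(masked, d)
            log.info(
                "fitted %s in %.1fs (converged=%s)",
                d.learner_id, time.time() - t0,
                fits[d.learner_id].converged,
            )
        except Exception as exc:  # noqa: BLE001 - one bad learner must not kill the run
            log.warning("learner %s failed: %s", d.learner_id, exc)
            fits[d.learner_id] = None

    panel = build_learner_panel(masked, fits)
    panel_train = panel.subset(train_ids)
    panel_test = panel.subset(test_ids)
    truth_train = truth[truth["id"].isin(set(train_ids))].reset_index(drop=True)
    truth_test = truth[truth["id"].isin(set(test_ids))].reset_index(drop=True)

    train_cohort = cohort.subset(train_ids)
    ensembles: dict[str, EnsembleModel] = {}
    for target in config.targets:
        y_train = truth_train[target].to_numpy()
        needs_cv = config.run_stacking or (
            config.run_voting
            and any(s != "none" for s in config.ensemble_selectors)
        )
        meta = None
        if needs_cv:
            meta = build_leave_one_data(
                train_cohort,
                [d for d in defs if fits[d.learner_id] is not None],
                y_train,
                target=target,
                k=config.cv_folds,
                seed=int(rng_seeds[3]),
                warm_starts={
                    lid: getattr(f, "warm_state", None)
                    for lid, f in fits.items()
                    if f is not None
                },
                fit_kw={"max_outer": 8},
            )
        cv_votes = cv_votes_from_meta(meta, target) if meta is not None else None
        if config.run_voting:
            for sel in config.ensemble_selectors:
                name = f"voting_{sel}_{target}"
                ensembles[name] = fit_voting(
                    panel_train, y_train, target=target, selector=sel,
                    seed=int(rng_seeds[2]), selection_votes=cv_votes,
                )
        if config.run_stacking:
            for sel in config.ensemble_selectors:
                name = f"stacking_{sel}_{target}"
                ensembles[name] = fit_stacking(
                    meta, target=target, selector=sel, seed=int(rng_seeds[2])
                )

    learner_metrics, ensemble_metrics = evaluate_all(
        panel_test, truth_test, ensembles, targets=config.targets
    )
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    result = PipelineResult(
        cohort=cohort,
        train_ids=train_ids,
        test_ids=test_ids,
        panel=panel,
        learner_metrics=learner_metrics,
        ensemble_metrics=ensemble_metrics,
        ensembles=ensembles,
        config=config,
    )
    if config.outdir:
        result.write(config.outdir)
    return result


def evaluate_all(
    panel_test: LearnerPanel,
    truth: pd.DataFrame,
    ensembles: dict | None = None,
    targets: tuple = ("macrosomia", "lga"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-learner and per-ensemble metric tables on the test subset.

    Test-set outcome labels are read here and nowhere else in the pipeline.
    Scores: PBW for macrosomia, the percentile margin for LGA, vote
    fractions / meta outputs for ensembles.  A single-class truth flags the
    AUC instead of failing.
    """
    order = {sid: i for i, sid in enumerate(panel_test.subject_ids)}
    truth = truth.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)
    if not np.array_equal(truth["id"].to_numpy(), panel_test.subject_ids):
        raise ValueError("truth table must cover exactly the panel's subjects")

    rows = []
    for lid in panel_test.learner_ids:
        for target, labels, scores in (
            ("macrosomia", panel_test.macro[lid], panel_test.pbw[lid]),
            ("lga", panel_test.lga[lid], panel_test.lga_margin[lid]),
        ):
            if target not in targets:
                continue
            y = truth[target].to_numpy()
            scr = scores.to_numpy() if 0 < y.sum() < len(y) else None
            rep = evaluate_classifier(labels.to_numpy(), scr, y)
            rows.append({"learner": lid, "target": target, **rep.to_dict()})
    learner_metrics = pd.DataFrame(rows)

    erows = []
    for name, model in (ensembles or {}).items():
        labels, scores = predict_ensemble(model, panel_test)
        y = truth[model.target].to_numpy()
        scr = scores if 0 < y.sum() < len(y) else None
        rep = evaluate_classifier(labels, scr, y)
        erows.append(
            {
                "ensemble": name,
                "method": model.method,
                "selector": model.selector,
                "target": model.target,
                "n_selected": len(model.selected_learners),
                **rep.to_dict(),
            }
        )
    ensemble_metrics = pd.DataFrame(erows)
    return learner_metrics, ensemble_metrics
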