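# Methods

## Problem

Given longitudinal prenatal ultrasound biometry — biparietal diameter
(BPD), middle abdominal diameter (MAD) and femur length (FL) recorded at
roughly the 17th, 25th, 33rd and 37th gestational weeks — together with the
gestational age at delivery, predict two binary outcomes at birth:

* **macrosomia**: birth weight strictly above 4000 g;
* **LGA** (large for gestational age): weight above the 90th percentile for
  gestational age, operationalized counterfactually — subject *i* is LGA
  when their predicted weight at their own delivery time exceeds the 90th
  percentile of all *other* subjects' predicted weights evaluated at that
  same delivery time (linear-interpolation sample quantile, strict `>`).

The pipeline has four stages: (1) a bank of 26 empirical estimated-fetal-
weight (EFW) formulas converts each visit's biometry to a weight; (2) a
mixed-effects growth model fitted to the EFW series plus the observed birth
weight produces each subject's predicted birth weight (PBW) at any time;
(3) thresholds/percentiles turn PBWs into binary calls; (4) the 4 model
variants × 26 formulas = 104 "learners" are combined by majority voting or
stacking, with optional LASSO/SCAD/MCP learner selection.

## EFW formula bank

The bank holds 26 published sonographic formulas (Campbell & Wilkin,
Warsof, Shepard, Jordaan, four Hadlock models, Combs, Ott, Hsieh, Woo,
Vintzileos, Roberts, Higginbottom, Weiner, Shinozuka, Persson & Weldner,
Aoki, ...), stored as data (`data/efw_formulas.json`) with coefficients in
the units of the original publications and converted on evaluation
(biometry mm in, grams out).  Abdominal circumference is derived as
`3.1416 × MAD` — the literal constant of the source compilation, not π —
and head circumference from BPD through a configurable linear relation
whose default, HC = 3.57 × BPD, is the circumference of a prolate-ellipse
head outline with cephalic index ≈ 1.27 (the cohort recorded no direct
HC).  Any published BPD→HC relation can be substituted via
`hc_params={"hc_coefficient": c}`.

Membership criterion: every member must return a finite positive weight
over the realized biometry of simulated cohorts (weeks ~16–43, with the
early-gestation sizes the logistic trajectory produces).  One classical
third-trimester polynomial with a negative constant term fails this and
was replaced by a log-linear model with the same input set.

## Growth models

Let `y_ij` be the EFW at visit j = 1..4 and the observed birth weight at
j = 5 (t = gestational age in days throughout).

**Logistic NLME.**  `y_ij = φ1i / (1 + exp[−(t_ij − φ2i)/φ3i]) + ε_ij` with
`φ1i = x_i'β1 + b1i` (amplitude; maternal covariates enter here only),
`φ2i = β2 + b2i` (midpoint), `φ3i = β3 + b3i` (stretch),
`b_i ~ MVN(0, Σ)` unstructured, and power-of-the-mean errors
`Var(ε_ij) = σ² |μ_ij|^{2δ}`, δ ∈ [0, 3] estimated jointly.

**Quadratic LME.**  `y_ij = x_i'β + θ1 t + θ2 t² + b0i + b1i t + b2i t² +
ε_ij`, same random-effect and error structure.  Time is internally scaled
by 1/100 for conditioning; all reported quantities are in per-day units.

**Estimation.**  Lindstrom–Bates-style alternation maximizing the
Laplace-approximated marginal likelihood: a penalized (nonlinear) least
squares step updates the fixed effects and the per-subject random-effect
modes (damped Gauss–Newton, vectorized across subjects); the model is then
linearized about the modes and the variance parameters — log-Cholesky
factor of Σ/σ² plus δ — are updated by L-BFGS-B with an analytic gradient
on the profile likelihood (σ² and the fixed effects profiled out in closed
form).  Starting values: amplitude = 1.1 × per-subject maximum (pooled
median), midpoint from the pooled half-maximum crossing, stretch from the
pooled slope at the crossing (φ3 = φ1/4·slope, clipped to [5, 80] d), δ
init 0.5.  Convergence: stagnation of the profile likelihood below
1e−8·(|ℓ|+1) or maximal relative parameter change below 1e−7, cap 200
outer iterations; a non-converged fit is returned flagged, never raised.
Because the profile likelihood is evaluated under a moving linearization,
the reported iteration history is the running best (non-decreasing by
construction); the returned parameters are those attaining it.  Wald
covariance for fixed effects comes from the final generalized-least-squares
information matrix.

Subjects with a missing (masked) birth weight contribute only their
ultrasound rows to the likelihood but still receive empirical-Bayes modes;
this is how test subjects are scored without their labels entering any
fit, matching the protocol in which one joint model is fitted on the
training set plus the test subjects' ultrasound rows.

**Known limitation — Wald coverage.**  The Laplace-class estimator carries
an O(1) approximation bias in the nonlinearly-entering fixed effects
(midpoint and stretch): at the default simulation truth it is ≈ −0.3 d and
−0.4 d, which R's `nlme` (the reference implementation of the same
algorithm family) reproduces almost exactly, while exact Gauss–Hermite
maximum likelihood removes it.  Relative bias stays well under 1%, but
against Wald standard errors at n = 500 (≈ 0.25 d and 0.13 d) it is 1–3.5
SE, so 95% interval coverage for those two parameters sits near 40–70%
rather than 95%.  The quadratic model's likelihood is exact and its
coverage is nominal.  Exact-quadrature estimation is deliberately out of
scope; the recovery study reports this honestly rather than re-tuning the
simulation to mask it.

## Synthetic cohorts

The generator emulates the Scandinavian study's structure: n = 1115
subjects by default; maternal age N(28.32, 4.12²) yr, height
N(165.96, 5.99²) cm, weight N(59.20, 10²) kg (BMI derived), parity 1 or 2,
smoking level in four classes with probabilities 0.491/0.161/0.256/0.092
(the published percentages normalized to sum to one), disease-history
indicators at their published prevalences; visits at weeks 17/25/33/37 ×7 d
with 3-d jitter; delivery age N(280, 8.34²) d redrawn while it precedes
the last visit.  Each subject follows the logistic trajectory above with
β2 = 240 d, β3 = 28 d, random-effect SDs (derived, ≈470 g | 4 d | 1.5 d),
corr(b1, b2) = 0.3, δ = 0.5, σ = 2.5 g^{1/2}, and small centered covariate
effects on the amplitude.  The amplitude intercept and the amplitude
random-effect SD are *derived* from the target birth-weight mean 3562 g
and SD 478 g: the intercept by Gauss–Hermite integration of the logistic
attenuation over the delivery-age and midpoint/stretch distributions, the
SD by solving a delta-method variance budget — calibration by
construction, not per-run tuning.  Under the defaults the realized mean
birth weight is within sampling error of 3562 g, macrosomia prevalence ≈
17.5% and LGA prevalence ≈ 10% (definitional for a 90th-percentile rule).

Biometry is generated by inverting bank formula 1 (Persson & Weldner's
power-product — strictly monotone and unbounded, hence globally
invertible): the age-typical (BPD, MAD, FL) proportions are scaled by a
common factor so the formula reproduces the subject's true weight, then
each measure gets independent multiplicative log-normal noise (CV 2.5%).
This is one admissible choice — the source material describes no biometry
trajectories — and it keeps EFW↔biometry self-consistent: applying formula
1 to noiseless biometry returns the true weight exactly.

What the generator does **not** emulate: 1980s device error structure,
covariate correlations (marginals are independent), the original
risk-group sampling design, and any real heterogeneity between formulas'
populations.  Because biometry is generated *through* one formula, the
learner that pairs the generating model with a well-calibrated formula is
close to correctly specified — a more favorable situation for single
learners than real data, which is borne out in the ensemble study below.

The 70/30 split is stratified with round-half-up totals and
largest-remainder per-stratum reconciliation, reproducing 781/334 from
1115; strata with fewer than two members go wholly to train with a
warning.

## Ensembles

**Voting.**  Positive when strictly more than half of the selected
learners vote positive (a tie is negative); the positive-vote fraction is
the ROC score.  Learner selection fits a penalized logistic regression of
the training outcome on learner votes and keeps the nonzero coefficients;
an empty selection falls back to all learners.  The selection design
matrix uses **cross-validated** votes (from the same leave-one data the
stacking stage builds) rather than full-fit training votes: in the joint
fit each training subject's empirical-Bayes prediction is shrunk toward
their observed birth weight, making full-fit training votes near-perfect
for every learner and hence uninformative about generalization — the
standard argument for cross-validated first-level predictions in the
super-learner literature.

**Stacking.**  K = 10 stratified folds (plain K-fold when a class is
smaller than K); per fold, every learner is refitted with the held-out
subjects' birth weights masked and their predictions collected into the
leave-one data.  Macrosomia: meta-features are CV predicted birth weights,
the meta-learner is linear regression (OLS, or LASSO/SCAD/MCP-penalized
when a selector is requested), decision = meta prediction > 4000 g.  LGA:
meta-features are CV binary percentile calls, the meta-learner is a
positive-constrained logistic regression (selector "none") or a penalized
logistic regression, decision = probability > 0.5.  Fold refits are
warm-started from the full fit with a reduced iteration cap (the modes and
variance parameters move little when one fold is masked).

## Penalized solvers

Coordinate descent on internally standardized columns with warm starts
along 100 log-spaced λ from λ_max (all-zero solution) down to 0.001·λ_max;
logistic loss via outer IRLS with step-halving on the true penalized
deviance; λ chosen at the (stratified) K-fold CV deviance/MSE minimum (not
1-SE).  SCAD shape a = 3.7 and MCP shape γ = 3 — the literature's standard
defaults.  Nonconvex solutions are polished from the LASSO path solution
at each λ (warm-start strategy against bad local minima).  Weighted
subproblems use the adaptive-rescaling update (penalty applied in the
curvature-standardized metric), identical to the exact thresholding
operator when the curvature is 1 — the case tested against grid oracles —
and continuous for any IRLS weights.  The inner kernel is JIT-compiled.
Path/CV fits use relaxed inner tolerances; single-λ fits (including λ = 0,
which reproduces the unpenalized MLE to ≤1e−6) use tight ones.  The
logistic path carries a saturation early-exit (deviance < 1% of null)
mirroring glmnet's behavior.  The positive-constrained logistic fit is
bound-constrained L-BFGS-B on the exact likelihood with analytic gradient.

## Metrics

Sens/spec/PPV/NPV with Clopper–Pearson exact intervals; ±LR with
log-method intervals; Youden J = sens + spec − 1 (asserted as an identity
on every report); AUC as the tie-adjusted Mann–Whitney statistic with a
DeLong interval.  Zero denominators yield NaN plus a flag, never an
exception.  Per-learner ROC scores: the PBW itself for macrosomia, the
PBW-minus-reference-percentile margin for LGA.

## Validation studies and sizes

* **Recovery** (`experiments.recovery_study`): 20 replicates at n = 500,
  simulating directly from each model's equations at the default-dynamics
  truth; reports per-coefficient relative bias (criterion: < 5%) and Wald
  coverage (see the limitation above).
* **Ensemble gain** (`experiments.ensemble_gain_study`): 20 cohorts at
  n = 300 with a 2 × 6 learner grid (logistic/quadratic × six formulas
  spanning the bank's functional families), SCAD-selected voting and
  stacking versus the *train-selected best individual learner* — the
  learner with the best cross-validated training Youden, i.e. the best
  single choice available without test labels (the per-replicate test-set
  maximum is an oracle no committed choice attains and is reported
  separately).  Run sizes are chosen so the full suite completes on one
  CPU in well under half an hour.

## Degenerate inputs and tie-breaks

Zero Σ is accepted (positive-semidefinite check; sampling via eigen
decomposition); indefinite or asymmetric Σ is rejected.  A learner whose
formula or fit fails is flagged, excluded from the panel, logged and never
fatal; a failed fold inside CV imputes that learner's fold column by its
mean with a warning.  Voting ties are negative, macrosomia at exactly
4000 g is negative, LGA at exactly the percentile is negative — all three
from the strict wording "more than" / "above".  The LGA reference set
excludes the index subject and defaults to all subjects in the fitted
panel.
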