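# Methods

`metarisk` asks a single scientific question on data it simulates itself:
do circulating/urinary metabolites add predictive value for cancer risk
beyond established demographic, clinical and lifestyle risk factors in a
matched case-control study nested in a cohort of post-menopausal women?
Because the motivating cohort data are access-restricted, every stage of
the analysis is exercised end-to-end on a synthetic cohort with known
truth. This note records the models, the defaults and why, the numerical
choices, and what the synthetic results do and do not show.

## The synthetic cohort

The generator emulates the *design* of the study, not the marginal
distributions of any real population:

- **Two outcomes, one control group.** Outcome A (breast-like, default
  577 cases) and outcome B (colorectal-like, default 181 cases) share
  758 controls; each outcome-specific analysis uses its cases plus all
  controls, with case = 1.
- **1:1 matching.** Each case is paired to a control within 2 years of
  age and 2 months of enrollment date, exactly on race/ethnicity. The
  generator builds a feasible pairing by construction;
  `match_controls` re-derives it by minimum-cost bipartite assignment
  (Hungarian algorithm) per race/ethnicity stratum, with distance
  |Δage|/2yr + |Δenroll|/2mo. A greedy matcher would not satisfy the
  "minimize an overall distance" contract and would make the
  brute-force enumeration test meaningless.
- **Covariate signal.** Case covariate distributions are mean-shifted
  (BMI, waist, alcohol, folate, smoking for both outcomes; colonoscopy
  and polyp history protective for B) so that covariate-only prediction
  is modestly informative (CV-AUC in the high 0.5s to low 0.6s at the
  default sizes), as in the motivating analysis. Risk covariates carry
  MCAR missingness at configured per-variable rates (defaults: <1% for
  anthropometry and smoking, 6% for energy expenditure, 2.5% for
  dietary intakes); base design covariates are complete.
- **Metabolites.** Per-platform log-normal features:
  log intensity = per-feature baseline + per-person biological
  variation (SD uniform on 0.3–0.8) + smooth per-batch run-order drift
  + measurement noise (SD 0.2 by default). QC rows are a pooled sample:
  no biological term. Platform sizes default to the detected-feature
  counts of the motivating study (150 / 687 / 59 / 107).
- **Planted signal.** `n_signal_features` metabolites (default 10) of
  the signal platform shift the mean of signal-outcome cases by
  `effect_size` × total SD on the log scale (default 0.5 SD). For a
  single feature this yields a binormal AUC of Φ(effect/√2), which is
  the closed-form oracle used in tests. The other outcome's metabolite
  signal is exactly null, reproducing the study's qualitative
  contrast (signal for the colorectal-like outcome, none for the
  breast-like outcome).
- **LOD censoring.** Missingness is lower-quantile truncation per
  feature (values below the detection limit are removed), with
  per-feature rates drawn uniformly on [0, 2 × `lod_missing_rate`];
  the NMR-like platform has none. `heavy_missing_frac` optionally
  plants features above the 20% filter threshold.
- **Batch drift.** Default: per-batch random low-order polynomial in
  run order on the log scale (amplitude `drift_amplitude`), so a span-
  0.75 loess can remove it. `drift_profile="linear"` injects a
  deterministic monotone drift spanning `exp(amplitude)`-fold, used by
  the normalization-efficacy checks with amplitude ln 2 (a 2× drift)
  and noise SD 0.05 so that drift dominates replicate variation.

What passing tests on this generator do **not** show: robustness to
correlated metabolite blocks, non-MCAR covariate missingness,
platform-specific heteroscedasticity, or real-world confounding between
batch and outcome (run order is randomized here). Conclusions about the
pipeline's behavior on the restricted cohort data remain qualitative.

## Preprocessing

Fixed order: missingness filter → half-minimum LOD imputation →
covariate multiple imputation → 3×IQR truncation → QC-anchored loess.

- Features missing in more than 20% of study samples are removed; the
  boundary survives (a literal reading of "more than"). QC rows are
  excluded from the denominator.
- Below-LOD entries become half the feature's minimum nonzero observed
  value. This precedes and is never revisited by the covariate MICE:
  LOD censoring is a detection mechanism, not ignorable missingness.
- Covariate MICE: chained equations, 10 burn-in sweeps, m = 10
  completed datasets by default (m is not pinned by the motivating
  description; 10 is conventional). Continuous variables use
  predictive-mean matching with 5 donors on a linear model of the other
  covariates; binary variables use logistic draws. The outcome is
  excluded from every conditional model by construction — flipping the
  outcome column provably changes nothing — which keeps downstream
  honest CV valid.
- Truncation clips each variable to [Q1 − 3·IQR, Q3 + 3·IQR], bounds
  computed across all study samples of an imputed dataset (not per
  batch), with the linear-interpolation quantile convention; an oracle
  test quantifies insensitivity to the convention.
- Loess normalization applies to the LC-MS- and GC-MS-like platforms
  only (the NMR panel has no missing values or appreciable drift and
  the lipid panel is internally standardized in the motivating study).
  Per batch and feature, a LOWESS curve (span 0.75, one robustness
  iteration) of log QC intensity vs run order is fit and every sample
  is divided by the curve, rescaled to the batch QC median so units are
  preserved. The smoother is locally linear; the drift injected by the
  generator is low-order polynomial, which local lines remove to the
  accuracy the tests require. Fitting is on the log scale because the
  drift is multiplicative. Batches with fewer than 4 usable QC rows
  fall back to batch-median scaling (logged). A local smoother is not a
  projection, so re-normalizing already-normalized data is a strong
  contraction rather than an exact no-op; the deterministic steps are
  exactly idempotent.
- Replicate precision is summarized as the median over features of
  CV% = 100·SD/mean across designated replicate (pooled QC) rows.

## Super Learner

Implemented from scratch. Candidates are wrapped behind one contract
(fit / predict probability / native variable importance):
elastic-net logistic regression (|standardized coefficient| as
importance, sign recorded separately), gradient-boosted trees and
random forests (total impurity-decrease importance). The default
library is an elastic-net mixing grid {0.25, 0.5, 0.75, 1}, boosted
trees of depth {2, 4} with 500 rounds and early stopping, and a
1000-tree forest; a reduced one-per-kind library backs quick runs, and
"screened" variants (per-fold univariate top-k and lasso-support
screens) augment the library for the screens procedure. Boosting uses
scikit-learn's gradient boosting so that all tree ensembles expose the
same impurity-decrease importance contract.

Ensemble weights minimize the V-fold cross-validated mean negative
log-likelihood of the convex combination of held-out candidate
predictions (predictions clipped to [1e-6, 1 − 1e-6]), solved with
SLSQP over the probability simplex with an analytic gradient and a
best-single-candidate fallback; for up to three candidates the solution
is verified against a 0.01-step grid search. V = 10 by default
(automatically reduced when n < 10·V), stratified by outcome. A
candidate that raises in any fold is dropped with a warning and the
weights renormalize over the survivors. Candidates are refit on the
full data for prediction.

Variable-importance ranks are per-learner permutations of 1..p (most
important = 1), ties broken by stable column order so reruns are
identical.

## Variable selection

- **Lasso.** L1-penalized logistic path over a 30-point geometric
  penalty grid, tuned by 10-fold cross-validated deviance. The base
  design covariates (age, enrollment time, race/ethnicity indicators)
  are forced: their standardized columns are rescaled by 1e3 before the
  fit, making their effective L1 penalty negligible — the per-feature
  penalty-factor-0 construction — and they are always unioned into the
  output. The intercept is effectively unpenalized
  (`intercept_scaling=100`). The default penalty rule is the
  CV-minimizing λ; the more conservative one-standard-error rule is a
  config switch.
- **Ensemble weighted rank.** Weighted rank of variable j =
  Σ_l w_l · rank_l(j) with the Super Learner's convex weights
  (renormalized over learners that report an importance); the k = 20
  variables with smallest weighted rank are selected. Forced base
  covariates do not compete for the 20 slots and are appended.
- **Stability.** Selection frequency over the m imputed datasets; a
  variable is final iff its frequency strictly exceeds 0.70. Final sets
  are unioned over the two selectors within platform, then over
  platforms for metabolites; covariates are the unique covariates
  selected in any platform analysis.

A practical caveat established during development and verified against
an independent R glmnet run of the identical protocol: because the m
imputed copies differ only in imputed covariate entries (the metabolite
block is shared), stability across imputations cannot filter
chance metabolite-outcome correlations; at n ≈ 900 and 140 null
features both selectors stably flag roughly 2–4% of null features. The
across-imputation stability rule is a reproducibility filter, not an
error-rate control.

## Honest evaluation

Six joint procedures are evaluated: SL and SL-with-screens (no separate
selection), lasso+GLM, lasso+SL, SL+GLM and SL+SL. For each of `reps`
Monte-Carlo replications a fresh stratified 5-fold partition is drawn
(the repetition count follows the motivating analysis's 100; the fold
count is this package's choice); within every training fold the
selector is re-run from scratch and the predictor fit on the selected
variables; held-out samples are scored. An assertion inside the loop
audits that selection never receives held-out rows. Per-imputation
held-out predictions are averaged within a fold before the replication
AUC is computed (averaging per-imputation AUCs is the switchable
alternative; with identical copies the two coincide exactly). The
report is the mean over replications with a normal-approximation 95%
CI from the replication SE.

AUC is the rank statistic with ties counted 1/2. PEV (proportion of
explained variation) is the Pearson correlation between the binary
outcome and out-of-fold logistic predictions from the base covariates
plus the variable (or the full selected set, for the joint PEV);
directions come from the coefficient signs of the full multiple
logistic fit, with a ridge fallback under separation.

Null calibration is assessed against the unconditional permutation
distribution: the label permutation is redrawn for every replication.
Conditional on a single fixed permutation, CV-AUC is systematically
biased below 0.5 — across partitions of a fixed dataset the training
and test fold associations are anti-correlated given the dataset's
near-zero total association — so a fixed-permutation CI around 0.5 is
not the right reference.

A second calibration fact worth knowing: under an *exactly null*
metabolite arm, the expected metabolite "gain"
(CV-AUC(metabolites+covariates) − CV-AUC(covariates)) of the
lasso+GLM procedure is strictly negative, not zero — measured at
−0.01 to −0.03 across sample sizes (450 and 1335), penalty rules and
fold counts on this generator. Two mechanisms contribute: with the
CV-minimizing penalty, occasionally admitted noise metabolites degrade
held-out discrimination; with the one-standard-error rule, metabolites
are almost never selected, but the extra penalized columns shift the
penalty path and its cross-validation curve so that a harsher penalty
is chosen, dropping informative risk covariates only in the metabolite
arm. Honest pipelines should therefore expect a small negative gain,
not exactly zero, when candidate features are pure noise; "no
improvement" claims on real data are qualitative. Gains are likewise a
property of the generating conditions rather than of one realized
cohort: at n ≈ 450 the dataset-conditional gain wanders ±0.03 across
realizations while concentrating tightly within each, so the contrast
checks average over several generated cohorts.

Sensitivity switches mirror the motivating analysis: exclusion of
hormone-therapy users before imputation, and a pooled-platform mode
that concatenates all platforms' features before selection and fits
lasso+GLM only.

## Problem sizes used by tests and the acceptance script

Repeated-CV evaluation of Super-Learner-based procedures is expensive,
so the test suite and `scripts/acceptance.py` run the statistical
conditions of interest at reduced computational scale: the reduced
one-per-kind library (or a 30-round/30-tree variant in tight loops),
2–5 evaluation folds, 4–5 Super Learner weight folds, 10–12 point
penalty grids, and cohorts of a few hundred participants where the
check does not pin the sample size. Statistical conditions that define
a check — 0.5-SD effects, 10 signal features, the 0.70 stability
threshold, 25 or 100 replications where stated, the full default
cohort for selection recovery — are never reduced. The acceptance
script's study uses 200+200 cases, 400 controls, a 50-feature
signal platform and a 20-feature null platform, 20 replications of
3-fold CV, m = 2 imputations, and the lasso+GLM procedure.

## Known limitations

- Metabolite features are generated independently; real panels have
  strong correlation blocks (lipid classes) that change both selection
  stability and the meaning of top-k rank selection.
- The elastic-net and tree tuning grids of the motivating analysis are
  in an inaccessible appendix; the grids here are declared defaults,
  config-driven, not inferred.
- The lasso's forced-covariate construction is an approximation
  (penalty reduced by 1e3, not exactly 0); in practice forced columns
  are always returned because the output unions them.
- PEV is computed on the first completed dataset rather than pooled
  across imputations.
- Rubin-style pooling of per-imputation AUCs and the
  prediction-averaging default coincide only when imputations are
  identical; the choice is exposed, not adjudicated.
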