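# Methods

## The staged model

Two bootstrap ensembles are trained on the same subjects: Ensemble 1 on
the clinical (Stage-1) block, Ensemble 2 on the clinical and
imaging-derived (Stage-2) blocks concatenated. Each ensemble fits B base
classifiers on independent bootstrap draws (with replacement) of
round(f·n) training rows; a draw containing a single outcome class is
redrawn, with a bounded retry count. For a subject the B predicted
probabilities yield a mean μ and a sample standard deviation s (defined as
0 when B = 1). Uncertainty is deliberately the spread of *probabilities*:
0.50 is the only natural anchor for the decisiveness condition.

The deferral rule retains the Stage-1 prediction iff s ≤ σ_thr and
|μ − 0.50| > h_thr, with boundary semantics exactly as written (≤ on the
uncertainty, strict > on the decisiveness, so μ = 0.50 always cascades).
Stage-2 base-model predictions are computed only for cascaded rows; the
package counts base-model prediction calls so the cost contract
(B₂ × #cascaded) is assertable.

### Threshold tuning

The gate is tuned on a validation set by exhaustive grid search over
(σ_thr, h_thr). The objective is the *scaled weighted AUC*

J = (n_r·AUC_r + n_c·AUC_c) / (n_r + n_c),

the size-weighted mean of the AUC among retained rows and the AUC among
cascaded rows, where an empty subset contributes zero weight and a
single-class subset contributes its size with AUC fixed at 0.5. This
concrete form is a design choice of the package — the metric's name admits
several definitions — and it is isolated behind one function
(`scaled_weighted_auc`) so it can be swapped. Ties in the grid search are
broken toward larger Stage-1 retention, then smaller σ_thr, then grid
order; the default σ grid is the set of percentiles (0–100 in 10-point
steps, plus 0) of the validation uncertainties, and the default h grid is
0 to 0.5 in steps of 0.05, so both the fully-permissive and fully-blocking
gates are always in the search space.

The two stages' probabilities are pooled raw (no cross-stage calibration)
when the staged predictions are assembled into one ROC. This is a known
limitation: the two ensembles need not be on a common probability scale,
and the staged AUC can be degraded by scale mismatch even when each
stage's ranking is good.

## Feature pipeline

Order is fixed as NZV → correlation filter → center/scale (+ spatial
sign) → optional RFE; each stage clears the next one's preconditions
(the correlation filter requires no constant columns, RFE requires no
exact duplicates). All statistics are learned on training rows only and
the fitted pipeline is bound to the ensemble, so base models share one
transform and no test-fold information leaks into it.

- **NZV** (caret convention): a column is dropped iff it is constant, or
  its most-common/second-most-common frequency ratio is ≥ 19 *and* its
  percentage of distinct values is ≤ 10. Both thresholds are exposed.
- **Correlation filter** (caret's greedy heuristic): while any retained
  pair has |r| above the threshold (default 0.9), the member of the worst
  pair with the larger mean absolute correlation to the other retained
  columns is dropped; exact ties keep the lower column index, so the
  procedure is deterministic under column order.
- **Center/scale + spatial sign**: columns are standardized with the
  training mean and sample sd; with spatial sign enabled each row is then
  divided by its Euclidean norm (all-zero rows are left unchanged — no
  direction exists and determinism is preserved). The projection blunts
  outliers at a small cost in linear signal.
- **RFE**: backward elimination driven by base-learner importances
  (|coefficients| for the linear learner, impurity gains for the
  gradient-boosted trees), removing `step` lowest-importance features per
  round and only enough on the last round to land exactly on the target
  count. It returns a full elimination-order ranking (rank 1 = retained
  longest, survivors ordered by final importance). RFE is off by default
  (`rfe_n_target=None`): the base estimator, step and target count are
  exposed configuration because no single choice is canonical.

Base learners live in a registry: `"logistic"` (L2-regularized logistic
regression, the default) and `"gbt"` (gradient-boosted trees). An
optional hyperparameter grid is tuned once per ensemble by stratified
inner CV on the training rows before the bootstrap models are fit. Class
imbalance is left unweighted by default (a stratified bootstrap is
available); a consequence visible in the reports is that at the
conventional 0.5 cutoff a well-regularized model on a ~17%-prevalence
cohort predicts few positives, so sensitivities are low even when AUCs
are high.

## Evaluation harness

Stratified outer folds (default 10; on n = 547 this gives ~492-row
training and 54–55-row test folds). Inside each outer-training fold two
stratified validation sets (default 45 rows each) are carved; the first
tunes the gate thresholds, the second is held out entirely and reported
separately (its downstream use is left open). Ensembles are refit per
fold with fold-derived seeds; every preprocessing/selection/tuning
artifact is recomputed inside the fold.

Metrics: AUC is the Mann–Whitney statistic; accuracy, sensitivity and
specificity use the fixed 0.5 cutoff (consistent with 0.50 anchoring the
deferral rule); a metric whose class is absent is reported missing, not
zero. Across-fold averages and standard deviations are reported per
model. DeLong variances and covariances are computed from structural
components (placement values, midrank formulation); the headline DeLong
p-values and confidence intervals are computed on the outer-test
predictions pooled across folds, with per-fold p-values also emitted.
McNemar tests are run separately within positive-labeled (sensitivity)
and negative-labeled (specificity) subjects, exact binomial when the
discordant count is below 25 and continuity-corrected chi-square
otherwise; no discordant pairs gives p = 1 by definition. The
uncertainty-percentile analysis restricts to subjects whose ensemble
uncertainty is at or above each percentile and reports AUC with its
DeLong interval per point, degenerate subsets emitted as missing.

Baseline-characteristics tables use Fisher's exact test (two-sided, by
point-probability ordering) and Pearson chi-square with Yates continuity
correction on one-vs-rest 2×2 tables (per level, plus a collapsed row for
binary features), and Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom computed directly from group
means/sds/counts — so the tests are reproducible from printed summary
tables alone. The Yates-corrected variant is the default because
published per-level p-values computed from the same printed counts match
the corrected statistic; the uncorrected variant is a flag.

## Synthetic cohorts

The generator emulates the structure the cascade assumes rather than any
particular dataset's marginals. Latent risk is

z = β₁·g·u₁ + β₂·u₂ + σ_ε·ε,

with u₁ and u₂ unit-variance linear reductions of the two blocks, ε
standard normal, and g = 3 for a random "easy" fraction of subjects
(default 25%) whose clinical signal alone is strongly separating — the
subjects a cascade can save. Labels are assigned by ranking z and marking
exactly `n_positives` subjects positive, so the cohort composition
(default 547/94) is identical across seeds and fixtures are stable. The
clinical block is half continuous Gaussian, half dummy-coded binary
columns; the imaging block is a single-factor equicorrelated Gaussian
(every pair of columns correlates at ρ₂, default 0.5). Defaults β₁ = 0.4,
β₂ = 1.2, σ_ε = 1 put the clinical-only oracle at AUC ≈ 0.65 and the
full-signal oracle at ≈ 0.91 — a weakly informative cheap block and a
strongly informative expensive one.

What the generator does **not** emulate: real clinical variables' joint
distribution and marginals, missing data, nonlinear or interaction
effects, measurement error structure, site effects, or any image-derived
feature semantics. Tests passing on these cohorts demonstrate the
machinery's correctness and the cascade's qualitative behavior (ordering
of AUCs, uncertainty–performance relationship, retention strictly inside
(0,1)), not clinical performance on real data.

`inject_degeneracies` appends constant and exactly-duplicated columns
(provenance in the column names) as fixtures for the NZV and correlation
filters. `raw_clinical_table` emits an un-coded categorical/continuous
table for the baseline-statistics machinery.

## Problem sizes and numerical choices

The shipped experiments use n = 547 cohorts, B = 25 base models, 10 outer
folds and two 45-row validation sets; tendency tests use 20–25 seeds at
these or smaller sizes — enough replication for the qualitative claims
they check while keeping a full run to minutes on one core. Determinism:
every stochastic component consumes an explicit integer seed, fold- and
model-level seeds are derived arithmetically from it, and repeated runs
are bit-identical. Degenerate cases are defined, not errors, wherever a
convention is standard (all-zero rows under spatial sign, single-class
subsets in the scaled weighted AUC, zero discordance in McNemar, zero
margins in Fisher); they are errors where silence would mislead (constant
scores in a DeLong interval, both-groups-zero variance in Welch,
single-class training labels).

## Known limitations

- No cross-stage probability calibration (see above).
- No reweighting for class imbalance by default; sensitivity at the 0.5
  cutoff is accordingly conservative on imbalanced cohorts.
- The scaled weighted AUC is one concrete reading of a named-but-undefined
  objective; alternatives (e.g. pooled AUC with a retention penalty) fit
  behind the same interface.
- The second validation set is carved and reported but drives nothing.
- Retention rates vary widely across seeds and folds; the reported
  25th/50th/75th percentiles are the honest summary of that spread.
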