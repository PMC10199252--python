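# Methods

## Data model

The unit of analysis is the *episode*: one participant's single 3-month
period, labelled with the module practiced in it (`Presence`, `Affect`,
`Perspective`) or `Retest` for the control cohort, and carrying 68 change
scores (post- minus pre-period questionnaire score).  Change scores are
stored raw; each panel variable has an *improvement direction* (+1 when a
raw decrease means less distress, −1 for wellbeing-coded scales such as
life satisfaction and the mental-health continuum), which is applied only
when improvement-oriented effects are computed, never at load time.

The packaged default panel distributes 68 facets over the 16 named
instruments.  The study's exact subscale inventory is not public; the
packaged composition is a realistic reconstruction (every variable named in
the reported effect profiles is present) and is plain CSV data, so a
verbatim inventory can replace it without code changes.  The default
cohort design is RCC 90 / TC1 80 / TC2 81 / TC3 81; TC1 practices
(Presence, Affect, Perspective), TC2 (Presence, Perspective, Affect), and
TC3 a single Affect period — consistent with the pooled episode counts the
analysis uses (161 Presence, 242 Affect, 161 Perspective episodes;
first-period training vs retest = 242 vs 90).  Episodes with any missing
variable are excluded listwise from a contrast; no imputation.

## Synthetic generator

Change vectors are multivariate normal with a block correlation matrix:
within-questionnaire correlation ρ_w = 0.4, between-questionnaire ρ_b =
0.1, unit variances by default.  Episodes of one participant share a normal
random intercept carrying a fraction γ = 0.1 of the variance; the residual
carries 1 − γ, so the *marginal* per-episode variance is exactly sd² and
planted standardized effects are recovered without attenuation.  A planted
improvement d for (module, variable) shifts that variable's mean in that
module's episodes by `improvement_direction × (−d) × sd`; retest means are
zero.  Whole-episode missingness (assessment-level) and participant
dropout (truncated follow-up) are available and off by default, matching a
complete-case analysis.

The packaged effect specification plants the 13 reported module-specific
effects at the midpoints of the printed ranges: Presence 0.24 (range
0.23–0.25), Affect 0.30 (0.2–0.4), Perspective 0.325 (0.31–0.34).  Where
the per-variable values are unpublished this is range-faithful, not
value-faithful.  The generator does not model raw item responses, pre/post
score pairs, heavy tails, or practice-dose effects; conclusions from
passing tests are about the pipeline's statistical behavior under a
Gaussian block-correlated world, not about real questionnaire data.

## Classifier families

* `logistic_regression` — unpenalized; on perfect separation it refits with
  a light ridge (1e-6) and flags the fallback.
* `random_forest` — 500 trees, √p features per split.  Its contract
  importance is out-of-bag permutation importance (mean per-tree accuracy
  drop on that tree's own out-of-bag rows; the bootstrap indices are
  re-derived from the per-tree seeds and verified against the forest's own
  OOB estimate in the tests).
* `elastic_net` — logistic elastic net, mixing 0.5, regularization strength
  chosen by inner 5-fold CV on a log-spaced path of 8 values; predictors
  standardized in-pipeline; importance = |standardized coefficient|.
* `bayesian_regression_tree` — a sum-of-trees classifier.  No posterior
  tree sampler is available in the dependency set, so this slot is backed
  by gradient boosting (50 shallow trees, depth 2), with the proportion of
  trees splitting on a variable as the inclusion-style importance; the
  backend is recorded in the fitted model's metadata.  Because greedy
  boosting chases sample-specific structure, its raw inclusion proportions
  are only meaningful against the label-permutation null used in stage 1
  (a fixed 1/p cutoff admits most variables even on pure noise — measured
  53/68 on a null dataset).

Class imbalance (e.g. 161 vs 242 episodes) is handled by the balanced
accuracy metric only; training folds are not resampled.

## Stability selection

Stage 1 cutoffs are scale-free and self-calibrated: elastic net — nonzero
coefficient; random forest and sum-of-trees — importance above the 95th
percentile of a pooled within-sample label-permutation null (4 and 2
permutation refits at desk scale; the score and its null always share the
importance definition).  The screening forests use 50 trees with
`min_samples_leaf=5`: importance *ranking* stabilizes far below the 500
trees used for prediction, and bounded leaves keep the null refits cheap.
Stage 2 keeps variables nominated by at least two of the three algorithms.

Stages 3–4 rescore candidate subsets with a logistic model refit on B = 100
shared bootstrap resamples and evaluated on out-of-bootstrap rows (fitting
is a batched weighted IRLS — bootstrap multiplicities as observation
weights, all B Hessians from one GEMM — validated against standard fits in
the tests).  Design choices that matter, each adopted after the obvious
alternative measurably failed:

* **Comparison scale.**  Subsets are compared by *paired mean out-of-
  bootstrap log-likelihood* (same resamples with and without a variable),
  not by balanced accuracy: BAC saturates, and once a model is at ~0.96 the
  per-variable BAC gain is far below any resolvable tolerance, so strong
  genuine contributors get dropped.  BAC-based variants (`paired_bac`,
  `median_bac`) remain available by flag.
* **Selection shrinkage.**  The scorer's ridge is fixed at 0.1·n on
  standardized coefficients (intercept unpenalized).  Near separation an
  unshrunk fit is overconfident and its held-out log-likelihood collapses
  on confident errors, hiding late contributors; at likelihood-optimal
  shrinkage the same masking persists (a 14th strong variable measured
  −0.0009 nats at optimal ridge vs +0.0024 at strong ridge).  The strong
  fixed shrinkage serves subset *comparison* only; inference models
  elsewhere are unpenalized.
* **Gates.**  Entry needs a paired gain > 1e-3 nats; removal in the
  backward pass happens only when it costs ≤ 2e-4 nats.  The asymmetry
  protects borderline true contributors from removal noise.
* **Marginal-relevance screen.**  A candidate may only enter if its
  single-variable model beats the intercept-only model on the paired
  criterion.  This excludes pure *suppressors* — variables that improve the
  joint model solely by cancelling noise in a correlated informative
  variable.  Suppressors are legitimate for prediction but have no marginal
  effect to interpret in an effect profile, which is this procedure's
  target.
* **Collinearity screen.**  Before performance-based elimination, a
  selected variable whose R² on the other selected variables exceeds 0.95
  is dropped (keeping the higher-ranked one).  Held-out likelihood cannot
  distinguish an exact duplicate from a weak independent contributor at any
  single shrinkage, so redundancy is detected in predictor space.
* **Above-chance screen.**  A final selection whose model's mean
  out-of-bootstrap BAC is ≤ 0.52 is discarded — selections with no held-out
  signal are noise.

The full filter runs on each training fold of a stratified
(participant-grouped) 10-fold cross-validation; a variable counts as
selected in a repetition when it survives in a strict majority of folds
(an any-fold option exists).  Selection rate = fraction of repetitions;
variables at rate ≥ τ = 0.95 form the replicable set.  A master seed
spawns child seeds per (repetition, fold, stage) through
`numpy.random.SeedSequence`, so runs are bitwise reproducible.

Performance estimation (10×10-fold CV) and selection-rate estimation
(nominally 200 repetitions; 20 at desk scale) are two separate loops
sharing the fold generator, mirroring the separate reporting of accuracy
summaries and selection-rate diagrams.

## CV engine

Module contrasts use all episodes of the two modules; the shared-effects
contrast uses first-period episodes only (every participant contributes
exactly one episode; an all-periods option exists).  Folds are stratified
by class and never split a participant (the leakage-safe choice, since
TC1/TC2 participants contribute episodes to both classes of a module
contrast); group integrity is asserted on every fold.  Filtered
configurations run the four-stage filter once per training fold and fall
back, logged, to all variables if nothing survives.  Chance level is fixed
at 0.5.  Per-repetition mean BACs are tested against 0.5 with a one-sided
Wilcoxon signed-rank test: exact null distribution for n ≤ 25 without
ties/zeros, otherwise normal approximation with continuity correction;
all-0.5 samples return p = 1 with a warning.

## Effect profiles

The exemplary logistic regression is fit unpenalized on z-standardized,
*improvement-oriented* predictors (improvement = −direction × change), so a
positive coefficient always means "improvement in this facet points to the
positive class" — the convention of the study's coefficient plots — and
attribution is just the coefficient sign.  Per attributed variable the
profile reports improvement-oriented Cohen's d (pooled-SD, n_a+n_b−2
denominator) and one-sided Welch t-tests (Satterthwaite df) against the
other module and against the retest comparator; `specific_effect` requires
both p < 0.05.  "t-test" is read as Welch's; no multiple-testing correction
is applied by default (Benjamini–Hochberg available by flag at the caller's
level).  The retest comparator uses RCC episodes from the periods in which
the attributed module was scheduled (matched-period; first-period by flag).

## Problem sizes and tolerances

Desk-scale defaults keep the full test suite and drivers in the tens of
minutes: 20 stability repetitions (vs the nominal 200), 4/2 permutation
refits in stage-1 nulls, 100 bootstrap resamples, 1000 replicates for the
d-estimator calibration (tolerance ±0.02 on a planted 0.25), 200-replicate
scaled variants (tolerance ±0.03) in unit tests.  The support-recovery
checks plant d = 1.2 and generate *independent* facets: under block
correlation, same-questionnaire siblings of planted variables are genuine
suppressors (optimal conditional coefficient ≈ −ρd/(1−ρ²)) and a
dataset-level marginal fluke (|d| ≈ 0.2 occurs for several of 54 null
variables at n = 403) is statistically indistinguishable from a true effect
of that size, so "recover exactly the planted set" is only a well-posed
oracle when the planted set is the complete discriminative set.  All other
tests keep the correlated default.

## Known limitations

* Like the original procedure, the pipeline cannot distinguish a
  dataset-level spurious association of |d| ≈ 0.25 from a true effect of
  the same size; the 95% selection-rate criterion measures within-dataset
  replicability, not across-dataset truth.
* At the reported real-data effect sizes (d ≈ 0.24–0.33) and cohort sizes,
  the synthetic pipeline's BACs are modest (≈0.6) and few variables clear
  the 95% criterion at 20 repetitions; the reported classifier accuracies
  (medians up to 84%) are not reproducible from printed summary statistics
  alone, and the generator makes no attempt to match them.
* The Bayesian-regression-tree slot is a gradient-boosting stand-in with
  inclusion-frequency importance, not a posterior sampler.
* The stepwise stage is a ranked single sweep (repeated to a fixpoint)
  rather than full greedy re-evaluation; with ≤ ~20 voted candidates the
  difference is immaterial and the cost is linear instead of quadratic.
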