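# Methods

`seqrisk` implements a multisite, multimodal prognosis pipeline for a
rare binary outcome (psychosis transition in a clinical high-risk /
recent-onset depression population, prevalence ≈ 7.8%): unimodal
linear risk calculators under leave-one-site-out nested
cross-validation, stacked and clinician-integrated fusion of their
out-of-fold scores, stability-based model condensation, and a
sequential deferral workflow optimizer. Everything is exercised on a
synthetic cohort generator, so the statistical claims the test suite
makes are claims about the generator's stated world, not about any
clinical dataset.

## Synthetic cohort model

The generator emulates the *structure* of the motivating study, not
its joint distribution (the clinical data are not public and no
generative model for them exists):

* **Sites and outcome.** 334 subjects over 7 recruitment sites with
  sizes (109, 25, 34, 63, 35, 38, 30) and 26 transitions allocated
  (10, 2, 2, 4, 2, 6, 0) across sites — one site has no events, which
  deliberately stresses the site-held-out evaluation.
* **Feature blocks.** Clinical-neurocognitive: 141 columns, 15
  informative; polygenic scores (PRS): 10 columns; gray-matter
  parcels (sMRI): 200 columns, 100 weakly informative. Informative
  features are unit-variance Gaussians whose mean is shifted by the
  block's standardized effect size for transition subjects.
* **Effect sizes** (clinical 1.0, PRS increment 0.25, sMRI 0.18·≈2 =
  0.35 per parcel) were calibrated once so that the unimodal
  calculators reach the balanced-accuracy ranges the motivating study
  reports on real data (≈ 76 / 66 / 71% for clinical / PRS / sMRI),
  and then frozen. Nothing in the generator was adjusted after the
  acceptance tests were written.
* **PRS block.** Column *k* is the re-standardized cumulative sum of
  *k* noisy liability increments, mimicking nested GWAS p-value
  inclusion thresholds: adjacent columns are strongly correlated and
  the most inclusive score carries the highest signal-to-noise ratio
  (the "only the most inclusive threshold is informative"
  phenomenology).
* **Raters.** Binary clinician prognoses are conditionally
  independent label flips at sensitivity 0.615 / specificity 0.849.
  This reproduces the raters' operating point, not their error
  correlations with any feature block (an optional dependence on a
  clinical latent factor is out of scope for the default world).
* **Missingness.** 2% missing-completely-at-random entries on the
  clinical block only. The true mechanism in the motivating study is
  unknown (its per-modality denominators differ); MCAR is the
  weakest assumption and is imputed per training split.
* **Cross-block correlation** defaults to 0 (blocks independent given
  the label); a shared latent factor with loading √ρ is available.

What a green test does **not** establish: real clinical features are
non-Gaussian, inter-correlated and site-shifted; raters correlate
with the clinical block; missingness is not MCAR. The suite
establishes correctness of the machinery and the qualitative
phenomena (fusion gains, deferral parsimony, calibration of the
significance machinery), not clinical performance.

## Base learner and nested cross-validation

* Outer loop: one fold per site (leave-one-site-out), testing
  geographic transportability.
* Inner loop: stratified k-fold (default 10-fold, 1 repeat) inside
  each outer training set; the margin penalty C is selected from a
  log₂ grid (2⁻⁶…2⁶) by mean inner-validation balanced accuracy, ties
  to the smaller C (stronger regularization).
* Learner: linear hinge-loss SVM with inverse-frequency class weights
  — mandatory at 7.8% prevalence to reach a high-sensitivity regime
  with a decision threshold of 0. The fit is done in the dual via
  libsvm on a Gram matrix precomputed once per inner split and shared
  across the C grid (deterministic and roughly 20× faster than a
  primal solve at large C); primal weights are recovered from the
  support vectors for stability mapping.
* Preprocessing per training split: median imputation, then
  z-scaling. Parameters never see held-out subjects. Site-effect
  correction is deliberately absent — cross-site transport is exactly
  what the outer loop measures.
* A held-out site is scored by the mean decision value of the inner
  ensemble at the selected C; pooled out-of-fold (OOF) scores are the
  interface to everything downstream.
* Sites whose held-out fold lacks one class are evaluated on the
  defined rate only (specificity for an event-free site); per-fold
  BAC feeds the model-comparison stage.

## Stacking and the cybernetic model

The meta-learner is the same linear family, trained under the *same*
outer fold plan on the base models' OOF scores (never resubstitution
scores). A subject's base score always comes from models that never
saw it, and the meta-model scoring a site never saw that site. The
cybernetic variant appends the binary rater estimate as the last
predictor column. Subjects missing any input score are excluded
(complete-case) and counted.

## Stability mapping and condensation

Two per-feature summaries of a weight ensemble:

* **Cross-validation ratio** — mean weight / standard error across
  the CV models; display threshold |ratio| ≥ 3; never used for
  condensation.
* **Sign-based consistency** — exact two-sided binomial test of the
  weight-sign agreement across models against a fair coin, mapped to
  a z score; selection requires z > 3.28 and Benjamini-Hochberg FDR
  < .05.

The binomial assumes independent votes. Weight vectors from nested-CV
folds violate this badly — inner training sets share most subjects,
so even a pure-noise feature keeps one sign across folds, and in
planted-truth simulations the CV-fold ensemble selected ~80 of 141
features (false-discovery proportion ≈ 0.8). The package therefore
votes with `subsample_stability_weights`: 15 models, each trained on
a class-stratified random 10% of the cohort (pairwise overlap ≈ 1%),
which makes the votes nearly independent; near-unanimity is then only
reachable by genuine signal. Measured on planted truth this yields an
empirical FDR ≈ 0.13 with ~11–12 of 15 planted features recovered.
The condensed model retrains the full nested CV on the selected
columns. Selection happens on the discovery data itself (mirroring
discovery-then-validate practice), so condensed-model discovery
metrics are optimistic; judge them on held-back data.

## Sequential deferral workflows

A workflow is an ordered list of stages (the entry model plus
cumulative stacks) with one shared pair of percentile propagation
cutoffs (lower, upper) and a parsimony weight Γ ∈ [0, 1]:

* At each stage, percentiles are computed transductively on the
  scores of the subjects entering that stage (Hazen convention,
  pct = 100·(rank − ½)/n, tie groups share their rank span).
  Subjects whose whole tie group lies below the lower cutoff exit as
  confident negatives; above the upper cutoff, confident positives;
  everything inside or straddling the window is deferred to the next
  assessment. At the final stage remaining cases are decided by score
  sign. An upper cutoff of 100 means "no early positive exits".
* Search: exhaustive over stage orderings and cutoff pairs, maximizing
  J = (1 − Γ)·BAC/100 + Γ·(1 − mean assessments / max assessments).
  Ties go to fewer assessments, then higher BAC (so a pure-parsimony
  search still returns the most accurate single-assessment rule),
  then lexicographic order. Γ = 0 optimizes accuracy alone; Γ = 1
  collapses propagation entirely (full-battery fraction 0).
* The objective J is this package's declared reading of "parsimony
  regularization" — the motivating study names Γ but not its
  objective. J reproduces the printed endpoints qualitatively; the
  Γ = 0.5 interior point is steeper here than in the study's real-data
  ladder (the linear assessment penalty dominates sooner).
* Because the search maximizes a cross-validated quantity over ~10³
  configurations, the winning workflow's BAC is transductively
  optimistic; the trace reports the configuration so it can be
  re-evaluated on fresh scores.

## Significance and model comparison

* **Permutation test:** the entire nested CV is re-run per permuted
  label vector; p = (1 + #{null ≥ observed})/(1 + B) with B = 1000 by
  default, 100 in the bundled pipeline for the one-CPU budget (the
  default permutes the clinical calculator; others are configurable —
  permuting all three at B = 100 would exceed the 15-minute budget).
* **Quade test** on the folds × models BAC matrix (within-fold ranks
  weighted by the rank of the fold's range, F-referenced); all-equal
  blocks are flagged p = 1. Post hoc pairwise contrasts use the
  Heckert–Filliben t form on the weighted rank sums with BH-FDR over
  all pairs, two-sided.

## Numerical conventions

* All rates live on the percent scale and are computed from unrounded
  ratios; half-away-from-zero rounding to one decimal happens only at
  presentation (this is the convention under which every printed
  derived value of the motivating study's performance table is
  reproduced exactly, including a positive likelihood ratio of 2.55
  printing as 2.6).
* Pearson χ² on 2×2 tables is uncorrected — the only variant that
  reproduces the printed group contrasts.
* LR⁺ with perfect specificity is reported infinite, undefined ratios
  as NaN; neither raises.
* One global seed expands into per-stage seeds via
  `SeedSequence([seed, stage_index])`; reruns are byte-identical.
* SVC iteration cap 20 000: extreme C values may stop early; the
  truncated margin fit is accepted (the affected C values lose the
  inner-CV selection anyway).

## Known limitations

* The generator's Gaussian world yields higher AUCs than real data at
  matched BAC; absolute fused-model performance is therefore not
  comparable to the study's, only directions and orderings are.
* The exact inner-CV geometry, learner and preprocessing of the
  motivating study live in unavailable supplementary methods; all are
  exposed as configuration rather than guessed as fixed truth.
* Percentile cutoffs are shared across stages (the printed workflow
  specifications show one pair per workflow); per-stage cutoffs are a
  straightforward extension not implemented.
* No probability calibration, nonlinear kernels, or cost-weighted
  economics of assessment burden.
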