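# Methods

## The model

`polyprisk` implements a risk-stratification pipeline for colorectal
neoplasia from routine health-checkup data (physical findings, blood panel,
lifestyle questionnaire). The pipeline, per sex:

1. **Eligibility filtering.** Records are excluded, in order, for: repeat
   colonoscopy within the study period, prior colorectal surgery, IBD,
   FAP/Lynch syndrome, age ≤ 20, and a checkup-to-colonoscopy gap > 365 days.
   A record with several flags counts only at its first matching stage, so
   stage tallies are disjoint. Records with a feature value above its
   schema's discard limit (implausible assay values) are dropped.
2. **Polyp-size-threshold labelling.** At threshold *t* ∈ {0, 6, 8, 10} mm a
   patient is labelled *yes* iff their largest recorded polyp is
   ≥ max(*t*, 1) mm; recorded polyp sizes start at 1 mm, so *t* = 0 means
   "any polyp". Patients with only sub-threshold polyps join the negative
   class.
3. **KDE probability transform.** For each feature, a Gaussian kernel
   density estimate is fit on the *polyp-positive training patients only*:
   f̂(x) = (1/nh) Σᵢ φ((x − xᵢ)/h), evaluated on 512 evenly spaced points
   spanning [min − 3h, max + 3h]; new values are linearly interpolated and
   clamp to the grid ends. The density is rescaled to unit maximum and
   raised to an exponent e ∈ {1, 2, 3, 4} that sharpens the contrast:
   T(x) = (f̂(x)/max f̂)ᵉ ∈ (0, 1].
4. **Sigmoid-like variant.** All grid values on one side of the density
   maximum are clamped to 1 — `direction = "higher"` saturates risk for high
   values, `"lower"` for low ones — producing a monotone risk curve. A
   running-maximum envelope toward the clamped side guarantees monotonicity
   even for multimodal densities (for unimodal densities it is the identity
   on the rising limb). The exponent is applied after clamping; clamped
   points are 1 either way, this is stated for determinism.
5. **Optimization loop.** A grid over thresholds × transform modes
   (none / kde / sigmoid_kde) × exponents × a ten-member classifier zoo
   (AdaBoost, Bernoulli naive Bayes, Gaussian process, gradient boosting,
   LDA, linear SVC, logistic regression, MLP, ridge, SVC — fixed
   widely-used hyperparameters, no per-candidate tuning). Every selection
   uses the Matthews correlation coefficient,
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
   defined as 0 for a degenerate table, estimated by stratified 5-fold CV
   on the training split. Optional stages: coordinate-wise bandwidth search
   (Silverman's rule × {0.25, 0.5, 1, 2, 4}, ties toward the smaller width)
   and backward feature elimination (retrain without each feature, drop the
   one whose removal maximizes CV MCC — the most harmful/least helpful —
   until 3 remain; ties break by column order). The top-6 candidates by CV
   MCC are refit on the full training split and compared once on the test
   split; the test-MCC argmax wins.
6. **Scores and reports.** The *polyp score* is the class-1 probability
   where available, otherwise the decision function min–max scaled by the
   training-score extremes and clamped to [0, 1]. Score-based binarization
   uses a 0.5 cutoff; the estimator's own `predict` uses the underlying
   classifier's native rule. Evaluation reports sensitivity, specificity,
   accuracy, AUC (trapezoidal over the ROC curve; ties count ½), MCC, and a
   per-true-class-normalized confusion matrix. A FIT baseline treats a
   positive fecal immunochemical test as the predicted label. Kruskal-Wallis
   H (tie-corrected, χ² p-values) screens features; raw p-values are
   reported with a Benjamini–Hochberg column for reference only.
7. **Attribution.** Shapley values of the polyp score, with marginal
   features drawn from a background sample (interventional expectation):
   exact coalition enumeration for p ≤ 12, permutation sampling otherwise
   (additivity base + Σφ = score holds exactly on both routes). The
   per-patient report lists each feature's sigmoid-KDE value, flags values
   ≥ 0.9 (configurable) as near risk saturation, and names the top-3
   Shapley contributors.

### Assumptions

- One record per patient (no longitudinal linkage); the colonoscopy within
  365 days reflects polyp status at checkup time.
- The transform is strictly per-feature; no joint/multivariate density is
  modelled.
- Missing feature values are median-imputed from the training split only.
- The KDE kernel is Gaussian; the normalization is to unit maximum (the
  transformed curve peaks at exactly 1), not unit area.
- `direction = "auto"` resolves by comparing class medians on training
  data (positive-class median higher ⇒ "higher"), with per-feature
  overrides available.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| threshold_mm | {0, 6, 8, 10} | mm | clinical polyp-size cutoffs |
| exponent e | {1..4} | — | KDE sharpening power |
| bandwidth h | Silverman | feature units | 0.9·min(sd, IQR/1.34)·n^(−1/5) per feature, positive-class values |
| h search grid | Silverman × {0.25,…,4} | — | coordinate-wise, CV-MCC objective |
| grid_size | 512 | points | evaluation grid |
| test_fraction | 0.25 | — | stratified split |
| CV folds | 5 | — | stratified, seeded |
| elimination floor | 3 | features | |
| best-k | 6 | candidates | global top-k per sex |
| flag threshold | 0.9 | — | "close to 1" biomarker flag |
| score cutoff | 0.5 | — | score-based binarization |

## The synthetic cohort generator

Real checkup+colonoscopy datasets of this kind are hospital-owned, so the
package ships a generator whose defaults define its study conditions:

- 39 features per patient: anthropometrics and most labs normal,
  right-skewed labs (triglycerides, GGT, CRP, transaminases, amylase, WBC)
  lognormal, lifestyle items ordinal {0, 1, 2}.
- 6 informative features at a +0.5 pooled-SD class shift (log scale for
  lognormal): age, BMI (obesity), triglycerides, GGT (alcohol/metabolic),
  CRP (inflammation), ALT (liver) — the obesity/alcohol/inflammation
  markers most consistently associated with colorectal adenoma.
- Prevalence 0.30 (men) / 0.20 (women); polyp sizes drawn from bands
  {1–5, 6–7, 8–9, ≥10} mm with probabilities (0.62, 0.18, 0.04, 0.16),
  uniform integer within band.
- FIT sensitivity 0.30 / specificity 0.90 given polyp status.
- One explicit RNG stream per cohort; identical seeds give byte-identical
  cohorts.

These defaults were calibrated so the class-conditional distributions
overlap heavily and an untransformed-baseline classifier lands at a
low-but-clearly-positive MCC (≈ 0.25–0.38 at threshold 0, n = 1000),
comparable to published no-transform baselines on real checkup data.

The generator emulates: sex-stratified cohorts, overlapping classes,
configurable prevalence/size law/FIT error rates. It does **not** emulate:
feature correlations (features are independent given class), non-monotone
risk shapes, multimodal class-conditional distributions, measurement
missingness patterns, or repeat-visit structure. Consequently, passing
tests on synthetic data demonstrate pipeline correctness and calibration,
not clinical performance.

A deterministic 1290-record reference roster reproduces a documented
screening cohort flow exactly (274/8/5 exclusions → 1003 eligible;
611 male / 392 female; nested polyp-size counts 547/210/113/93; 704
FIT-positive; screening context 21 447 screened, 1133 FIT-positive) and
anchors the filtering tests.

## What the transform can and cannot do here

The sigmoid-KDE transform is a per-feature **monotone** map (the envelope
guarantees it). Under the generator's independent location-shift family,
scale-invariant linear classifiers (LDA, logistic regression) on the raw
features already realise essentially all available signal, so no monotone
per-feature reparametrization can beat them — measured across seeds the
best untransformed model's test MCC exceeds the best sigmoid-KDE model's
by ≈ 0.03–0.08. On real checkup data the transform's value comes from
properties this family deliberately excludes (skewed multimodal geometry,
non-monotone risk, classifiers applied to unscaled raw features). Relatedly,
both classes' transformed distributions peak at the clamp plateau (mode ≈ 1
for both), so class separation induced by the transform shows in the
class-conditional *means* of the transformed values, not the modes; the
property suite asserts the mean-separation version.

## Numerical choices

- MCC of a confusion matrix with a zero marginal is 0 (not NaN).
- Bandwidth for a degenerate (zero-variance) feature: flagged with a
  warning, token-positive Silverman fallback.
- Bandwidth-search and elimination ties break deterministically (smaller
  h; earlier column).
- `select_best` ties break by higher CV MCC, then classifier zoo order.
- The Gaussian-process classifier uses a fixed 1.0·RBF(1.0) kernel without
  marginal-likelihood optimization — transformed features live in (0, 1],
  where a unit length scale is appropriate — keeping candidates strictly
  fixed-hyperparameter and fits O(n³) once.
- Empty score-summary cells yield empty summaries; score KDEs are rescaled
  to unit maximum for plotting.

## Experiment problem sizes

The packaged experiments (also run by `scripts/acceptance.py`) use:

- *Transform contrast*: male cohort, n = 1000, threshold 0, zoo
  {logistic regression, Gaussian process, LDA}, Silverman bandwidths, full
  feature set, per-mode winner by training-CV MCC compared on test MCC,
  10 seeds. The coordinate-wise bandwidth search is exercised in its own
  unit test (planted bimodal signal) rather than inside this loop; on this
  generator it shifts the contrast by < 0.02 MCC.
- *No-signal null*: n = 2000 with every class shift removed, a 50 % test
  split for a precise null measurement, linear zoo {logistic regression,
  LDA, linear SVC}, full grid at threshold 0, final `select_best(k = 6)`,
  10 seeds.
- *Feature recovery*: 5 features (2 informative at +1.0 pooled SD, 3
  noise), n = 600, prevalence 0.5, logistic regression on the sigmoid-KDE
  transform, elimination to the 3-feature floor, exact Shapley importance,
  10 seeds.

## Known limitations

- No hyperparameter search, stacking, calibration, or deep models.
- The per-patient report flags biomarkers; it does not recommend
  interventions.
- The FIT comparison is reported both on all eligible records and on the
  model's sex-matched subset, since the appropriate denominator is
  context-dependent.
- Candidate tables can be large; the grid is embarrassingly parallel but
  runs single-process by default, and results are independent of execution
  order.
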