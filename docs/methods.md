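# Methods

## Model and procedure

`depclust` treats each respondent as a point in raw item space
(ℤ₊^m, m = 13 for BDI-13, each coordinate 0–3) and partitions the sample
with Lloyd's k-means, k fixed a priori to the number of norm severity
levels (4). No standardization is applied: all items share one bounded
scale, and the cutoff-based comparison is defined on the same raw units.

**Initialization.** Random seeding makes k-means non-reproducible and
occasionally unstable, which is unacceptable for a classification that
screening decisions may rest on. The package therefore uses farthest-
point (max–min) seeding anchored at the literal all-zero vector. The
anchor is used even when no respondent scored all zeros: it is the
semantically defined "no symptoms" point, and a data-dependent anchor
would make the model depend on which respondents happened to be
sampled. All argmax/argmin ties break to the lowest row/center index;
given that rule the entire fit is a pure function of the data matrix.

**Iteration and convergence.** Assignment uses squared Euclidean
distance; centers are recomputed as cluster means; iteration stops when
no center changes (exact equality; a tolerance knob exists and defaults
to 0) or after 100 iterations. A cluster left with no members keeps its
previous center — this cannot arise under max–min seeding on data of
this shape, but the rule must be defined for the contract to be total.
The within-cluster sum of squares is recorded per iteration and asserted
non-increasing on every fit (Lloyd monotonicity); a violation raises
rather than returning a silently wrong model.

**Severity ordering.** Cluster indices are arbitrary; severity levels
are not. Clusters are mapped to levels None < Mild < Moderate < Severe
by ascending *center total score*, the sum of the center's coordinates —
the natural severity statistic on these scales. Ties (equal totals)
break by cluster index.

## Cutoff criteria

Cutoffs are stored as inclusive integer upper bounds of the first k−1
levels, so the conventional "0–4 / 5–7 / 8–15 / 16–39" notation maps
exactly onto a partition of [0, 39] with no half-open ambiguity. The
built-ins are the original BDI-13 norms and the two one-point-shifted
variants (`criterion1`: 0–3 / 4–6 / 7–14 / 15–39; `criterion2`:
0–5 / 6–8 / 9–16 / 17–39) that stand in for plausible re-normings.
Custom criteria (other scales, other level counts) are constructed from
(name, bounds, score_max).

## Careless-response screen

Inattentive responding is screened with Tukey fences on a per-respondent
scalar: remove respondents whose statistic falls outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]. The statistic is the total score — the
only per-respondent scalar defined for bare item data — and quartiles
use the linear-interpolation convention (`numpy.percentile` default);
both choices are configuration points, and the convention matters for
bit-reproducibility of exactly who is removed. The screen is one-pass:
re-fencing the retained sample could remove more respondents, so it is
deliberately not idempotent. A multiplier of `inf` disables it. Missing
item responses are rejected at read time, never imputed. Note that this
screen catches extreme totals, not uniform-random responding near the
sample median; it is an outlier rule, not a full careless-response
index (longstring, Mahalanobis and response-time indices are out of
scope).

## Evaluation harness

**Classifier.** The linear discriminant (shared-covariance Gaussian
class model) is scikit-learn's `LinearDiscriminantAnalysis` with the SVD
solver and tolerance 1e-4; singular directions of the pooled covariance
below the tolerance are dropped, which regularizes rank-deficient item
matrices (e.g. a constant item in a subsample).

**Cross-validation.** Folds are stratified by label and shuffled under
the given seed. With a smallest class of a few percent of the sample,
unstratified folds can lose a class entirely, making per-class
sensitivity undefined; stratification is the defensible default.
Metrics per fold: overall accuracy, per-class recall (sensitivity), and
AUC macro-averaged one-vs-rest over the class posteriors — the most
common single-number AUC convention for a 4-class problem. Class
imbalance is addressed by optional random under-sampling of every class
to the smallest class size (without replacement, order-preserving,
seeded).

**Robustness protocol.** Reference labeling: the deterministic max–min
k-means on the full sample. Per replicate: draw a random
`train_fraction` (default 0.7) subsample (indices kept sorted, so row
order — and with it the tie rule — is preserved and the degenerate
`train_fraction=1` replicate reproduces the reference exactly); re-run
the full constructor on it; fit the LDA on the subsample with its
cluster labels; label the complement with the LDA; reassemble the
full-sample labeling in original respondent order; score against the
reference with the adjusted Rand index. Reported: all replicate ARIs,
their mean, and the sample SD (denominator reps − 1). A replicate whose
subsample cannot support the constructor (fewer than k distinct points)
is excluded and counted. Default is 200 replicates, which stabilizes
the mean to ~±0.005 on the cohorts used here; the protocol itself is
replicate-count-agnostic.

**Learning curves.** For each requested training-set fraction:
stratified 30% holdout, stratified subsample of the remainder, LDA fit,
train and test accuracy, averaged over seeded splits. Fractions leaving
less than one member of some class are skipped with a warning.

## Agreement statistics

Cohen's kappa is implemented directly on the confusion matrix
(unweighted; the ordered-category weighted variant is deliberately not
used, matching the comparison being audited), returning NaN when chance
agreement p_e = 1 (all mass in one marginal cell), where the statistic
is undefined. The adjusted Rand index is the Hubert–Arabie
permutation-model form (via scikit-learn); the test suite checks it
against an independent brute-force pair-counting oracle, and kappa
against scikit-learn's label-based implementation.

## Convergent validity

Pearson chi-squared (no continuity correction) for demographics ×
levels; one-way ANOVA with eta-squared = SS_between / SS_total for
correlate scales, with per-level means reported to show the direction
of the gradient. p-values carry no multiple-testing correction; the
report records the number of tests run. Degenerate inputs (constant
scores) return F = 0, eta² = 0 rather than NaN.

## Synthetic cohorts

The generator draws, i.i.d. per respondent: a latent severity class
from fixed proportions; item scores as conditionally independent
categoricals given the class; correlate scores from class-conditional
normals with a common SD; demographics from class-conditional
categoricals. A `careless_rate` fraction of respondents then has its
items overwritten with uniform-random categories. Conditional
independence given class is the simplest generative structure a k-means
partition can recover; it deliberately omits item-level difficulty/
discrimination structure (no graded-response or Rasch models), local
item dependence, and longitudinal structure. Passing tests therefore
demonstrate that the pipeline recovers the latent structure *it
assumes*, not that real questionnaire data satisfy that structure.

Two recipes:

- `well_separated` — each class's items concentrated on one category
  (class totals ≈ 0.5 / 13 / 26 / 38.5); used wherever a test needs a
  known recoverable truth (recovery ARI, robustness floor).
- `paper_like` — overlapping profiles calibrated so expected class-mean
  totals are ≈ 1.5 / 8.0 / 11.0 / 19.0 with class proportions
  0.525 / 0.319 / 0.087 / 0.069 and 4.6% careless contamination — the
  severity gradient, imbalance and contamination level typical of a
  large general school sample. Item profiles are identical across the
  13 items within a class; per-item variation would not change any
  tested property and would add 156 free parameters. Correlate means
  (e.g. anxiety analogue 38/50/57/64, SD 10) were set so that
  eta-squared computed on the *derived* severity labels lands in the
  0.2–0.35 band plausible for real screening correlates — class overlap
  attenuates label-conditional effect sizes relative to
  truth-conditional ones, and the calibration accounts for that.
  Demographic class-conditional probabilities encode weak gradients
  (e.g. female proportion 0.48 → 0.60 across severity) of the direction
  and size reported in school epidemiology.

## Problem sizes and numerical choices

Default analysis scale is n = 8,000 respondents, 10-fold CV, and 200
robustness replicates; the full pipeline at that scale runs in well
under a minute on one CPU, and all package defaults are chosen to be
the sensible scientific defaults at that scale. Exact center-equality
convergence is used rather than an SSE tolerance because item data are
small integers and centroids are exact rational means — float equality
is reached quickly and reproducibly (typically 20–40 iterations at
n = 8,000). Seeds: every stochastic routine takes an explicit seed; the
pipeline spawns per-stage seeds from one master seed via
`numpy.random.SeedSequence`, so one integer reproduces the entire
report bundle byte-for-byte.

## Known limitations

- k is fixed by design to the number of norm levels; no silhouette or
  elbow selection, and no alternative clusterers.
- The IQR screen on totals cannot detect careless responders whose
  random totals fall inside the fences (most of them, at 13 items);
  detecting them needs pattern-based indices, which are out of scope.
- On overlapping cohorts the two middle clusters may sit close together
  in total score (their separation lives in the item profile, not the
  total); the severity ordering remains well defined but *Mild* vs
  *Moderate* membership is the least stable part of the solution — the
  resampling ARI quantifies exactly this.
- Label-conditional effect sizes (kappa, eta²) on synthetic cohorts
  characterize the generator as much as the method; they are structural
  checks, not claims about any real population.
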