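# depclust

Norm-free severity classification for questionnaire screening data, with
a complete evaluation harness comparing it to fixed-cutoff norms.

## The problem

Large-scale depression screening with self-report scales (here the
13-item short-form Beck Depression Inventory, BDI-13: 13 items scored
0–3, total 0–39) traditionally assigns severity by fixed total-score
cutoffs — e.g. 0–4 *None*, 5–7 *Mild*, 8–15 *Moderate*, 16–39 *Severe* —
established on a reference population decades ago. Such norms age badly
and transfer poorly across populations, and re-norming studies are rare
and expensive. `depclust` instead derives the severity levels from the
sample at hand, with no labels and no tuning, and provides the
statistical machinery to judge whether the result is trustworthy. It is
aimed at researchers and practitioners running questionnaire screening
programs (schools, clinics, epidemiological surveys).

## The method

Respondents are clustered in raw item space (each of the m items is one
feature) by k-means with k fixed to the number of norm levels (k = 4).
The usual random initialization is replaced by a deterministic
**zero-anchored max–min (farthest-point) seeding**:

1. c₁ = **0** — the all-zero "no symptoms" vector, whether or not any
   respondent attained it;
2. c₂ = argmaxₓ ‖x − c₁‖₂ — the respondent farthest from no-symptoms;
3. each further center is the respondent maximizing its minimum
   Euclidean distance to the centers already chosen, until k centers
   exist.

Lloyd iterations (nearest-center assignment, centroid recomputation)
then run until no center changes, capped at 100 iterations; ties break
to the lowest index, so the whole fit is deterministic. Clusters are
mapped to ordered severity levels by ascending center total score
(the sum of a center's coordinates).

The evaluation harness mirrors how such a data-driven classification
should be audited:

- **robustness** — re-derive the clustering on random 70% subsamples,
  extend to the held-out 30% with a linear discriminant (LDA), and score
  the full-sample labeling against the reference clustering with the
  adjusted Rand index (ARI), repeated many times;
- **correspondence** — cross-tabulation and unweighted Cohen's kappa
  against the original cutoffs and against ±1-point shifted variants;
- **model performance** — stratified 10-fold cross-validated LDA
  accuracy, macro one-vs-rest AUC and per-class sensitivity, with and
  without random under-sampling to the smallest class;
- **convergent validity** — chi-squared association with demographic
  variables and one-way-ANOVA eta-squared against related scales
  (anxiety, perceived stress, insomnia, stressful life events).

Because no respondent-level cohort is distributed, the package ships a
synthetic-data generator (`depclust.synthgen`) producing cohorts with a
latent 4-class severity mixture over the 13 ordinal items, careless-
responder contamination, severity-graded correlate scales and weakly
associated demographics.

## Worked example

```bash
depclust simulate --separation paper_like --n 8000 --seed 1 --out cohort.csv
depclust cluster cohort.csv --out labeled.csv
# converged=True after 33 iterations; center totals: 1.71, 9.10, 9.16, 19.46
depclust classify-norm labeled.csv --out labeled.csv
depclust compare labeled.csv --col-a severity_level --col-b severity_norm
```

which prints the clustering-vs-norm cross-tabulation and its agreement:

```
|          |   None |   Mild |   Moderate |   Severe |   Total |
|:---------|-------:|-------:|-----------:|---------:|--------:|
| None     |   4145 |    239 |          0 |        0 |    4384 |
| Mild     |     11 |    335 |        755 |        2 |    1103 |
| Moderate |      0 |    483 |       1095 |        0 |    1578 |
| Severe   |      0 |      0 |         80 |      855 |     935 |
| Total    |   4156 |   1057 |       1930 |      857 |    8000 |
kappa = 0.692
ARI   = 0.782
```

Center totals 1.71 / 9.10 / 9.16 / 19.46 are the severity anchors the
data itself produced; kappa 0.692 says the norm-free levels agree
substantially — but not perfectly — with the decades-old cutoffs, and
the table shows where they part ways (the norm's *Moderate* band is
split between data-driven *Mild* and *Moderate*). Resampling stability:

```bash
depclust robustness cohort.csv --reps 200 --seed 1
# ARI mean 0.841, SD 0.039 over 200 reps (0 failed)
```

The full pipeline (filter → cluster → norms → agreement → CV →
robustness → validity) runs from one command and one master seed:

```bash
depclust run-all --synthetic paper_like --n 8000 --reps 200 --seed 1 \
    --outdir report/
```

and writes per-stage CSV/JSON artifacts plus `summary.json` /
`summary.md`. Real data enter through `run-all --input-csv` or
`depclust.read_survey` (columns `id`, `item_1..item_13`, optional
demographic/correlate columns).

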