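# crlmsig

Prognostic gene-signature discovery and validation for colorectal liver
metastasis (CRLM) resection cohorts.

## The problem

About 60–80% of patients relapse after a curative resection of
colorectal liver metastases. A gene-expression signature that flags the
patients destined to recur early would let clinicians target adjuvant
therapy; published clinical risk scores (Fong, Nordlinger, Iwatsuki,
Mayo/Zakaria, Basingstoke) fill that role today using clinicopathological
factors only. `crlmsig` implements, as a tested and reusable library, the
full machinery such a study needs — and, just as importantly, the
machinery needed to show when a signature is *not* there:

- **Signature discovery by multiple random sampling.** Training patients
  are dichotomized by disease-free survival (DFS; high risk = recurrence
  within 1 year, or the stricter ≤ 6 months vs > 2 years rule). In each
  of 1000 iterations a stratified 2/3 subsample is drawn; every gene is
  ranked by three metrics — the signal-to-noise ratio
  (μ_high − μ_low)/(σ_high + σ_low), the Welch *t* statistic, and the
  Wald *z* of a univariate Cox fit — and the three ranks are averaged.
  The top-75 genes feed a nearest-mean (centroid) classifier scored as
  corr(x, c_low) − corr(x, c_high), which predicts the held-out 1/3.
  Held-out scores pooled over all iterations give one **combined AUC**:
  ≈ 0.5 means the expression carries no prognostic information, however
  good any single training fit looks.
- **Forward selection** along the iteration-averaged ranking, keeping
  the signature size with the best leave-one-out accuracy, then
  **independent validation**: Kaplan–Meier curves, Mantel–Cox log-rank
  test and a Cox hazard ratio comparing DFS between the predicted
  classes of never-seen patients.
- **Survival statistics** (lifelines-backed): KM, log-rank, univariate /
  multivariate Cox with Efron ties, Schoenfeld log-rank power,
  Benjamini–Hochberg FDR, baseline-table comparisons (Fisher exact /
  Mann–Whitney) and dichotomous classification metrics.
- **Clinical risk scores** as editable YAML rubrics with the published
  dichotomization thresholds (Fong ≥ 3, Nordlinger ≥ 4, Iwatsuki ≥ 3,
  Mayo ≥ 2, Basingstoke ≥ 10); missing inputs score 0 points and clear a
  completeness flag.
- **Differential expression** between neoadjuvant-treated and untreated
  patients: per-gene fixed-effects ANOVA (array + dye + treatment) on
  channel-level intensities, tested with a hybrid-denominator F
  statistic against a globally permuted residual null.
- **Two-channel preprocessing**: print-tip loess normalization, exact
  dye-swap signal/bias decomposition, and the sample-QC exclusion
  cascade (RIN/yield → amplification → labelling).
- **A synthetic cohort generator** that emulates the study structure all
  of this assumes — ~119 patients from two centres, ~20k genes of log2
  ratios, censored DFS, an optional planted signature, a
  neoadjuvant-treatment expression shift confounded with risk, and QC
  annotations — so every stage is testable without patient data.

## Worked example

`examples/03_discover_signature.py` plants a 50-gene signature (2 log2
units between patients destined for early vs late recurrence) in a
119-patient cohort, discovers it on a 75-patient training split and
validates on the remaining 44:

```
training set: 75 patients, labels: {'high': 36, 'low': 27, 'unlabelable': 12}
combined held-out AUC over iterations: 1.000 (95% CI 1.000-1.000); well above 0.5 means real predictive structure
planted genes inside the averaged top-75: 50/50
forward selection chose 3 genes (training LOOCV accuracy 1.00)
validation: log-rank p = 1.08e-06, HR (low vs high) = 0.05 (0.01-0.24)
```

All 50 planted genes are recovered, and the predicted-low-risk
validation patients recur far later (hazard ratio 0.05). On a null
cohort the same pipeline returns a combined AUC near 0.5 and a
non-significant validation log-rank — the behaviour that distinguishes
honest resampling-based discovery from training-set overfitting.

The other examples cover cohort generation and baseline margins (01),
two-channel normalization and the QC cascade (02), clinical risk scores
(04), and permutation-ANOVA differential expression (05). Each prints
what it computes and what the numbers mean.

A thin CLI wraps the same functions:

```bash
crlmsig synth --config cohort.yaml --out data/ --seed 1
crlmsig discover --expr data/expression.tsv --clinical data/clinical.csv \
    --config discovery.yaml --seed 1 --out run/
crlmsig scores --clinical data/clinical.csv --out scores.csv
```

## Layout

```
src/crlmsig/      library (cohort, synthdata, preprocess, discovery,
                  survival, clinscores, diffexp, pipeline, cli)
src/crlmsig/rubrics/  the five clinical-score YAML rubrics
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, parameter choices, limitations
```
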