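# Methods

This note documents the models implemented by `crlmsig`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Risk stratification

Patients are dichotomized on disease-free survival (DFS, months from
resection to first radiological recurrence; censored at death or last
follow-up). Under the default rule a patient is **high risk** iff a
recurrence was observed at DFS ≤ 12 months and **low risk** iff DFS > 12
months (event or censoring beyond that point proves recurrence-free
survival past the threshold). Patients censored at or before 12 months
without an event are **unlabelable**: they are excluded from signature
discovery but retained for survival validation, where the model predicts
a class for every sample. The stricter variant labels high ≤ 6 months
and low > 24 months. Boundary times count as high (≤, >).

## Multiple-sampling discovery

Defaults: 1000 iterations, stratified subsampling of 2/3 of each class
(rounded, at least 2 and at most class-size − 1 per class), top
`k = 75` genes, three ranking metrics. Degenerate draws (a class with
fewer than 2 training samples, no held-out sample, or no event in the
draw) are redrawn and logged, never silently accepted.

Per-gene metrics on a draw:

- **snr** — Golub signal-to-noise (μ_h − μ_l)/(s_h + s_l) with
  sample (ddof = 1) standard deviations;
- **tstat** — Welch two-sample *t*;
- **coxhr** — |Wald *z*| of a univariate Cox fit on continuous
  expression. |z| rather than the raw hazard ratio so protective and
  adverse genes rank symmetrically.

Genes are ranked 1..G per metric by descending |score| (ties broken by
gene order; zero-variance genes get NaN scores and the worst ranks, with
a warning). The **combined rank** is the mean of the three metric ranks;
the top-k genes by combined rank form the iteration's signature, and
combined ranks are averaged over iterations into the final ranking.

The per-gene Cox ranker is an in-package vectorized Newton solver
(Breslow tie handling, per-gene standardization, clipped steps, 3
iterations inside the sampling loop, 6 in the public `rank_genes`). It
matches lifelines' Wald z to ~1e-4 on untied data in the tests;
survival-module Cox fits (`cox_fit`) use lifelines with Efron ties.

### Nearest-mean classifier

Signature genes are standardized by the training mean and SD; class
centroids are the per-class means of standardized training samples. The
continuous score of a sample is corr(x, c_low) − corr(x, c_high)
(Pearson across the signature genes); score ≤ 0 predicts high risk — the
tie goes to high, the conservative direction for a screening test. For a
single-gene signature the correlation is undefined and the signed
standardized distance |x − c_high| − |x − c_low| is used (logged).
Because Pearson correlation centers across genes, a signature whose
genes all shift in the same direction carries no correlation signal;
informative signatures need an expression *pattern* (mixed directions),
which the synthetic generator plants accordingly.

Held-out scores are pooled as **risk scores** (the negated raw score, so
higher = more high-risk-like) and summarized as one combined AUC:
P(score_high > score_low) with ties counted 1/2, computed by rank sums.
The 95% CI is a stratified bootstrap (default 2000 resamples) at the
*patient* level — each patient's pooled scores are kept together — which
is materially wider than an observation-level bootstrap, because pooled
scores of one patient are strongly correlated across iterations.

### Known behaviour of the null combined AUC

Under a null (expression independent of outcome) the pooled AUC is
unbiased (≈ 0.5 on average) but has a seed-to-seed standard deviation of
about 0.066 at 75 patients × 2,000 genes: the top-75 selection is stable
across overlapping 2/3 draws, so each patient's pooled score is nearly
deterministic and the AUC retains patient-level sampling noise
(≈ sqrt[(1/n_h + 1/n_l)/12]) that pooling iterations cannot remove. At
much larger gene counts the selection tail destabilizes and an
*anti-learning* bias appears (pooled null AUC systematically below 0.5;
≈ 0.45 at 8,000 and ≈ 0.41 at 20,000 genes in our runs), the classic
consequence of feature selection under subsampling without replacement:
training and held-out class means are negatively coupled given the
finite cohort. Consumers of the combined AUC should therefore judge it
against a seed-resampled null distribution, not against a fixed narrow
band. `scripts/acceptance.py` pools held-out scores over five
independent null cohorts to report a tighter estimate of the null
operating point.

### Forward selection and validation

For sizes 1..75 along the averaged ranking, leave-one-out accuracy of
the nearest-mean classifier on the labeled training samples is computed
(standardization and centroids refit per left-out sample; prefix-sum
correlations give all sizes in one pass). The smallest size attaining
the maximum accuracy is selected, and the final model is refit on the
full labeled training set. Validation enforces training/validation id
disjointness (hard error), predicts every validation sample, and
compares DFS between predicted classes with the Mantel–Cox log-rank test
plus a companion Cox hazard ratio and Wald CI.

## Survival module conventions

- Kaplan–Meier, log-rank and Cox go through lifelines; Cox ties are
  handled by Efron's method (the stronger default; the modelled
  workflow does not specify one). Times are continuous months; exact
  ties are allowed.
- `cox_fit(mode="auto")` screens covariates univariately and enters
  those with p < 0.1 into the joint model.
- Log-rank power uses the Schoenfeld approximation
  Φ(|ln HR|·sqrt(d·p·(1−p)) − z_{1−α/2}); the tests check it against a
  10,000-replicate simulation.
- Fisher's exact two-sided rule sums all tables whose point
  hypergeometric probability does not exceed the observed one (the
  dominant software convention; verified against exhaustive enumeration
  in the tests). Baseline tables with more than two observed levels fall
  back to an uncorrected chi-square, and a `categorical_test="chi2"`
  option applies the uncorrected chi-square to 2×2 tables as well —
  published baseline tables are sometimes computed that way even when a
  footnote names Fisher.
- Benjamini–Hochberg adjustment is statsmodels' step-up implementation.

## Clinical risk scores

Each rubric is a YAML file of criteria (field, comparator, cut-off,
points) plus a high-risk threshold. Thresholds are the published
dichotomizations (Fong ≥ 3, Nordlinger ≥ 4, Iwatsuki grade ≥ 3, Mayo ≥ 2,
Basingstoke ≥ 10). Component criteria are transcribed from the scores'
original publications with two caveats marked in the files themselves:
fields not carried on `ClinicalRecord` are approximated (Nordlinger's
serosal invasion → stage group ≥ 2) or structurally disabled
(Basingstoke's extrahepatic-disease criterion, since the emulated cohort
excludes extrahepatic disease), and the Iwatsuki total includes a
constant baseline point so it lives on the published grade scale
(grade = 1 + number of factors). Missing inputs contribute 0 points and
clear the completeness flag — with hepatoduodenal nodal status
unrecorded, the Mayo score can never exceed 2, mirroring real cohorts.
Rubrics can only under-call risk on incomplete records.

## Differential expression

Observations are channel-level log2 intensities of a common-reference
dye-swap design; the per-gene fixed-effects model is
`y = μ + array + dye + treatment`, with treatment ∈ {reference, treated,
untreated}. The treated-vs-untreated term (1 df) is tested by

F2 = (SS_treat / df1) / (w·MSE_pooled + (1 − w)·MSE_gene), w = 0.5,

a hybrid denominator that shrinks the per-gene residual mean square
toward the across-genes pooled one (w configurable). The null is built
by permuting reduced-model residuals **globally** — one shared
permutation of residual rows per shuffle, preserving inter-gene
correlation of the null statistics (a per-gene independent shuffle is
available but off by default); p = (1 + #{F* ≥ F})/(1 + n_perm), never
zero and finite-sample valid. Raw (not studentized) residuals are
permuted. Aliasing of the treatment term with the array/dye layout is
detected by a rank check and is a hard error. The fixed-effects model
puts biological replicate variance into the residual; the synthetic
design generator draws iid residuals (its `sample_effect` is zero), so
the calibration shown by the tests covers the model's own assumption,
not the extra-Poisson biological variance of real cohorts.

## Two-channel preprocessing

M = log2(Cy5/Cy3) is kept in dye orientation; A is the mean log2
intensity. Print-tip loess fits a degree-1 locally weighted regression
of M on A per print-tip group (tricube weights, span 0.4, 3 robustness
iterations — statsmodels' lowess) and subtracts it; groups with fewer
than 20 usable spots fall back to a global fit with a warning. Control
spots are excluded from fitting and output; duplicate spots per gene are
averaged after normalization. Loess absorbs any constant dye offset and,
on sparse arrays, a small share of biological signal (the tests quantify
both). Dye-swap merging uses the exact sign-flip decomposition: with
M₁ = s + b and M₂ = −s + b across the swap, bias b = (M₁ + M₂)/2 and
signal s = ±(M₁ − M₂)/2. The QC cascade applies RIN/yield →
amplification → labelling gates in order (RIN ≥ 6, cRNA ≥ 2000 ng,
fragment ≥ 500 nt, Cy incorporation 1.5–3%), attributing each exclusion
to the first failing stage; whether real exclusion groups are disjoint
is unknowable from totals alone, so the cascade order is this package's
convention.

## Synthetic cohorts

`CohortSpec` defaults describe the emulated study: 119 patients, 20,000
genes, ~60% one-year event rate, 875 treatment-shifted genes, unit
(log2) residual noise. Each patient carries a latent risk r ~ N(0,1);
event times are exponential with log-rate `log λ0 + r` (+ optionally
0.9 per Fong point when clinical factors drive the hazard), where λ0 is
solved by root-finding so the realized cohort's expected one-year event
fraction equals `event_rate_1yr`. Censoring times are exponential with a
rate solved so E[μ/(μ + λ)] equals `censor_rate` (default 0.25 — the
real censoring fraction is not derivable from published summaries, so
this is a package choice consistent with a ~27-month mean follow-up);
exponential censoring was chosen over uniform-plus-administrative
because the expected censored fraction then has a closed form that can
be calibrated exactly against the realized hazards.

Planted signature genes shift by `signature_effect` log2 units (random
per-gene sign) between the **destiny classes** — true event time within
one year versus later — so the nominal effect is exactly the
between-risk-class contrast, and realized high/low labels are subsets of
the destiny classes. Neoadjuvant treatment probability rises with r
(logistic, slope 0.8 around a 54% base rate), reproducing the
overrepresentation of treated patients among early recurrences; treated
patients' expression shifts by `treatment_effect_size` in the (by
default disjoint) treatment gene set. Centre B adds a per-gene N(0,
`center_batch_sd`) offset. Clinical covariates are drawn to match the
emulated cohort's published marginals (sex, age, site, differentiation,
nodal status, synchronicity, metastasis count and size, CEA); they are
mutually independent except where noted, which real cohorts are not.
Hepatoduodenal nodal status is always "unknown", as in the emulated
study. All randomness flows from the single integer seed through one
generator; identical specs give byte-identical cohorts.

What the generator does **not** emulate: probe-level intensity
distributions, gene–gene correlation (genes are independent given the
planted structure), non-proportional hazards, informative censoring, and
covariate collinearity. Passing tests therefore demonstrate correctness
of the machinery under the stated model, not performance on real
microarray data.

## Problem sizes used by the test and acceptance runs

Chosen to exercise the full procedures at desk scale: discovery runs use
2,000 genes and 75 training patients (1000 iterations for the null
calibration, 250 for planted-recovery runs, whose signal makes longer
rank averaging unnecessary); the log-rank type-I calibration uses 2,000
null cohorts of 80 patients × 120 genes; the permutation-F calibration
uses 20,000 genes × 48 channel observations with 999 shared shuffles.
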