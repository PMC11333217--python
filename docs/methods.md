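# Methods

## Scope

`gdmprs` implements a complete small-panel polygenic-risk-score (PRS)
analysis for gestational diabetes mellitus (GDM): genotype-dosage quality
control, weighted scoring, association modelling, and incremental-value
evaluation of adding the PRS to a traditional-risk-factor model. Because no
patient-level data ship with the package, a first-class synthetic cohort
generator provides inputs whose generative parameters are known exactly, so
every estimator can be validated by parameter recovery.

## The synthetic cohort generator

### Covariates

Eleven baseline covariates are drawn from stated marginals: age and
pre-pregnancy BMI (PBMI) as truncated normals, the rest as multinomials.
Defaults are the control-group marginals of a 2,258-woman antenatal cohort
(age 28.99 ± 3.54 y, PBMI 21.00 ± 2.82 kg/m², gravidity 62/21/17%,
parity ≥2 18%, employed 62%, etc.). Truncation bounds (age 16–50 y, PBMI
14–45 kg/m²) are plausibility limits chosen by the package, not data-derived;
the truncated normal's location is re-solved so the *realized* mean equals
the configured mean (plain truncation would shift the PBMI mean by ~+0.05).
The realized SD is the scale parameter shrunk ~2% by truncation.

Covariates are generated independently — the source table states only
marginals — but a Gaussian-copula hook (`GeneratorConfig.copula`) accepts a
user correlation matrix over any subset of covariates for sensitivity work.

### The score

Two sources:

- `prs_source="normal"` draws the raw score directly from
  Normal(0.31, 0.08²), the control-group score distribution; this is the
  mode used for all parameter-recovery experiments.
- `prs_source="genotype"` simulates the five-variant panel under
  Hardy–Weinberg (genotype ~ Binomial(2, f)), degrades genotypes with
  Normal(0, 0.15) dosage noise clipped to [0, 2] plus 2% missingness
  (a stand-in for imputation from 0.06–0.1× coverage sequencing — the
  imputation algorithm itself is out of scope), mean-imputes, and scores
  with the panel weights.

The built-in panel lists five established GDM/T2D loci (MTNR1B, CDKAL1,
TCF7L2, CDKN2A/B, HKDC1 regions) but its weights (~0.05 per allele) and
effect-allele frequencies (~0.6) are **illustrative**: they are chosen so the
weighted dosage score has mean ≈ 0.31 and SD ≈ 0.08 (mean = Σ 2wf, variance
= Σ 2w²f(1−f)), and must be replaced with real GWAS summary statistics
before scoring real genotypes.

### Outcome

`logistic` mode (default): GDM ~ Bernoulli(expit(b0 + Σ βj xj)). The default
effect sizes are the log odds ratios of the multivariate analysis this
pipeline reproduces — PBMI 1.14 per kg/m², age 1.09 per year, employment
0.75, gravidity 2 vs 1 1.43 and ≥3 vs 1 1.36, parity ≥2 0.66, and PRS 19.68
per raw-score unit (≈1.27 per SD of 0.08). The intercept b0 is root-found
(Brent) on a ≥10⁵-subject Monte-Carlo pool drawn from dedicated calibration
streams so that the mean outcome probability hits the prevalence target
(default 283/2541 ≈ 11.1%); calibration error is ≤ 0.002 at the default pool
size, ≤ 0.004 at 10⁶. In quintile mode the linear predictor instead carries
within-cohort score-quintile indicator effects (defaults ln 1.26, 1.72,
1.81, 2.01 for Q2..Q5), targeting *unadjusted* quintile odds ratios.

OGTT glucose is linear in the linear predictor:
`measure = base + slope·lp + N(0, sd)` with positive slopes, so
corr(PRS, glucose) > 0 by construction. The link parameters are invented
(no published glucose model exists for this design); defaults give fasting
glucose ~4.0 ± 0.4 and plausible post-load values.

`ogtt_threshold` mode derives the label from the diagnostic cutoffs
(fasting ≥ 5.5, 1-h ≥ 10.0, 2-h ≥ 8.0 mmol/L) applied to the generated
glucose, so case/control status is exactly consistent with the cutoffs.
Prevalence is then controlled by the glucose baselines; a helper
(`calibrate_ogtt_shift`) solves a common per-measure shift (in noise-SD
units) to hit the target. The shift is opt-in so degenerate configurations
(baselines far below the cutoffs) honestly yield zero prevalence.

### Randomness

One root seed; every stage draws from a named child stream
(`SeedSequence(root, spawn_key=crc32(stage))`), so adding a stage never
perturbs earlier draws and identical configurations are byte-identical.

### What a green test does not establish

The generator emulates marginals, a correctly specified logistic model, and
independent covariates. Real cohorts have correlated covariates,
non-logistic risk, linkage between panel variants, ancestry structure, and
informative missingness — none of which are modelled. Parameter-recovery
results therefore validate the *estimators*, not the transportability of any
particular published effect size.

## Quality control

Sample level: kept iff depth ≥ 0.05× **and** mapping rate ≥ 0.90 (exclusion
is strict `<`, so boundary samples stay). Variant level (all strict
retention): MAF > 0.05 with MAF = min(m, 1−m), m = mean non-missing
dosage / 2 (the dosage mean uses all imputation information); exact
Hardy–Weinberg p > 1e-6; missing rate < 0.1. The HWE exact test needs
genotype counts, so dosages are rounded to hard calls (.5 rounds up) for the
test only — a documented choice, as no dosage-based exact test is standard.
The test is the two-sided conditional exact test: the p-value sums the
probabilities of all heterozygote counts no more likely than the observed
one given the allele counts; probabilities are computed in log space and
renormalized, and ties are included with a 1e-12 relative tolerance.
Post-QC missing dosages are mean-imputed so every subject receives a score.

## Scoring

Raw score = Σ weight × effect-allele dosage (readers re-orient VCF `DS`
values to the effect allele, replacing d by 2−d when the file's ALT is the
panel's other allele, and refuse sites matching neither orientation).
Standardization uses the population (1/n) SD, giving exactly unit variance;
at n ≈ 2,500 the 1/n vs 1/(n−1) choice is inconsequential. Quintiles are a
rank-based equal-count split (ties by stable input order, remainders to the
lowest quintiles: 2,541 → 509/508/508/508/508), not interpolated quantile
cutpoints — deterministic and invariant to monotone transforms of the score.

## Association models

Screening: equal-variance two-sample t-test for continuous covariates
(mirroring the classic SPSS output line; Welch is a scipy call away),
Pearson chi-square without continuity correction for categorical, switching
to Fisher's exact test for 2×2 tables with any expected count < 5 (the
Fisher fallback is 2×2-only; larger sparse tables keep the chi-square and
are flagged by their expected counts).

The multivariate model is maximum-likelihood logistic regression by
Newton–Raphson IRLS with step-halving; convergence at max |score| < 1e-8 or
relative log-likelihood change < 1e-10, cap 100 iterations. Gravidity
enters as two indicators (2 and ≥3 vs 1), parity as one (≥2 vs 1). The PRS
enters on its **raw** scale by default: a per-unit OR near 20 on a score
with SD 0.08 equals a per-SD OR near 1.27, which is the scale on which such
headline PRS odds ratios are coherent with a Q5-vs-Q1 OR near 2
(`prs_scale="z"` switches to per-SD). Inference is Wald: OR = exp(β), 95%
CI = exp(β ± 1.96·SE). Rank-deficient designs fail loudly naming the
collinear columns; |β| > 15 flags suspected separation. The fit is verified
against the 2×2 closed-form OR (ad/bc) and against statsmodels.

Quintile association fits the unadjusted four-indicator logistic model
(Q1 reference); `adjust=True` adds the traditional covariates. A quintile
with an empty case or control cell reports an undefined OR rather than a
diverged fit. PRS–glucose association is the Pearson correlation with the
two-sided t-test p, pairwise-complete.

## Model comparison

AUC is the Mann–Whitney statistic (ties count ½) with DeLong
structural-component variance; paired model comparison uses the DeLong
covariance z-test. IDI = difference in discrimination slopes; NRI is the
category-free (continuous) variant by default — no clinical risk categories
are established for GDM — with the categorical variant available given
thresholds. `nri_overall = nri_event + nri_nonevent` holds to machine
precision by construction.

Confidence intervals for the incremental metrics come from a stratified
subject-level bootstrap. Two flavours exist deliberately:

- `idi()` / `nri()` bootstrap fixed probability vectors (the op-level
  contract; appropriate when the models are external);
- `incremental_value()` **refits both nested models in every bootstrap
  draw**. This is what the headline report uses: holding the fitted
  probabilities fixed ignores model-estimation noise and measured only
  ~0.76 coverage of the population IDI at n = 2,541, while the refit
  bootstrap measures ~0.95.

Cross-validation: outcome-stratified k folds (default 5). Within each
*training* fold only, controls are randomly under-sampled to 1:1 with cases
(configurable ratio); test folds keep natural prevalence, otherwise the
reported metrics would be distorted. Metrics are refit-per-fold and averaged;
the full-data fits provide the headline multivariate odds ratios and the
bootstrap IDI/NRI — the report carries both, since published analyses of
this kind are often ambiguous about which is printed.

## Numerical choices and degenerate inputs

- Logistic start: zero coefficients with the intercept at logit(ȳ);
  likelihood is evaluated via `-logaddexp(0, ∓lp)` for stability.
- Intercept calibration brackets [−40, 10] and errors if the target is not
  bracketed; degenerate covariate SD = 0 yields a point mass.
- Glucose is floored at 0.1 mmol/L (positivity invariant).
- Monomorphic variants get HWE p = 1 (single attainable configuration);
  all-missing variants fail the missingness filter with NaN metrics.
- Zero-variance scores refuse standardization; n < 5 refuses quintiles.
- Bootstrap CIs are percentile, 1,000 draws by default; p-values for
  bootstrap estimates use the normal approximation value/SD(draws).

## Known limitations

- Only 2×2 Fisher fallback (see above); no exact r×c network algorithm.
- No LD between panel variants; no strand-ambiguous (A/T, C/G) site
  resolution beyond erroring on mismatched allele pairs.
- Finite-sample MLE bias: replicate geometric-mean odds ratios at
  n = 2,541 recover wide-CI terms (the raw-scale PRS) only to within a few
  per cent; no Firth correction is implemented.
- Calibration modelling (Hosmer–Lemeshow, recalibration curves) and
  decision-curve analysis are out of scope.
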