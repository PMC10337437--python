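# Methods

## The analysis in brief

`carecascade` implements a cascade-of-care analysis for type 2 diabetes
(T2D) survey microdata, of the kind used to audit how a health system loses
patients along the care continuum. A cross-sectional sample of adults aged
40 and over is classified into six ordered bars:

1. **prevalence** — meets the T2D case definition;
2. **tested** — blood glucose tested within the last 3 years;
3. **diagnosed** — tested *and* ever told by a health worker they have T2D;
4. **in care** — diagnosed *and* received care in the past 12 months;
5. **in treatment** — in care *and* taking antidiabetic drugs or insulin
   (past 2 weeks);
6. **under control** — in treatment *and* HbA1c < 8%.

The case definition is `(FBG >= 126 mg/dL and HbA1c >= 6.5%)` with both
measurements present, **or** reported use of antidiabetic drugs/insulin
irrespective of biomarkers. Stages are *nested conjunctions*: a respondent
who reports a diagnosis but no test within 3 years does not count as
diagnosed. All percentages use the **fixed denominator** (the prevalence
bar), so successive drops show cumulative leakage; the under-control bar is
a percentage of all cases, not of the treated. The engine also emits the
raw (non-nested) flag counts as diagnostics, and a stage-conditional
percentage mode for exploratory display.

A participant is **undiagnosed** when they meet the case definition but
were never told of the condition. Among cases, undiagnosed status is
cross-tabulated against age group, sex, marital status, education, wealth
quintile and care-initiative setting (Pearson chi-square without continuity
correction; an exact/permutation option exists for sparse tables), and
modelled by multiple logistic regression with block-wise backward
elimination.

## Wealth index

Socioeconomic position follows the Demographic and Health Surveys (DHS)
asset-index construction: the score is the first principal component of the
standardized 20-item household asset matrix. Constant indicators are
dropped with a warning; the leading eigenvector of the correlation matrix
defines loadings; the score is oriented so households owning more assets
score positive (tie on orientation falls back to the sign of the loading
sum). Quintiles (1 = poorest) partition the score ranking into five
near-equal groups, ties broken by household identifier so the assignment is
invariant to row order. Quintiles are computed at household level relative
to the analysis sample (not national cut-points, which the survey context
does not provide) and joined to individuals.

## Undiagnosed-status model

The outcome is undiagnosed status among cases. Covariates enter as
categorical blocks with fixed reference levels: age ≥60, female, richest
quintile, hospital-based setting, married, secondary-or-higher education.
The initial model contains *all* blocks regardless of bivariate
significance. Backward elimination then repeatedly removes the block with
the largest p-value until every remaining block has p < α (default 0.05).
Block p-values use the likelihood-ratio test by default (a Wald block test
is available); whole blocks are removed, never single levels, so
non-significant levels inside a significant block are retained — matching
how such tables are conventionally reported. Ties in p are broken by the
fixed covariate order (age, sex, marital, education, wealth, setting), and
the elimination trace is recorded, making the procedure fully
deterministic.

Fitting is a binomial GLM by IRLS (log-likelihood tolerance 1e-8, 200
iterations). Adjusted odds ratios are `exp(coef)` with Wald 95% intervals
`exp(coef ± 1.96·SE)`. Separation is checked only on the *final* model
(|coef| > 15, SE > 100 or non-finite), because likelihood-ratio
comparisons remain valid while a level's MLE diverges; intermediate
elimination fits therefore tolerate a separated sparse level, which is
usually eliminated or, if retained, raises a `SeparationError` naming the
level. Note that when a sparse level separates, the block's LRT is
*inflated*, so separation tends to keep the block in — callers running
replicate studies should treat such replicates as failures, as the
acceptance script does.

Known limitation: with ~14 parameters per ~550 cases, the unpenalized MLE
has the usual small-sample away-from-null bias (a planted odds ratio of 3.2
is recovered with geometric mean ≈ 3.3 across replicates), so Wald CI
coverage sits slightly below nominal (≈92% rather than 95% in the
parameter-recovery study). Firth-penalized or profile-likelihood intervals
are out of scope.

## Synthetic-data generator

`generate_population` emulates a five-setting household survey of adults
aged ≥40 (one participant per household, the settings being operational
districts hosting different T2D care initiatives). Defaults are calibrated
to the surveyed conditions: prevalence 560/5072 ≈ 11.04%, and stage
retention probabilities equal to the observed cascade transition ratios
(tested|case 353/560, diagnosed|tested 309/353, care|diagnosed 279/309,
treated|care 273/279, controlled|treated 60/273); the advice-bundle rate
among the treated defaults to 130/273. The factorization is deliberately
minimal: covariates → case status → a nested Markov chain of stage flags,
with *diagnosis* the only covariate-dependent transition (this is the
quantity the association analysis targets).

- **Covariates.** Age group (38/30/32% across 40-49/50-59/≥60), sex (64%
  female — household surveys of this kind over-sample members present at
  home), education (30/55/15%), marital status (70/27/3%). These are
  plausible for a rural Cambodian population aged ≥40; the source survey
  prints covariate distributions only among cases, so the population-level
  mix is the package's own choice.
- **Wealth.** A latent standard-normal wealth factor drives 20 binary asset
  items through a two-parameter item-response model (slope 2, difficulties
  evenly spaced on [-2, 2]). The generator's true quintile is the sample
  quintile of the latent factor; the analysis pipeline re-estimates
  quintiles from the assets by PCA, so wealth carries realistic (mild)
  misclassification.
- **Planted effects.** The probability of being *diagnosed* (told) given
  case status has a logistic linear predictor with per-level log-odds
  offsets raising the odds of remaining undiagnosed. The defaults are the
  adjusted odds ratios the survey analysis reported (age 40-49: 3.2, age
  50-59: 1.2, male: 1.7, poorest quintile: 2.3, and the four non-hospital
  settings: 1.9/1.9/2.1/1.2). To keep the marginal stage-retention
  calibration exact in the presence of planted effects, the intercept is
  re-centred per realized population (Brent root-finding so the mean
  diagnosed probability among cases equals
  `p_tested × p_diagnosed_given_tested`). Testing among the never-told is
  then drawn at the residual rate that preserves the marginal tested
  proportion exactly.
- **Biomarkers.** Untreated cases draw FBG/HbA1c from truncated normals
  above the diagnostic thresholds; treated-and-controlled cases draw
  HbA1c < 8 (possibly < 6.5 — the drug flag classifies them); treated but
  uncontrolled cases draw HbA1c ≥ 8; non-cases draw below threshold.
  Missing biomarkers are generated only on request (default 0%), and only
  for records whose classification does not depend on the biomarker clause.
- **Determinism.** One `numpy` Generator seeded from `GeneratorParams.seed`
  drives everything; identical parameters give byte-identical output.

What the generator does **not** emulate: survey design weights and
clustering (the source analysis is unweighted; households appear only as
identifiers), within-household correlation, biomarker measurement error
correlated with care-seeking, non-response, or covariate-dependent
retention beyond the diagnosis stage. Passing tests on these data therefore
demonstrate the correctness and calibration of the *method*, not robustness
to those real-data complications.

## Deterministic fixture

`reconstruct_fixture` inverts published summary counts into an
individual-level dataset, seed-free and idempotent. Allocation is a greedy
block fill in a fixed covariate order (age, sex, marital, education,
wealth, setting) separately within the diagnosed and undiagnosed case
groups, with diagnosing provider filled within setting blocks and cascade
stages assigned as nested prefixes. Only margins actually present in the
spec are guaranteed — unprinted higher-order joints (e.g. per-setting stage
counts) are not. Biomarkers are representative in-range values consistent
with each record's stage (FBG 150 / HbA1c 9.0 for uncontrolled cases,
HbA1c 7.5 for controlled, FBG 150 / HbA1c 6.0 for raised-glucose
non-cases, 95 / 5.5 otherwise). Asset vectors are a nested ownership
pattern (0/5/10/15/20 items by quintile) sized so the PCA quintile
assignment reproduces the wealth table exactly. Internal consistency
(monotone bars, matching margins, provider sums) is validated up front with
errors naming the violated constraint.

Because covariates are filled in blocks over the same orderings, they are
strongly collinear in the fixture; the full logistic model on the fixture
is quasi-separated, and the pipeline records the regression as skipped.
This is expected: printed margins alone cannot reproduce the survey's
adjusted odds ratios, and the fixture makes no attempt to.

## Numerical and design choices

- Pearson chi-square without continuity correction reproduces the printed
  bivariate p-values (sex .03; marital .53, education .53, wealth .45,
  setting .22); a warning is emitted when any expected count is below 5.
- The sparse-table option uses Fisher's exact test for 2×2 tables and a
  seeded Monte-Carlo permutation null of the Pearson statistic (conditional
  on both margins, Patefield sampling, add-one p-value) for larger tables.
- Percentages are displayed to one decimal; counts are exact integers.
- Zero-case inputs produce a degenerate all-zero cascade (percent defined
  as 0 and flagged) rather than an error; downstream association stages are
  skipped with a logged reason.
- Pipeline outputs are a pure function of (config, seed, input bytes); the
  manifest records the seed, input checksum and per-artifact SHA-256.

## Problem sizes used in the checks

The replicate studies use 200 replicates of n = 5000 (≈550 cases each) for
parameter recovery and null elimination, and 200 seeds of n = 100,000 for
stage-retention calibration (each mean bar proportion within 3 Monte-Carlo
SEs of the analytic product of retention probabilities). The oracle
comparisons use 10,000 simulated records against a per-record brute-force
filter, and 20,000-draw permutation nulls on seeded 3×2 tables with totals
250–500 — small enough to be exactly resampled, large enough that the
asymptotic chi-square approximation is valid (at total 30 with all expected
counts ≥ 5 the permutation distribution is so discrete that no continuous
approximation can track it; see the table-size note in the test helper).
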