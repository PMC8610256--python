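# Methods

`parrisk` implements the external-validation workflow for a points-based
hospital readmission risk score — the PAR-Risk Score, a 12-item model for
potentially avoidable readmissions (PAR) within 30 days of discharge — as a
reusable pipeline over EHR-style tables, together with a synthetic cohort
generator that reproduces the statistical structure the analysis assumes.

## The score and its predictors

The raw score of a patient is the sum of integer point weights over the
predictors present at discharge:

* length of stay > 4 days (strict on exactly 96 h; the inclusion rule
  "at least 48 hours" is inclusive on exactly 48 h);
* an admission in the previous six months, fixed here as any prior discharge
  in `[admission − 183 d, admission)` with the window start inclusive — the
  source analysis gives no day count, so 183 days (≈ 6 × 30.5) is the
  package's choice;
* eight ICD-10-coded comorbidities (anaemia, hypertension, heart failure,
  acute myocardial infarction, chronic ischaemic heart disease, diabetes
  with organ damage, cancer, metastatic carcinoma), matched by uppercasing,
  dot-stripping and prefix comparison against a configurable map;
* opioid dispensing during the stay (ATC `N02A` and sub-levels, dispense
  time inside `[admission, discharge]`, both ends inclusive);
* hyperkalaemia: any serum potassium > 5.5 mmol/L (strict) among the draws
  in the final seven in-stay days, carrying the most recent earlier in-stay
  value forward when the window is empty. A patient with no potassium value
  at all is assumed normokalaemic (values treated as not missing at random)
  and flagged `potassium_missing`.

Risk groups are score bands: low `< c1`, medium `c1..c2` inclusive, high
`> c2`. The original cut pair is (3, 10); the cohort-adapted pair is
recomputed from tertiles of the observed score distribution.

**Synthetic stand-ins.** Two bundled data files are stand-ins, marked as such
in their filenames and docstrings. The per-item point weights
(`par_risk_score_synthetic.yaml`) pin the one published weight (anaemia = 2)
and fill the other eleven with plausible integers whose total (57) exceeds
both published upper cut-points; the comorbidity map
(`comorbidity_map_synthetic.yaml`) uses standard Charlson-style ICD-10
ranges because the development study's exact code lists are in a
non-redistributable supplement. Users validating the real score should
supply their own transcriptions; every API accepts external definition
files.

## Cohort rules and missing data

Inclusion: age ≥ 65 years and stay ≥ 48 h. Exclusion, evaluated in the
fixed order *death before discharge, transfer to another hospital,
non-Swiss residency, missing dispensing information*, with each record
tallied once at its first matching reason (the source does not state an
order; fixing one makes the cascade reproducible). Three sensitivity
cohorts mirror the published missing-data analyses: hyperkalaemia forced to
1 for all potassium-missing patients, and the dispensing-missing patients
re-admitted with opioids forced to 0 or to 1.

## Statistics

* **Logistic regression** is fitted by iteratively reweighted least squares
  with convergence at a maximum absolute coefficient change below 1e-8
  (at most 100 iterations) and covariance equal to the inverse observed
  information. Rank-deficient designs are rejected with the collinear
  columns named; separation is reported as non-convergence with a
  diagnostic. The implementation is cross-checked in the test suite against
  statsmodels and, for a single binary covariate, against the closed-form
  cross-product odds ratio.
* **Discrimination**: the C statistic is computed via midranks (exactly the
  all-pairs concordance with ties counted one half) with a DeLong
  placement-variance confidence interval.
* **Accuracy**: Brier score, the mean squared difference between fitted
  probability and outcome.
* **Global goodness of fit**: the unweighted sum-of-squares test,
  T = Σ(y−p̂)², standardised by E[T] = Σ p̂(1−p̂) and the variance
  dᵀ(V − VX(XᵀVX)⁻¹XᵀV)d with d = 1 − 2p̂ and V = diag(p̂(1−p̂)), compared
  two-sided against the standard normal. In the saturated limit the
  variance is exactly zero while T equals its expectation; the
  implementation returns z = 0, p = 1 there rather than dividing by zero.
* **Calibration**: observed event proportion versus model-predicted risk
  per distinct score value, weighted by the number of patients at each
  value.
* **Group comparisons**: odds ratios of medium and high versus low risk
  with Woolf intervals, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) — this
  convention reproduces every published group interval at printed
  precision. An optional Haldane continuity correction (0.5 added to all
  four cells) covers zero-cell tables; the pipeline falls back to it with a
  logged warning rather than aborting a run. Coefficient intervals default
  to Wald; a profile-likelihood option is provided and, on the sparse
  hyperkalaemia 2×2 reconstruction, reproduces the published 0.37–8.56
  interval that Wald/Woolf cannot, which suggests the original analysis
  used likelihood-based intervals for the per-predictor table.
* **Classification metrics** restrict the cohort to the low group plus one
  comparison group, treat comparison-group membership as the positive test
  and PAR as the condition, and report sensitivity, specificity, PPV and
  NPV (internally as proportions; percentages to one decimal in reports,
  odds ratios to two decimals).

**Tertile cuts on a discrete score** rarely split exactly in thirds. The
adapted cut pair is chosen by exhaustive search over attained score values,
minimising the maximum deviation of the three group sizes from n/3 and
breaking ties toward the smaller lower cut, then the smaller upper cut.
This is a documented convention; the quantile rule used on the original
patient data cannot be recovered from published information.

## The synthetic cohort generator

The generator draws the twelve predictor flags independently at the
published marginal prevalences (e.g. stay > 4 days 73.8%, hypertension
69.6%, opioids 26.5%, hyperkalaemia 0.3%), draws the outcome from a
logistic model whose slopes default to the logs of the published unadjusted
odds ratios — a convenience default, not a claim about the true joint model
— and whose intercept is calibrated by root-finding on the exact 2¹²-term
expectation so the marginal PAR rate is 5.7%. Potassium results are missing
for 7.2% of patients (their hyperkalaemia flag is forced off, consistent
with the not-missing-at-random assumption) and dispensing records for 1.5%.
Each flag is materialised as concrete records, including deliberately
adversarial ones: pre-admission opioid dispensings, non-opioid N02B
analgesics, stale prior admissions outside the six-month window, and
hyperkalaemic values placed before the seven-day window so the flag is only
recoverable through carry-forward. Extraction on the emitted tables
recovers the generating flags exactly for fully observed patients.

Records violating the filters are appended at configurable rates (death
5%, transfer 10%, non-Swiss 3%, under-age/short-stay 5% of the retained
size); the published cascade reports only the total attrition, so these
per-reason rates are one-time realistic choices. An optional exchangeable
Gaussian-copula correlation between predictors exists for robustness
experiments but defaults to off, because only marginal prevalences are
published. One admission per synthetic patient is generated; multi-stay
histories beyond the six-month flag are out of scope.

What the generator does **not** emulate: real ICD-10 co-occurrence
structure, the readmission adjudication algorithm (the outcome label is an
input everywhere in the package), free-text medication entries, and
haemoglobin-based anaemia. Passing tests therefore demonstrate correctness
of the pipeline's arithmetic and bookkeeping under the assumed data model,
not clinical transportability of the score.

## Problem sizes and numerical choices

The test suite validates the heavy properties at sizes chosen to keep runs
comfortable while leaving the statistics sharp: concordance against the
O(n²) all-pairs oracle on 200 cohorts of up to 300 patients; goodness-of-fit
null calibration over 1,000 replicates of n = 500 (type-I error required in
[0.03, 0.07] at α = 0.05); Wald coverage of all twelve generating log odds
ratios over 500 synthetic cohorts of n = 20,000 (required in [0.92, 0.98]);
round-trip and determinism checks on a 2,000-patient cohort. Published
cohort-level results that require the original patient records — C = 0.605,
Brier = 0.053, the adapted cuts 12/25, adjusted odds ratios, and the mean
predicted risks computed from the development study's coefficients — are
documented as non-reproducible and covered by these property substitutes
instead; the count-derived tables (group odds ratios and intervals, all
sixteen classification measures, observed proportions, all twelve
unadjusted odds ratios) are reproduced at printed precision.

## Known limitations

* The bundled weights and code lists are stand-ins; absolute score
  distributions (hence the synthetic tertile cuts) are not comparable to
  the published ones.
* Predictor independence in the generator understates real comorbidity
  clustering; the correlation hook is a crude surrogate.
* The prior-admission window counts admissions to any source table row;
  whether the original analysis restricted to the same hospital is
  unstated.
* External predicted risks accept a per-score (intercept, slope) pair only;
  per-item external coefficient sets would require the original model's
  full specification.
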