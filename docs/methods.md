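# Methods

## Outcome and exposure classification

A participant is classified **diabetes** if any of three criteria holds:
self-reported diabetes, fasting glucose ≥ 7.0 mmol/l (single measurement),
or reported use of antidiabetic medication.  Absent all three,
**prediabetes** is impaired fasting glucose in [6.1, 7.0).  The nominal IFG
band is 6.1–6.9 mmol/l stated for values reported to one decimal; the
implementation keeps full-precision glucose and therefore treats the band
as half-open at 7.0, so unrounded values such as 6.95 are not silently
dropped from every class.  A record with no glucose value is **excluded**
only when the diabetes question was also left blank (no criterion can be
evaluated); a record that answered "no" without a measurement falls in the
**reference** class, since the only applicable criterion is negative.
Classification is a pure function of the record: the four classes partition
any cohort, and raising glucose can never demote a record to a lower class.

Exposures are dichotomous.  Parental history of diabetes (PHD) is diabetes
in either parent; a maternal-history analysis excludes all subjects
reporting paternal diabetes (including biparental reporters) and
symmetrically for paternal analyses — expressed as eligibility flags in the
exposure panel so each analysis filters explicitly.  Current smokers are
contrasted with never+ex smokers; leisure and work inactivity are level 1
of their four-level questionnaire items; BMI is dichotomised strictly above
25 and strictly above 30.  SAD, waist circumference, WHR and BMI are also
dichotomised at sex-specific 90th-percentile cutoffs computed from the
analysed cohort by linear interpolation between order statistics (the
common "type 7" quantile; the convention is a package choice since several
definitions exist, and the differences are far below sampling noise at
these sizes).  "High" always means strictly above the cutoff, so a
degenerate constant measure flags nobody.  Missing raw fields propagate to
missing flags; no imputation anywhere.

## Odds-ratio estimation

Prevalence odds ratios come from maximum-likelihood logistic regression,
fitted by Newton-Raphson/IRLS with step-halving, convergence when the
largest absolute score falls below 1e-8 or the relative log-likelihood
change below 1e-10 (at most 50 iterations), and coefficient covariance
equal to the inverse information at the MLE.  Quasi-complete separation is
detected by coefficient divergence beyond ±15 on the log-odds scale and
raised as an error: a "significant" OR of e±15 is a fiction, and no Firth
or exact correction is attempted.  For a single binary exposure the crude
fit coincides (to numerical tolerance ~1e-9) with the closed-form 2×2
cross-product ratio and Woolf standard error, which the test suite uses as
an independent oracle, alongside a brute-force likelihood grid search and a
cross-check against statsmodels.

Each model contrasts one outcome class against the reference class only;
the other outcome class and excluded records are dropped.  The published
tables do not state this comparison group unambiguously, and it is the one
choice under which their "reference category" descriptives are coherent;
it is a documented parameter of the analysis functions rather than a
hard-wired rule.  Adjusted models add dummy variables for current and ex
smoking (never = reference), the two inactivity indicators, and BMI as a
continuous term; the source analysis names BMI among adjustment factors but
dummy-codes only the lifestyle variables, so continuous BMI is the default
and BMI>25/BMI>30 indicator adjustment remains available by passing those
panel columns instead.  All models are complete-case, with dropped-record
counts carried in every result.  95% intervals use z = 1.959964; values are
rounded (half away from zero, one decimal) only in the human-readable
report layer, never in computation.

## Additive interaction

The interaction model is a single logistic fit with three joint-exposure
indicators against the doubly-unexposed reference, plus any covariates.
S, RERI and AP are computed from the exponentiated coefficients; by
construction the consistency identities S = (OR₁₁−1)/((OR₁₀−1)+(OR₀₁−1)),
RERI = OR₁₁−OR₁₀−OR₀₁+1 and AP = RERI/OR₁₁ hold exactly, and the measures
are symmetric in the exposure order.

The CI for S uses the delta method on ln S: with D = (e^{β₁₀}−1)+(e^{β₀₁}−1)
and N = e^{β₁₁}−1, the gradient of ln S w.r.t. (β₁₀, β₀₁, β₁₁) is
(−e^{β₁₀}/D, −e^{β₀₁}/D, e^{β₁₁}/N), propagated through the fitted
covariance block; the interval is exp(ln S ± 1.96·se).  RERI and AP get
delta-method intervals on their own scales.  When the double-exposure cell
is sparse these intervals are wide — that is the honest answer, and a
seeded percentile bootstrap (resampling records, refitting, discarding
degenerate resamples) is provided as a cross-check.  Degenerate cases carry
status flags: `no_result` when OR₁₁ ≤ 1 (non-positive numerator; this takes
precedence, so a fully null triplet is also `no_result`), and
`undefined_antagonism_denominator` when OR₁₁ > 1 but the denominator is
non-positive.

## The synthetic-cohort generator

No individual-level data accompany the study this package operationalises,
so the generator is a first-class component: it produces cohorts with the
statistical structure the analysis assumes, with known ground truth, so
estimator correctness, CI calibration and pipeline robustness are all
testable.

Records are drawn independently.  Per sex: parental flags as independent
Bernoullis (maternal/paternal probabilities chosen so the union matches the
target PHD prevalence), sibling history conditional on PHD (family
clustering), smoking as a three-category draw with an optional log-odds
shift of current smoking given PHD (the emulated cohort's PHD-positive men
smoked less; men default 0.684, women 1.0), four-level activity items from
configured distributions, and BMI from a per-sex normal whose tail gives
the obesity prevalence (men 26.6 ± 3.55 → 17% BMI>30, women 26.3 ± 4.05 →
18%).  Waist, hip, SAD and height are normals; the adiposity measures load
on the BMI z-score with correlation 0.8 (a single latent adiposity factor —
the real joint distribution is unreported).  Weight is back-computed from
BMI and height.

The outcome is a baseline-category logit over
{reference, diabetes, prediabetes} on the four cells of a designated
exposure pair (default: obesity × PHD), with the diabetes cell effects
equal to the configured log odds ratios (OR₁₀, OR₀₁, OR₁₁) and prediabetes
given multiplicative obesity/PHD effects.  Because the analysis contrasts
each outcome against the reference class, this parameterisation makes the
configured ORs exactly the estimands of the fitted models — a sequential
Bernoulli scheme would not, since the prediabetes share varies across
cells.  The two intercepts are calibrated by root-finding so the marginal
class prevalences hit their per-sex targets (men 10.06% / 10.99%, women
5.16% / 5.25%); infeasible targets raise a config error.

Glucose is log-normal per class, matched to a median and IQR (men with
diabetes 8.7 (7.4–11.1) mmol/l, prediabetes 6.3, reference 5.2; women
slightly lower) and truncated to the class band, so re-classification
reproduces the latent class for every record.  Diabetes cases get a
reporting structure: a configurable fraction self-report (men 0.546, women
0.637); of those, 78%/71% report medication and a small fraction (3%/13%)
are "non-validated" — self-report only, glucose below 7.0, no medication.
Glucose-identified cases are drawn above 7.0.  A tiny fraction of records
(3/4232) is emitted as excluded (no glucose, blank self-report).
Missingness is masked per field at small configured rates (e.g. smoking
4.4%) and never touches the outcome-defining fields outside the excluded
mechanism.

Default interaction truths are the obesity-by-parental-history triplets
(3.4, 2.0, 9.1) in men — synergy index 2.38 — and (4.4, 1.6, 4.0) in women.
One known tension: the marginal prevalences, exposure prevalences and cell
ORs are mutually determining, and with these defaults the model-implied
proportion of diabetic men among the PHD-exposed is ≈16–17% rather than the
≈20% a fully consistent cohort would show; the published summary numbers
cannot all be hit at once from rounded inputs, and the calibration
prioritises the marginal prevalences and the cell odds ratios, which are
what the estimators consume.

What the generator does **not** emulate: correlation between obesity and
PHD (independent by default), within-family pedigree structure, age
variation (everyone is 60), measurement error and digit preference in
anthropometrics, skewness of BMI, and informative missingness.  Passing
tests therefore demonstrate correctness of the estimators and calibration
of their intervals under a well-specified model, not robustness to these
real-data features.

## Problem sizes and test design

Validation uses cohorts of 4232 (the default study size) for pipeline
checks; 5000 × 200 seeds for CI-coverage simulations (ln S under an
additive-odds truth, Wald OR under a null generator, both expected at
0.95 ± 0.03); 50000 × 100 seeds for parameter recovery (each log-OR and
ln S within 3 SE in ≥ 95% of seeds); 500 seeds at n = 4232 for prevalence
calibration (seed-averaged diabetic fractions within one percentage point
of target); and 100000 records for the classification-consistency sweep.
These sizes put Monte-Carlo error comfortably below the tolerances being
asserted while keeping the full suite around a minute of compute.

## Limitations

- No multiple-testing adjustment anywhere, matching the single-comparison
  0.05 convention of the emulated analysis; with ~dozens of rows per report
  some nominally significant results are expected by chance.
- Delta-method intervals for S are first-order and can misbehave with very
  sparse double-exposure cells; the bootstrap cross-check and the explicit
  zero-cell notes in the interaction table are the guard rails.
- Separation raises rather than being penalised away; rare exposures (e.g.
  biparental history in small strata) legitimately yield flagged rows.
- Prevalence odds ratios approximate incidence rate ratios only under
  stable prevalence and exposure-independent disease duration; the package
  computes the former and makes no claim about the latter.
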