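# Methods

## Scores and their components

All three scores are sums of integer points over independent components;
each is monotone in every component's severity and bounded by the sum of
component maxima (6 for all shipped definitions). Point allocations are
data (`ScoreDefinition`), not code: each component maps a record field
through an ordered list of non-overlapping bins with explicit inclusive or
exclusive bounds, validated at construction. Integer clinical scales (GCS,
MRS, NIHSS, age in years) use inclusive integer bounds so no
floating-point edges appear in shipped definitions.

**ICH score.** GCS 3–4 → 2, 5–12 → 1, 13–15 → 0; hematoma volume
≥ 30 cm³ → 1; IVH → 1; infratentorial location → 1; age ≥ 80 → 1. The two
"≥" boundary choices matter clinically: a patient exactly 80 years old or
with exactly 30 cm³ scores the point.

**New / Modified New ICH score.** Severity bin (NIHSS 0–10/11–20/21–40 or
MRS 0–2/3–4/5 → 0/1/2) plus one point each for elevated temperature,
widened pulse pressure, IVH, and SAH. The temperature and pulse-pressure
point thresholds are **assumptions** in this package — the shipped
defaults are 37.5 °C and 85 mmHg, chosen as round values near the febrile
threshold and the upper normal pulse pressure of an older hypertensive
population. They are flagged `assumed: true` in the serialized definition,
embedded in every evaluation report, and overridable via
`--score-config` / the `default_*_definition(...)` factory arguments. No
fixture-based evaluation result depends on them.

MRS 6 denotes death and is rejected at admission scoring; admission MRS
0–5 are all accepted. (Reference cohorts sometimes exclude MRS 0 and 6
from initial tabulation; we accept 0 because an asymptomatic admission is
representable and maps to the lowest severity bin anyway.)

**ABC/2 volume.** V = A·B·C/2 cm³ with A the largest hematoma diameter on
the index CT slice, B the diameter perpendicular to A on the same slice,
and C the number of slices showing blood times the slice spacing. The
formula is the half-ellipsoid approximation; it is symmetric in A and B
and homogeneous of degree 3. When a record carries both a measured volume
and diameters, the measured volume wins and a warning is logged.

## Evaluation engine

Counts of deceased/surviving patients per score value
(`ScoreOutcomeTable`) are the sufficient statistic for everything the
engine computes. The positivity convention is fixed: predicted death ⇔
score ≥ cutoff.

All proportions are exact `fractions.Fraction` ratios. Rounding occurs
only at presentation and is half-away-from-zero (the convention clinical
tables use), stated in every report. LR+ with specificity 1 (and LR− with
specificity 0) is reported as infinity, not an error; predictive values
with an empty predicted class are reported as undefined (`null`), as is
the mortality of an empty stratum.

The AUC is the Mann–Whitney pairwise estimator with half-credit for ties
— the standard convention for ordinal predictors, made explicit here
because heavily tied integer scores make the tie term large. Every call
also computes the trapezoidal area under the empirical ROC polygon and
asserts exact equality; the two are the same rational number by a standard
summation-by-parts argument, so the assertion costs little and catches
count bookkeeping errors. The test suite additionally cross-checks the
AUC against scikit-learn's `roc_auc_score` on materialized patients, and
checks cutoff metrics against a brute-force oracle that classifies
patients one by one.

The Youden-optimal cutoff maximizes J = sensitivity + specificity − 1 by
exhaustive search over the observed score values plus one value above the
maximum (the all-negative rule). Ties break toward the lower cutoff,
favoring sensitivity — appropriate when the positive class is death and a
missed high-risk patient is the costlier error. Note that on the packaged
reference tables the J-maximizing cutoffs (ICH ≥ 3, Modified ≥ 4) differ
from the cutoffs conventionally reported for these scores (≥ 2 and ≥ 3);
reports therefore show metrics at both requested and optimal cutoffs.

### Known print inconsistencies in the reference table

The packaged count tables imply ICH-row PPV 53/70 ≈ 0.76 and NPV
29/37 ≈ 0.78, Modified-row specificity 24/46 ≈ 52.2% and LR+ ≈ 1.85, and
Modified sensitivity 54/61 ≈ 88.5%. Published summaries of the same
cohort print 0.70, 0.83, 53%, 1.87, and 88 for these cells — values that
cannot be derived from the counts (they appear computed from pre-rounded
percentages, and the sensitivity truncated). This package always reports
count-derived values; the discrepancy is documented here and asserted in
the tests, not chased.

## Synthetic cohorts

The generator emulates a 107-patient emergency-department cohort with 57%
30-day mortality (61 deceased / 46 survivors).

**score_level** (default; used by all fixture-style evaluations): each
patient's outcome is Bernoulli with the prevalence implied by the joint
(score, outcome) probability table — by default the observed joint,
i.e. cell counts normalized by 107 — and each scoring system's value is
then drawn from its outcome-conditional distribution, independently
across systems given the outcome. Each system's marginal (score, outcome)
joint therefore equals the configured table in expectation; the
cross-system association beyond that induced by the shared outcome is not
modelled (none is published).

**component_level**: raw admission covariates are drawn per outcome group
from normals truncated to physiologic ranges (age [18, 110] y, GCS
[3, 15], MRS [0, 5], temperature [30, 43] °C, pulse pressure [10, 150]
mmHg, volume [0.5, 150] cm³), with the published group means/SDs as
location/scale; integer scales are rounded. IVH, SAH, and infratentorial
location are outcome-conditional Bernoullis at the observed rates.
Diastolic BP is not published per outcome; dbp ~ N(85, 12) truncated to
[40, 130] mmHg is assumed for both groups and sbp = dbp + pulse pressure,
which guarantees sbp > dbp. Covariates are conditionally independent
given the outcome — real admission covariates are correlated (GCS with
volume and IVH in particular), so component-level cohorts are suitable
for pipeline and contract testing, not for studying joint covariate
structure. Because truncation shifts moments, the truncated distribution's
mean — not the configured location — is the generator's true mean; the
parameter-recovery test checks recovered means against the
scipy-computed truncated moments, and against the configured values
directly for the lightly truncated covariates where the two coincide.
Only mean ± SD is published for the integer scales, so rounding a
truncated normal is a modelling choice, not an inference.

A single integer seed drives one `numpy.random.default_rng` stream; no
global RNG state is touched, and identical configs produce byte-identical
cohorts.

## Problem sizes and numerical choices

Fixture-based results are exact desk-scale computations on 107 patients
and involve no sampling. Simulation-based checks use 50 000 patients for
AUC recovery (binomial-pair variance puts the Monte-Carlo SD of the AUC
well below the 0.02 acceptance band), 10 000 patients × 20 seeds for
covariate recovery, and 1000 random small tables for the engine's exact
identities. The full test suite runs in a few seconds on one CPU.

## Limitations

* Passing fixture tests shows the engine reproduces the reference
  analysis exactly; it says nothing about how either score transports to
  other cohorts.
* The generator models no covariate correlations and no anatomical-site
  structure.
* No confidence intervals or AUC-comparison tests are provided; the
  engine is purely point estimation over a fixed table.
* The New/Modified New vital-sign thresholds are assumptions (above);
  component-level scores shift if they are changed, which is why they are
  surfaced in every report.
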