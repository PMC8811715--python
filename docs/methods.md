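# Methods

`anctrial` implements the computational core of a pragmatic two-arm
cluster-randomised comparison of antenatal-care quality between clinics using
a digital client registry with clinical decision support (CDSS) and clinics
using paper records.  The unit of randomisation is the primary-care clinic
cluster; the unit of observation is a pregnancy episode (registration,
antenatal contacts, delivery).  This note records the models, conventions and
numerical choices the package makes, and what its synthetic-data experiments
do and do not demonstrate.

## Visit schedule and eligibility

The guideline requires five routine visits after booking, labelled 16,
18–22, 24–28, 32 and 36 weeks.  The guideline names visits, not
gestational-age intervals for the single-week labels, so the package declares
a default window table (completed weeks, half-open):
wk16 = [14, 18), wk18_22 = [18, 23), wk24_28 = [23, 29), wk32 = [29, 34),
wk36 = [34, 43).  The windows are contiguous and non-overlapping so that any
contact maps to at most one scheduled visit; the table is configurable via
YAML (`anctrial/data/windows.yaml`).  When two contacts fall in one window,
the earlier one is the scheduled visit; later ones are extra contacts and
remain condition-eligible where a screening row matches.

Condition eligibility follows the guideline's screening table: haemoglobin at
booking, 24–28 and 36 weeks; blood pressure at booking and all five visits;
blood sugar at booking when before 24 weeks (urine or blood test) or after
the 24–28 window (blood test), and at 24–28 weeks (blood test); fundal
growth at a booking contact after 20 weeks; presentation at the 36-week
visit.  "First contact after 20/28 weeks" rows are read literally: they apply
to the booking contact when its gestational age exceeds the threshold.  Care
moves to a referral clinic once a woman is referred, so contacts after a
referral are excluded from routine-care denominators; the referring contact
itself is retained (the referral is the management performed there).

Attendance denominators: a woman counts for a scheduled visit if she
registered before the window closed and had not been referred before it
opened; a woman booking after the last window contributes zero opportunities.

## Rules engine

Classifier thresholds and the condition-to-action map are data (YAML), not
code branches, so the production engine's larger rule set can be emulated by
extending configuration.  Thresholds (with the boundary conventions chosen
for internal consistency with the delivery-outcome definitions):

* anaemia (g/dL): severe < 7.0 ≤ moderate < 10.0 ≤ mild < 11.0 ≤ none.  The
  printed mild band ends at 10.9; [10.9, 11.0) is closed into "mild", the
  smallest extension.
* gestational hypertension (mm Hg): mild 140–149 / 90–99; moderate 150–159 /
  100–109; severe ≥ 160 / ≥ 110.  The printed severe band (">160 or >110")
  leaves exactly 160/110 unassigned; it is resolved as severe, matching the
  at-delivery definition of severe hypertension (≥ 160 / ≥ 110).
* glucose: positive at random blood sugar ≥ 140 mg/dL; before 24 weeks a
  urine test alone counts as screening, from 24 weeks a blood test is
  required.
* growth: abnormal when the fundal-height − gestational-age discrepancy is
  strictly greater than 2 or strictly less than −2, or ultrasound suspects a
  growth abnormality.

Deadlines are calendar days inclusive of the final day: "within 4 weeks" =
28 days (repeat haemoglobin), "within 4 days" (repeat blood pressure),
"within 1 week" = 7 days (follow-up ultrasound).  Whether chronic
hypertension is known is an input flag on the pregnancy; the engine does not
infer it from repeated readings.  Iron/folate supplementation is not part of
the management definitions (mirroring its unreliable documentation in the
source records).

## Outcome adjudication

Process (adherence) success per eligible contact = screening documented AND
(finding normal OR the guideline management documented within its deadline).
Undocumented means not performed, so process outcomes have no missing data.
For moderate/severe/chronic hypertension the default requires a documented
referral; a configuration switch (`accept_monitoring`) also accepts a
documented repeat measurement, reflecting in-clinic monitoring.

The composite delivery outcome has five constituents, each
occurred/absent/missing: admission haemoglobin < 10 g/dL; admission SBP ≥
160 or DBP ≥ 110 mm Hg; term (≥ 37 completed weeks) birthweight ≥ 3258 g
(LGA); term birthweight ≤ 2394 g (SGA) with no antenatal abnormal-growth
finding; non-cephalic presentation at delivery at ≥ 36 weeks with no
non-cephalic finding at a contact at ≥ 34 weeks (the 36-week window).  The
two birthweight cutoffs are the printed 37-week percentile values and are
applied to all term births by default; a per-gestational-age percentile
table can be supplied in configuration.  The composite occurred if any
constituent occurred, is absent only if all five are absent, and is missing
otherwise.  Stillbirth = no signs of life at ≥ 28 completed weeks.

## Constrained randomisation

Stratified 1:1 allocation constrained on four cluster covariates: annual
enrolments, laboratory availability, proportion of women over 40, proportion
primiparous.  Procedure: 10 000 candidate stratified allocations, the 1000
best balanced retained, one drawn uniformly.  The balance metric is not
published; this package uses the sum over covariates of the absolute
difference in arm means divided by the overall between-cluster SD, which is
scale-invariant across counts, binary indicators and proportions.  Any
monotone metric satisfies the described procedure; this one is declared and
configurable, with ties broken by candidate index so selection is
reproducible for a given seed.

## Power

Design effect for unequal cluster sizes: DE = 1 + ((cv² + 1)·m̄ − 1)·ρ,
with m̄ the mean cluster size, cv its coefficient of variation, ρ the ICC.
At the trial's design parameters (m̄ = 44, cv = 0.85, ρ = 0.04) DE ≈ 3.99.
Analytic power is the two-proportion normal approximation at effective
per-arm size n = clusters·m̄/DE, reporting both rejection tails (so the null
case returns exactly α).  The simulation oracle draws cluster event
probabilities from a Beta distribution with dispersion matched to ρ
(exchangeable-correlation model), counts Binomial events per cluster, and
tests arms with an unweighted t test on cluster-level proportions; with
unequal cluster sizes that analysis is slightly less efficient than the
effective-sample-size approximation, and the tests assert agreement only up
to that known gap.  The stated 15–25% process-outcome improvement is treated
as absolute percentage points (the conservative reading); the power bound is
verified at +15 points from an assumed 30% baseline.

## Trial analysis

Mixed-effects logistic regression, reporting cluster-specific adjusted odds
ratios: contact-level process outcomes include random intercepts for clinic
and pregnancy; pregnancy-level outcomes include a clinic intercept.  The
adjustment set (stratification variable plus the four constraining
covariates) is configurable per model; the stratum is excluded for the
severe-hypertension constituent, which it can separate perfectly.  The GLMM
optimisation is delegated to lme4::glmer (Laplace approximation) through a
batched `Rscript` bridge; the package owns data assembly, nesting, MI
orchestration, pooling and re-expression.  On a failed fit with two random
effects the model is refitted with the clinic intercept only and flagged
(logged warning).  A pure-Python Gauss–Hermite-quadrature ML fitter for the
single-intercept model serves as an independent numerical cross-check in the
tests (agreement to ~0.01 on coefficients).

OR re-expression: additional successes per 1000 women =
1000·(p₁ − p₀) with odds₁ = OR·p₀/(1 − p₀).  Applied to a cluster-specific
OR this is an approximation, and the baseline (raw control proportion vs a
marginal prediction) is an explicit argument; at OR 1.88 and baseline 0.288
the conversion gives ≈ 144 per 1000.

Little's MCAR test: EM maximum-likelihood mean/covariance of the incomplete
multivariate-normal sample (tolerance 1e-7, ≤ 200 iterations, ridge 1e-10
on solves), then the pattern-weighted Mahalanobis statistic with
df = Σⱼ pⱼ − p.  Binary constituents are treated as numeric, the standard
practice.  A single missingness pattern returns p = 1 with a warning.  The
test has no power against missingness that depends only on an unobserved
variable uncorrelated with the rest — the power checks use correlated
constituents, as in real delivery data.

Multiple imputation: chained equations with Bayesian logistic draws for
binary variables (IRLS with ridge 1e-3, coefficient draw from the
asymptotic normal) and Bayesian linear draws (scaled inverse-chi-square
variance) for continuous ones; default 10 cycles (5 in the heavier pipeline
runs), m = 50 per the trial (reducible in tests).  Variables are visited in
increasing order of missingness.  All randomness flows through one
`numpy.random.Generator`, so imputations are bit-identical under a fixed
seed.  Rubin pooling: T = W̄ + (1 + 1/m)·B, CI from a t quantile with
Barnard–Rubin degrees of freedom (reducing to the classic formula at the
default infinite complete-data df).  Latent-scale ICC =
σ²c/(σ²c + π²/3) from a random-intercept logistic fit, with an optional
profile-likelihood CI on the variance component.

## Synthetic cohort

The generator emulates the trial's data-generating setting and every latent
parameter is recorded in a ground-truth file.  Where the study states a
condition it is the default: 120 clusters in five strata, gamma cluster
sizes with mean 44 and cv 0.85 over an 8-month recruitment window, process
ICC 0.04 (clinic intercept SD on the logit scale), field-level delivery
missingness of 7.2% (gestational age), 9.8% (birthweight), 24.4% (admission
haemoglobin) and 33% (admission blood pressure, masked as a pair), ~3.4%
with no birth record, and control-arm documentation propensities near the
observed control proportions (anaemia 0.32, blood pressure 0.95, glucose
0.40, growth 0.80, presentation 0.78).  The intervention effect is a single
log-odds shift (default log 1.9) applied only to documentation and
management propensities — never to physiology — so arm exchangeability of
measured values is a testable invariant.  Per-woman visit attendance is a
Beta propensity with mean 0.43 and concentration 1.65, calibrated jointly
with booking and risk-referral rates so ~9% of women complete the full
five-visit schedule while ~43% of opportunities are attended.  Field
missingness uses a Gaussian copula (r = 0.7) across fields within a woman,
emulating record-quality clustering and keeping the composite-outcome
missing fraction near the observed one-third rather than the independent
product.

Declared calibration conveniences (not study facts): measurement
distributions (Hb N(11.9, 1.0); SBP/DBP bivariate normal 110/70, r = 0.6;
RBS N(95, 20); fundal-height noise SD 1.2 weeks) chosen so detected-
condition prevalences are of the observed order; term birthweight
N(2850 + 80·(GA − 39), 330) g so the fixed LGA/SGA cutoffs yield ~11%/~8%
constituent rates (a stylised choice — the mean is deliberately below the
population term mean because the cutoffs are applied GA-invariantly); no
latent link between antenatal fundal-height findings and delivery
birthweight (growth "detection" is noise-driven), so the undetected-SGA
constituent exercises the logic but not a realistic detection process.
These simplifications mean passing tests demonstrate correctness of the
pipeline's logic and calibration of its statistics under a known model —
not that the intervention effect or missingness structure of real registry
data would be recovered.

## Problem sizes in the test suite

Simulation-based checks run at deliberately reduced scale, chosen as the
smallest sizes at which the asserted bands are statistically meaningful:
type-I error uses 200 replicates of 20+20 clusters (mean size 15); effect
recovery uses 100 replicates of 120 clusters (mean size 12); MI recovery
uses one 40-cluster trial with m = 10; Little's calibration uses 500
replicates at n = 300.  Mixed-model replicates are fitted in a single
batched R session.  The acceptance script reports a 60-cluster trial
(mean size 25) with m = 50 imputations.

## Known limitations

* The GLMM route requires `Rscript` with lme4 on the PATH.
* Wald intervals are used for fixed effects; no small-sample (Kenward-
  Roger-style) correction is attempted at 120 clusters.
* The rules engine implements the sentinel subset of the guideline rules;
  the schema is extensible but no attempt is made to encode the full
  production rule set.
* The OR→per-1000 conversion documents the standard formula only; the
  trial's own re-expression method is under-specified and its printed
  values are not reproduction targets.
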