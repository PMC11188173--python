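# Methods

## Setting and notation

A cohort of young people (ages 11–17) is enrolled after an index
SARS-CoV-2 PCR test taken in one of seven months, September 2020 –
March 2021. Data-collection sweeps are scheduled 3, 6 and 12 months
post-test, but a person's month of test determines which sweeps exist
for them: January–March 2021 testers have all three; October–December
2020 testers have the 6- and 12-month sweeps; September 2020 testers
only the 12-month sweep. (A configurable "contacted at 6 months" flag
covers the partial 6-month contact of December 2020 testers; its default
probability is 1.) The *envisioned population* at a sweep is everyone
whose month of test gives them that sweep; the *analytic sample* is the
subset who responded, responded timely (< 24 weeks at 3 months, ≤ 34 at
6, ≤ 60 at 12 — note the strict inequality only at 3 months), and were
not (re)infected.

## The weighting model

Selection into the analytic sample is decomposed sequentially:

Pr(analytic | X) = Pr(respond | X) · Pr(timely | respond, X, Q) ·
Pr(not (re)infected | timely, X, Q),

where X are design covariates known for everyone (sex, age, region,
index status, IMD decile) and Q are questionnaire measures observed only
for responders. Each factor is modelled by logistic regression on its
nested risk set; each mini weight is the reciprocal of the fitted
probability and the envisioned-population weight is their product. The
estimator of a prevalence is the Hájek ratio 100·Σwᵢyᵢ/Σwᵢ, invariant to
rescaling of the weights.

Assumptions: selection is missing-at-random given the modelled
covariates at each stage, every selection probability is positive, and
the logistic forms are adequate. The package makes no attempt to detect
MNAR selection; the generator can create MNAR stress tests by letting
selection coefficients reference the latent symptom terms directly.

### Model architecture

All models force sex, age, region, index status and IMD; the single
exception is the 3-month (re)infection model, which omits index status
because a positive episode cannot recur within 3 months (its outcome is
structurally zero for index-positives, and including the indicator would
be quasi-separated by design). Candidates for stepwise refinement are
all ten two-way interactions of the forced covariates for the response
model — nothing else exists for non-responders — and, for the timely and
(re)infection models, ethnicity plus current questionnaire measures
(vaccination status, physical health, loneliness, symptom count,
SWEMWS, EQ-VAS, EQ-5D-Y, SDQ, CFS). Only current-sweep measures are
used, avoiding recall-based predictors.

### Functional forms

Age and IMD enter through the form with minimum AIC among linear,
categorical (ages 11–13 / 14–15 / 16–17; IMD quintiles built from
deciles), linear+quadratic, and fractional polynomials of degree ≤ 2
over the standard power set {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (power 0 is
ln x; a repeated power p contributes x^p and x^p·ln x): 8 FP1 and 36 FP2
candidates, 47 in total. Forms are selected per outcome, sequentially —
age first with IMD linear in the baseline, then IMD given age's winner —
with the other forced covariates always present. AIC is 2k − 2·loglik
with k counting all estimated coefficients. Exact AIC ties go to the
form with fewer basis terms, then to the earlier position in the menu.
Variables are pre-scaled (divided by 10) so the working variable is
positive and of order one before powering; the scaling is stored in the
`FormSpec` and is a fixed reparametrization, so AIC ranking and
predictions are unaffected.

The IMD categorical entry deserves a note: the source design names a
five-group categorical IMD coding that is ambiguous between deciles and
quintiles; this package uses quintiles derived from deciles.

### Stepwise selection

Forward steps add the candidate term-block with the smallest joint Wald
chi-square p-value when it is below 0.157; backward steps remove the
included block with the largest p-value when it is at or above 0.200.
Blocks (a categorical factor's dummies, an FP pair, an interaction's
products) enter and leave whole. Forced terms are never removed. Because
the entry threshold is stricter than the removal threshold, cycling is
possible in principle; a visited-model-set guard stops at the first
revisit, and `max_iterations` (default 50) caps the loop. Fits are
complete-case over all forced and candidate variables. The p-values are
Wald tests from a single fit per candidate, not likelihood-ratio tests —
cheaper by one fit per comparison and asymptotically equivalent.

### Separation and numerics

Perfect prediction is detected two ways: a categorical level whose
outcome is constant, and a converged fit whose standardized coefficient
exceeds 15 in absolute value or whose standardized SE exceeds 100
(an odds ratio of e¹⁵ per standard deviation is far outside any
plausible effect here). Offending variables — forced ones included —
are dropped and recorded on the fitted model.

Fractional-polynomial bases over narrow supports are nearly collinear
(age³ and age³·ln age correlate > 0.999 over 11–17), so the fitting
layer standardizes all non-intercept columns, fits on that scale, and
maps coefficients and covariance back. Newton-Raphson is tried first;
if its undamped steps oscillate (common on resampled ill-conditioned
designs) a line-searched BFGS fallback is used. Fitted probabilities
are clipped to (1e-12, 1 − 1e-12). The in-sample concordance statistic
is computed by the midrank (Mann–Whitney) formula, ties counting 0.5.

## Trimming

Weights are trimmed to the cutoff median + k·IQR with k = 3 (the
conservative end of the usual 3–4 range), then multiplied by a common
factor restoring the original sum; quartiles use linear-interpolation
quantiles, which makes the worked example (1, 2, 3, 4, 50) → cutoff 9,
rescale 60/19 exact. The cutoff is unaffected by the magnitude of the
largest weights. All four per-sweep weights are trimmed for reporting;
longitudinal combination uses *untrimmed* components and trims the
combined weight once.

## Longitudinal combination and calibration

The longitudinal target population is everyone envisioned at 6 months.
January–March 2021 testers must have completed the 3-month questionnaire
(it carries their baseline symptom report) and be in the 6- and
12-month analytic samples; their weight is the 3-month *response* mini
weight times the 6- and 12-month envisioned weights. Whether the full
3-month envisioned weight should be used instead is genuinely open —
only completion, not timeliness, of the 3-month questionnaire is
required for inclusion, so the response-only component is the default
and the alternative is a config switch (`jan_mar_component`).
October–December 2020 testers need the 6- and 12-month analytic samples
and multiply those two envisioned weights. September 2020 testers have
no 6-month sweep and are excluded, with reasons logged per person.

Calibration cells are sex × age band (11–14, 15–17) × region = 36
cells. The ratio census count / weighted sample total is computed per
cell and multiplies every weight in the cell, making weighted cell
totals match the census exactly. An occupied sample cell missing from
the margins is an error; a census cell with no weighted sample is
warned about — that stratum cannot be represented. Iterative raking
over non-joint margins and bounded calibration are out of scope.

## Bootstrap

Percentile intervals (default 95%, 1000 replications) resample *persons
from the envisioned population* with replacement — not the analytic
sample — so that model-coefficient uncertainty at every stage is
propagated. By default each replication keeps the full-data functional
forms and stepwise term selections and refits coefficients only;
repeating the form search and stepwise inside replications is available
by flag but multiplies cost roughly fifty-fold. Stratified resampling by
index status is offered for matched designs. Replications whose models
cannot be fitted (one-class outcomes, empty dummy levels in small risk
sets) are dropped and counted; more than 10% dropped aborts with an
error. A reduced single-stage configuration short-circuits to an
array-based replication loop that computes the identical estimator
(checked against the general path in the tests).

## The synthetic generator

`CohortConfig` holds the covariate distributions (sex, age 11–17, nine
English regions, IMD deciles, ethnicity, index status ≈ 41.5% positive,
month of test), per-sweep selection models and a symptom model. The
generator emulates:

- month-of-test → sweep availability, including the December-2020
  partial 6-month contact;
- covariate-driven (MAR) response, timeliness and (re)infection, with
  the 3-month structural zero for index-positives;
- weeks-to-response from per-sweep gamma distributions truncated to the
  side of the cutoff matching the drawn timeliness indicator, so the
  binary indicator honours its model by construction (only the indicator
  enters the method; the continuous timing is cosmetic);
- latent symptom states at 0/6/12 months (`true_*`, oracle columns a
  real study never has — real-data mode writes files without them) with
  observed counterparts (`obs_*`) only where a questionnaire captured
  them: the baseline report requires responding at the person's first
  available sweep;
- questionnaire scores on plausible instrument ranges via
  covariate-linked linear predictors with noise — psychometric realism
  is irrelevant to the weight mechanics;
- a person-level N(0, 2.5²) "engagement" random effect shared across
  sweeps in the response log-odds. Without it, cross-sweep response
  would be independent and the longitudinal sample would all but vanish
  (~0.1% instead of the realistic few percent). The effect is
  independent of symptoms given covariates, so MAR and estimator
  consistency are preserved, at the price of mild misspecification of
  the per-sweep marginal logistic response model — visible as
  conservation ratios a fraction of a percent off 1.

Default marginal rates (response ≈ 9–14% falling with follow-up length,
timeliness ≈ 90–93%, (re)infection ≈ 3–4% early and ≈ 20% by 12 months)
echo the real cohort's ordering; timeliness and early reinfection are
deliberately less extreme than the real study's (~99%, ~2%) so that a
desk-scale cohort (default n = 20,000, scalable to the real 219,175)
leaves every risk set enough events to fit ~15-column models. Symptom
trajectories rise from a few percent at baseline to ~30–45% at 12
months, higher in index-positives. What passing tests on this generator
show is that the *machinery* is correct under its stated assumptions;
they cannot show that real-world selection is MAR, that the real
functional forms are captured, or how the method behaves under MNAR —
the generator's MNAR hooks exist precisely to explore that last
question.

Two fixed study configurations are provided: `mar_recovery_config`
(n = 50,000; response rates 5–30% across sex × IMD strata; symptom
prevalence solved by Brent's method to be exactly 30% in expectation;
no engagement effect, so the response model is correctly specified) and
`one_stage_config` (n = 5,000; response the only selection stage) for
the interval-coverage study.

## Problem sizes used in the shipped studies

Parameter recovery averages 20 cohorts of n = 50,000; stepwise operating
characteristics use 200 replicates at n = 20,000; the coverage study
uses 200 cohorts × 200 bootstrap replications at n = 5,000 — sizes
chosen so each study's Monte Carlo error is small relative to the effect
it measures while the whole suite stays desk-runnable. The analysis
scripts use 200 bootstrap replications for the illustrative intervals;
1000 is the production default in `BootstrapConfig`.

## Known limitations

- Weights address only selection on observables (MAR); MNAR mechanisms
  bias the weighted estimates too.
- The combined longitudinal weight multiplies per-sweep marginal
  weights, implicitly treating selection as sequentially independent
  across sweeps given covariates; correlated response (the engagement
  effect) violates this, though Hájek normalization absorbs most of the
  impact on prevalence estimates.
- In-sample C-statistics are optimistic diagnostics, not validated
  discrimination.
- Variance estimation is bootstrap-only; no linearization variance is
  provided.
- Small risk sets (3-month sweep at desk scale) can make FP2 and
  interaction-rich candidates unfittable; such candidates are skipped
  with warnings, which is the designed behaviour but means selected
  models can differ across scales.
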