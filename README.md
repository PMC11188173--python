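# cohortweights

Sequential conditional inverse-probability survey weights for
longitudinal cohort studies whose analytic samples are shaped by three
nested selection steps: **non-response** to a questionnaire sweep, **late
response** past a timeliness cutoff, and exclusion for **(re)infection**.
The package was built around the design of national matched
test-positive/test-negative follow-up studies of post-COVID symptoms in
young people (sweeps 3, 6 and 12 months after an index PCR test), but the
machinery — propensity models with fractional-polynomial functional
forms, stepwise candidate refinement, weight trimming, longitudinal
combination, census calibration and a weights-aware bootstrap — is
generic. It is aimed at epidemiologists and biostatisticians who need to
ask: *would my prevalence estimates change if the people I lost were not
like the people I kept?*

## The method

At every sweep, each person in the *envisioned population* (everyone who
could have provided data) passes through three nested stages. Three
logistic models estimate the conditional retention probabilities, and
each **mini weight** is the reciprocal of its probability:

- w_response = 1 / Pr(responded | envisioned),
- w_timely = 1 / Pr(timely | responded), where *timely* means responding
  < 24 weeks (3-month sweep) or ≤ 34 / ≤ 60 weeks (6- / 12-month sweeps)
  post-test,
- w_reinfection = 1 / Pr(not (re)infected | timely) — the retained group
  at this stage is the non-(re)infected,

with the **envisioned-population weight** w_env = w_response · w_timely ·
w_reinfection. Weighted by w_env, the analytic sample (timely,
non-(re)infected responders) reconstructs the envisioned population: a
Horvitz–Thompson argument gives Σ w_env ≈ N_envisioned when the models
hold.

Every model forces the design covariates (sex, age, region, index test
status, deprivation decile), with the functional form of age and IMD
chosen by minimum AIC from {linear, categorical, linear+quadratic,
fractional polynomials of degree ≤ 2 over powers (−2, −1, −½, 0, ½, 1,
2, 3), power 0 ≡ ln x, repeated power p ⇒ x^p and x^p·ln x}. Further
candidates (all two-way design interactions for the response model;
current questionnaire measures for the others) enter by forward
(p < 0.157) / backward (p ≥ 0.200 removes) stepwise selection on joint
Wald tests. Index status is structurally excluded from the 3-month
(re)infection model: a test-positive person cannot be reinfected within
3 months of the positive episode. Variables that perfectly predict an
outcome are dropped and reported; in-sample C-statistics diagnose each
model.

Weights are trimmed at median + 3·IQR and rescaled to preserve their
sum. Longitudinal target-population weights multiply untrimmed per-sweep
components (3-month response weight × 6- and 12-month envisioned weights
for January–March testers; 6- × 12-month envisioned weights for
October–December testers) and are trimmed once. Final weights can be
calibrated to external sex × age-band × region census counts via
per-cell ratios, after which weighted cell totals equal the census
exactly. Percentile bootstrap intervals resample the envisioned
population and refit the models inside every replication, so the
uncertainty of the estimated weights is propagated.

Because the real cohort data are confidential, the package ships a
synthetic-cohort generator (`cohortweights.synthetic`) that reproduces
the selection structure above — month-of-test-dependent sweep
availability, covariate-driven MAR selection, latent symptom
trajectories with known truth — so every stage is testable end to end.

## Worked example

```python
import cohortweights as cw

config = cw.CohortConfig(n_population=20_000, seed=7)
cohort = cw.generate_cohort(config)
margins = cw.derive_census_margins(config, inflation=10.0)

pcfg = cw.PipelineConfig()
result = cw.run_weight_pipeline(cohort, margins, pcfg)

print(cw.flow_counts(cohort).to_string(index=False))
m = result.models[12]["respond"]
print(f"12m response model: C = {m.c_statistic:.3f}")
w = result.combined["w_combined_trimmed"].dropna()
print(f"longitudinal weights: n = {len(w)}, median = {w.median():.1f}")

est = cw.pipeline_estimates(cohort, result, pcfg)
est = est.set_index(["symptom", "group", "timepoint", "variant"])
for variant in ("unweighted", "target_trimmed", "census_trimmed"):
    v = est.loc[("tired", "Negative", 12, variant), "value"]
    print(f"tiredness, test-negative, 12m, {variant}: {v:.2f}%")
```

prints

```
 sweep  envisioned  responded  timely  analytic  retention_pct
     3       10860       1603    1502      1470             14
     6       17973       2088    1934      1859             10
    12       20000       2016    1887      1574              8
12m response model: C = 0.616
longitudinal weights: n = 524, median = 302.3
tiredness, test-negative, 12m, unweighted: 25.42%
tiredness, test-negative, 12m, target_trimmed: 26.45%
tiredness, test-negative, 12m, census_trimmed: 27.74%
```

Reading it: of 20,000 envisioned at 12 months only 8% survive the three
selection steps; the response model discriminates modestly (C ≈ 0.62,
as expected when only design covariates are available for
non-responders); 524 people satisfy the longitudinal inclusion rules,
each carrying a weight reconstructing roughly 300 envisioned peers; and
the weighted 12-month tiredness prevalences move a point or two from
the unweighted one — the direction and size of the selection effect.

The numbered scripts under `analysis/` run the same stages as a
narrative: `01_simulate_cohort.py` → `02_fit_propensity_models.py` →
`03_build_weights.py` → `04_estimate_prevalence.py` →
`05_bootstrap_uncertainty.py` → `06_simulation_studies.py`, writing
their tables to `results/`. A `cohortweights` CLI (subcommands
`simulate`, `weights`, `estimate`, `bootstrap`, `full`) chains them for
reproducible runs from a YAML config.

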