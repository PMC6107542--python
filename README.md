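# evigrid

High-throughput comparative-cohort evidence generation with empirical
calibration, on synthetic claims data.

Observational healthcare databases can answer thousands of comparative safety
questions at once — every ordered pair of treatments for an indication crossed
with every outcome of interest — but each estimate carries systematic error
(unmeasured confounding, selection, measurement) that a nominal confidence
interval ignores. `evigrid` implements the full evidence-engine pipeline for
that setting, for methodologists who want to study or extend it without access
to licensed claims data:

1. **Synthetic claims data** (`evigrid.simulate`): persons, observation
   periods, drug eras and condition occurrences in common-data-model style,
   with treatment choice confounded by binary baseline covariates and
   time-to-event outcomes with *known* true hazard ratios.
2. **New-user cohorts** (`evigrid.cohorts`): first-ever-use index dates, a
   365-day washout, exclusion of dual-exposed subjects and of subjects with
   the outcome before index, calendar-overlap restriction, and on-treatment
   (30-day era gap) or intent-to-treat time-at-risk.
3. **Propensity-score stratification** (`evigrid.propensity`): large-scale
   covariate construction (everything on or before index; covariates with
   fewer than 100 non-zero values discarded), L1-regularized logistic
   propensity models with 10-fold cross-validated penalty selection, decile
   stratification, and standardized-difference-of-mean balance diagnostics.
4. **Hazard-ratio estimation** (`evigrid.estimation`): Cox proportional-hazards
   partial likelihood conditioned on the propensity strata (Breslow ties,
   Newton with step-halving), Wald intervals; no estimate is produced when an
   arm has fewer than 2500 persons, but the skip is recorded — every attempted
   analysis appears in the output.
5. **Control hypotheses** (`evigrid.controls`): a packaged registry of 52
   negative-control outcomes (true HR 1), and synthetic positive controls at
   true HR 1.5 / 2 / 4 created by injecting simulated outcome occurrences into
   one arm at rates predicted from baseline covariates, preserving measured
   confounding.
6. **Empirical calibration** (`evigrid.calibration`): the systematic-error
   distribution on the log-HR scale is Gaussian with mean `a + b·θ` and
   standard deviation `exp(c + d·θ)` in the true log hazard ratio `θ`. Given
   control estimates `y_i ~ N(θ_i + a + b·θ_i, exp(2(c + d·θ_i)) + se_i²)`,
   the four parameters are fitted by maximum likelihood, and the calibrated
   interval for a new estimate solves
   `y = θ + a + b·θ ± z·sqrt(exp(2(c + d·θ)) + se²)` in `θ`. Coverage is
   evaluated by leave-one-out cross-validation over the controls.
7. **Result-set diagnostics** (`evigrid.synthesis`): transitivity of
   significant risk orderings (if A > B and B > C significantly, A > C should
   be significant) and between-database heterogeneity via Cochran's Q and
   `I² = max(0, (Q − df)/Q)`.
8. **Literature mining** (`evigrid.litmine`): regex extraction of effect
   estimates (OR/RR/HR with a parenthesized CI or p-value) from abstract
   text, log-scale standard errors from the CI (preferred) or p-value, and
   rounding-aware jitter for estimate-vs-SE scatter plots that expose the
   publication-bias boundary at the CI-excludes-1 line.

`evigrid.runner.run_study` orchestrates everything over a grid of
treatments × outcomes × databases and emits an evidence bundle (estimate and
control tables, systematic-error models, heterogeneity and transitivity
tables, a manifest). A thin `evigrid` CLI wraps the main entry points
(`simulate`, `run-study`, `litmine`, `plot`).

## Worked example

A toy study — three treatments, two outcomes (one with true HR 2 for
treatment 1, one null), three negative controls, one synthetic database of
4000 subjects with eight confounders:

```python
import numpy as np
import evigrid as eg

sim = eg.simulate.default_confounded_config(
    n_subjects=4000, n_covariates=25, n_confounders=8,
    outcome_ids=(218, 215, 301, 302, 303),
    true_log_hr={218: float(np.log(2)), 215: 0.0, 301: 0.0, 302: 0.0, 303: 0.0},
    baseline_hazard=8e-4, seed=7, drug_ids=(1, 2, 3))
study = eg.StudyConfig(
    databases={"dbA": sim}, treatment_ids=[1, 2, 3], outcome_ids=[218, 215],
    negative_control_ids=[301, 302, 303], target_hrs=(2.0,),
    min_cohort_size=100, min_covariate_count=30, model_min=50, inject_min=10,
    seed=0)
bundle = eg.run_study(study)

row = bundle.estimates.query(
    "target_id == 1 and comparator_id == 2 and outcome_id == 218").iloc[0]
print(f"HR {row.hr:.2f} (95% CI {row.ci95_lower:.2f}-{row.ci95_upper:.2f}), "
      f"calibrated {row.calibrated_hr:.2f} "
      f"({row.calibrated_ci95_lower:.2f}-{row.calibrated_ci95_upper:.2f})")
print(bundle.manifest["n_cells"], "cells,",
      bundle.manifest["n_control_estimates"], "control estimates")
```

prints

```
HR 2.19 (95% CI 1.75-2.74), calibrated 2.33 (1.85-2.95)
12 cells, 36 control estimates
```

The unadjusted comparison of treatment 1 and 2 is confounded; the stratified
Cox estimate recovers the true hazard ratio of 2, and calibration against the
comparison's own negative and positive controls adjusts the interval for the
residual systematic error those controls reveal. All 12 grid cells are present
in the bundle — cells that fail the minimum-cohort-size rule would appear with
a skip reason rather than vanish.

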