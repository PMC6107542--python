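# Methods

## The estimation problem

Each research question is an ordered target–comparator–outcome (TCO) triple:
does initiating the target drug rather than the comparator change the hazard
of the outcome? The pipeline answers every TCO in a grid with one consistent
design — new-user cohorts, propensity-score decile stratification, a
stratified Cox model — and then confronts the resulting estimates with
control hypotheses of known truth to measure and remove residual systematic
error from the confidence intervals. Everything runs on synthetic data with
known ground truth, so every stage of the machinery is testable end to end.

## Synthetic claims data

`simulate.simulate_population` draws, per subject:

- binary baseline covariates `x_j ~ Bernoulli(p_j)`, with prevalences `p_j`
  uniform on a configured range (default 0.02–0.30). Covariates are
  independent; correlated blocks can be emulated by giving several covariates
  the same coefficients.
- a treatment via multinomial logit over the configured drugs, where the
  covariate coefficients (log-odds) load on the first drug's utility. With
  two drugs this is exactly a logistic model for receiving the target. The
  multinomial form exists so grid-level orchestration can be exercised with
  more than two treatments; the two-drug case is the canonical configuration.
- an index date uniform over the calendar window, an observation period
  starting 365–1095 days before index (so the washout rule is satisfiable by
  construction but not vacuous) and ending at an exponential censoring time
  (default mean 730 days).
- drug eras starting at index, with exponential durations (default mean 180
  days) and, with probability 0.2, a second era after a 1–60-day gap — this
  exercises the era-stitching rule.
- for each outcome `k`, a first-event time that is exponential with per-day
  hazard `h_k · exp(x'β_k + 1[target] · θ_k)`; `θ_k` is the configured true
  log hazard ratio (0 for negative-control outcomes). Events round up to the
  next day, so no event collides with the index date.

Covariates are materialized as condition occurrences on or before index, so
the downstream covariate builder rediscovers exactly the confounders the
assignment model used. Outcomes whose covariate coefficients overlap the
treatment model's are confounded; the default confounded configuration
(`default_confounded_config`) gives 20 covariates log-odds and log-hazard
effects of magnitude `ln 2` with alternating sign, which produces
pre-stratification standardized differences well above the 0.1 balance
threshold while leaving substantial propensity overlap.

What this generator does *not* emulate: correlated covariate structure,
time-varying hazards and treatment switching, outcome misclassification,
informative censoring, and unmeasured confounding. Passing tests therefore
demonstrate that the machinery is correct under its own assumptions — in
particular that calibration restores coverage when the systematic-error model
is well specified — not that it removes bias mechanisms absent from the
generator (the real purpose of negative controls in practice).

`simulate_control_estimates` bypasses the pipeline entirely and samples
control estimates directly from the assumed systematic-error distribution;
it is the clean harness for the calibration machinery.

## Cohort rules

New user: the first-ever era of a drug is the index; any earlier era of the
same drug disqualifies within the data at hand. Washout is measured against
the observation-period start (365 days by default). Subjects ever exposed to
both compared drugs are excluded (which subsumes requiring washout free of
the comparator), as are subjects with the outcome strictly before index.
Index dates are restricted to the overlap of the two drugs' first-to-last
recorded era-start interval. All intervals are closed and day-granular.
Time-at-risk starts at index; on-treatment follow-up stitches successive eras
separated by at most 30 days and truncates at observation end, intent-to-treat
runs to observation end. An empty arm is a recorded signal, not an exception.
The minimum-cohort-size rule (2500 per arm, boundary inclusive) gates
estimation; skipped cells keep their reason in the output.

## Propensity scores and balance

Covariates: one indicator per age band, gender, index year, index month, per
prior condition concept and per prior drug concept (never the compared
treatments); precomputed numeric risk scores can be appended. Covariates with
fewer than 100 non-zero values are dropped. The propensity model is
L1-regularized logistic regression (liblinear) with the penalty chosen from a
log-spaced grid by 10-fold arm-stratified cross-validated log-loss; folds are
seeded. Strata are the deciles of the pooled (target + comparator) score;
ties share a stratum, so a degenerate constant score collapses to one
stratum. Balance is the standardized difference of the mean,
`(m_T − m_C)/sqrt((v_T + v_C)/2)`; the post-stratification version replaces
each arm mean by stratum-specific arm means weighted by the stratum's share
of the pooled cohort, over the same pooled-variance denominator. Strata
containing a single arm are dropped from the adjusted means with a logged
warning. Zero-variance covariates get SDM 0 when arm means agree and are
flagged otherwise.

## Stratified Cox estimation

The single-covariate partial likelihood conditions risk sets on the
propensity stratum. Ties are handled with the Breslow approximation — times
are day-granular so ties are routine, and Breslow keeps the likelihood in the
simple closed form that a brute-force oracle can maximize independently.
Optimization is Newton from 0 with step-halving and a relative score
tolerance of 1e-8; a monotone likelihood (all usable events in one arm) is
caught by a bound and returned flagged rather than thrown, and a cohort with
no stratum containing events from both arms yields an absent estimate.
Standard errors come from the observed information; intervals and p-values
are Wald. The common alternative of Efron tie handling would change estimates
only in the third decimal at these event counts; agreement with an
Efron-based library fit is asserted on tie-free data in the tests.

## Controls and injection

Negative controls (52, packaged) are outcomes believed caused by neither
compared treatment: true HR 1, but simulated with covariate effects shared
with the treatment model so unadjusted estimates are biased away from 1.
Positive controls are synthesized per comparison by injection: a Poisson
regression with a log person-time offset (IRLS, ridge fallback) predicts each
person's outcome rate per day at risk from the same covariates as the
propensity model; each target-arm person then receives extra simulated events
as a Poisson process with rate `(HR* − 1)` times their predicted rate over
their time-at-risk, and the outcome date becomes the earliest event
(first-event analysis, snapped to the day grid). The comparator arm is
untouched, so balance diagnostics are bitwise unchanged. Eligibility: no rate
model below 100 persons with the outcome across both arms, no injection below
25 persons with the outcome in the injected arm; both thresholds are
configurable. Injection targets the *target* arm by default (configurable) —
the controls only need a known non-null effect of one exposure relative to
the other. The nominal target HR is recorded as the truth; the achieved
event-count ratio is kept as a diagnostic.

## Empirical calibration

Systematic error on the log-HR scale is Gaussian with mean `a + b·θ` and SD
`exp(c + d·θ)`, `θ` the true log hazard ratio. Control estimates contribute
the likelihood `y_i ~ N(θ_i(1 + b) + a, exp(2(c + d·θ_i)) + se_i²)`;
maximization is L-BFGS-B from `(0, 0, log 0.1, 0)` with 10 jittered restarts
and objective tolerance 1e-8, and the parameter covariance comes from a
finite-difference observed information. When all controls share one `θ`
(negatives only) the slopes are unidentifiable; the fit drops to intercepts
with a warning. Calibrated bounds solve the pivot equation by bisection on
`[−10, 10]` (log-HR scale) taking the root nearest the calibrated point, with
a monotonicity check of the pivot through the solved interval. A steep fitted
log-SD slope can push one bound to infinity — the pivot approaches its target
asymptotically; by default this raises naming the bracket, while coverage
evaluation treats the bound as unbounded (an infinite interval covers).
Calibrated p-values are deliberately not produced; coverage is assessed with
leave-one-out cross-validation so no control is calibrated by a model fitted
on itself. Calibration is applied per comparison per database, matching the
exchangeability assumption that a comparison's controls share its bias
distribution; pooling across comparisons is possible but not the default.

## Result-set diagnostics

Transitivity uses calibrated CIs by default (configurable to nominal):
within one outcome and database, for every pair of significant orderings
A>B and B>C, the A-vs-C estimate is looked up; the triple "holds" when its
lower bound also exceeds 1, and the reported fraction is over triples whose
A-vs-C estimate exists. Heterogeneity is fixed-effect Cochran's Q with
inverse-variance weights and `I² = max(0, (Q − df)/Q)`; the "sufficient data"
rule requires an estimate row in every database. Triplets are counted per
database.

## Literature mining

The extraction pattern is an effect-measure phrase (odds ratio / o.r. / or /
relative risk / r.r. / rr / hazard ratio / h.r. / hr / hazard / rate ratio)
plus a decimal number, followed by a parenthesized CI
(`number (-|to|,) number`) or p-value (`p [<=>] 0?.ddd`). The bare tokens
"or"/"hr"/"rr" make the pattern deliberately greedy; a strict mode adds word
boundaries and escapes the dotted abbreviations, with no further attempt to
guess post-filters. En/em dashes and the minus sign are normalized to "-"
before matching because published abstracts routinely use en-dashed CIs.
Standard errors: from a CI, `(log u − log l)/(2·z₀.₉₇₅)`; from a p-value, a
two-sided normal test on the log scale, `|log v|/Φ⁻¹(1 − p/2)`; the CI wins
when both appear. Estimates of exactly 1 with only a p-value keep no SE and
are flagged rather than dropped. For plotting, uniform jitter within the
half-unit of the last printed digit (offset 1e-9 so the draw still rounds
back) removes rounding bands without moving any printed value. The module
consumes local text only; no retrieval is performed.

## Orchestration

`run_study` enumerates T×(T−1)×O×D cells and guarantees each appears in the
bundle with an estimate or a skip reason. One propensity model is fitted per
ordered comparison per database, on the comparison's base cohort (entry rules
without the outcome-specific prior-outcome exclusion, of which every
outcome- and control-specific cohort is a subset); outcomes of interest and
controls share that model and its strata. All randomness flows from the
configured seeds, and identical configurations reproduce byte-identical
tables.

## Problem sizes and numerical conventions

The test suite and acceptance script use desk-scale problem sizes chosen to
keep Monte-Carlo error well inside the asserted tolerances: coverage runs use
200 control estimates per replicate (50 at each true HR in {1, 1.5, 2, 4})
over 5–20 replicates; balance restoration uses a 21 000-subject cohort with
200 covariates and 20 confounders; injection recovery uses 40 replicates of
1500-subject cohorts. Tolerances follow binomial/normal 3-sigma bands at
those sizes. Wald z is the exact 0.975 normal quantile (1.95996…), not 1.96;
the literature miner's CI-to-SE arithmetic therefore differs from the
2×1.96 convention in the fifth decimal.

## Known limitations

- Covariate independence makes the propensity model's job easier than in
  real claims data; balance results should be read as a correctness check,
  not a difficulty benchmark.
- Injection assumes a constant per-person rate over time-at-risk; a
  time-varying predicted hazard is out of scope.
- The calibration model is exactly the Gaussian linear-in-truth family; no
  Bayesian or heavier-tailed variants.
- Matching or weighting on the propensity score is not implemented
  (stratification only), and no pooled meta-analytic estimates are produced —
  heterogeneity is reported, not averaged away.
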