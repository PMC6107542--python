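"""Hazard-ratio estimation with a Cox model conditioned on propensity strata.

The outcome model is a Cox proportional-hazards partial likelihood with a
single binary treatment covariate, with risk sets formed within each
propensity stratum. Ties are handled with the Breslow approximation (survival
times are day-granular, so ties are common). Because the model has one
parameter, the partial likelihood is maximized by a scalar Newton iteration
with step-halving; the standard error is the inverse square root of the
observed information, and confidence intervals and p-values are Wald.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import StudySpec, apply_min_cohort_size, build_cohort_pair, compute_time_at_risk
from .propensity import StratifiedCohort, build_covariates, fit_propensity_model, stratify_by_ps

__all__ = ["EffectEstimate", "fit_stratified_cox", "estimate_cell", "run_estimation_grid",
           "enumerate_grid", "stratified_cox_loglik"]

log = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class EffectEstimate:
    """One hazard-ratio record for a target-comparator-outcome-database cell."""

    target_id: int
    comparator_id: int
    outcome_id: int
    database_id: str
    log_hr: float
    se_log_hr: float
    ci95: tuple[float, float]  # on the HR scale
    p_value: float
    n_target: int = 0
    n_comparator: int = 0
    events_target: int = 0
    events_comparator: int = 0
    converged: bool = True
    tar_variant: str = "on-treatment"

    @classmethod
    def from_log_hr(cls, log_hr: float, se_log_hr: float, **kw) -> "EffectEstimate":
        lo = float(np.exp(log_hr - Z95 * se_log_hr))
        hi = float(np.exp(log_hr + Z95 * se_log_hr))
        z = log_hr / se_log_hr if se_log_hr > 0 else np.inf * np.sign(log_hr)
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else (1.0 if log_hr == 0 else 0.0)
        return cls(log_hr=float(log_hr), se_log_hr=float(se_log_hr),
                   ci95=(lo, hi), p_value=p, **kw)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def to_row(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("target_id", "comparator_id", "outcome_id", "database_id", "log_hr",
              "se_log_hr", "p_value", "n_target", "n_comparator", "events_target",
              "events_comparator", "converged", "tar_variant")}
        d["hr"] = self.hr
        d["ci95_lower"], d["ci95_upper"] = self.ci95
        return d


def _stratum_summaries(strat: StratifiedCohort):
    """Per-stratum Breslow sufficient statistics.

    Returns a list of (event_times d, d1, n0_at_risk, n1_at_risk) arrays, one
    entry per usable stratum, plus event counts per arm.
    """
    rows = strat.rows
    time = (rows["tar_end"].fillna(rows["tar_start"]) - rows["tar_start"]).dt.days.to_numpy(float)
    has_event = rows["outcome_date"].notna().to_numpy()
    event_time = (rows["outcome_date"] - rows["tar_start"]).dt.days.to_numpy(float)
    time = np.where(has_event, event_time, time)
    x = (rows["arm"] == "target").to_numpy().astype(int)
    strata = rows["stratum"].to_numpy()

    summaries = []
    for s in np.unique(strata):
        in_s = strata == s
        if len(np.unique(x[in_s])) < 2:
            continue  # single-arm stratum contributes nothing to the conditional likelihood
        t_s, e_s, x_s = time[in_s], has_event[in_s], x[in_s]
        ev_times = np.unique(t_s[e_s])
        if len(ev_times) == 0:
            continue
        d = np.zeros(len(ev_times))
        d1 = np.zeros(len(ev_times))
        n1 = np.zeros(len(ev_times))
        n0 = np.zeros(len(ev_times))
        for k, tv in enumerate(ev_times):
            at_risk = t_s >= tv
            ev = e_s & (t_s == tv)
            d[k] = ev.sum()
            d1[k] = (ev & (x_s == 1)).sum()
            n1[k] = (at_risk & (x_s == 1)).sum()
            n0[k] = (at_risk & (x_s == 0)).sum()
        summaries.append((d, d1, n0, n1))
    return summaries, x, has_event


def stratified_cox_loglik(beta: float, summaries) -> float:
    """Breslow partial log-likelihood at ``beta`` given stratum summaries."""
    ll = 0.0
    eb = np.exp(beta)
    for d, d1, n0, n1 in summaries:
        ll += beta * d1.sum() - np.sum(d * np.log(n0 + n1 * eb))
    return float(ll)


def _score_info(beta: float, summaries):
    eb = np.exp(beta)
    score = 0.0
    info = 0.0
    for d, d1, n0, n1 in summaries:
        denom = n0 + n1 * eb
        pi = n1 * eb / denom
        score += d1.sum() - np.sum(d * pi)
        info += np.sum(d * pi * (1 - pi))
    return score, info


def fit_stratified_cox(strat: StratifiedCohort, *, target_id: int = -1,
                       comparator_id: int = -1, outcome_id: int = -1,
                       database_id: str = "db", tar_variant: str = "on-treatment",
                       tol: float = 1e-8, max_iter: int = 50) -> EffectEstimate | None:
    """Maximize the stratified Breslow partial likelihood for the treatment effect.

    Returns ``None`` when no stratum contains events from both arms at risk
    (no usable information; recorded by callers as a skip, not an error).
    Monotone likelihoods (all events on one arm) are caught by a bound on
    |beta| and returned flagged as non-converged.
    """
    summaries, x, has_event = _stratum_summaries(strat)
    counts = dict(
        n_target=int((x == 1).sum()), n_comparator=int((x == 0).sum()),
        events_target=int(has_event[x == 1].sum()), events_comparator=int(has_event[x == 0].sum()))
    if not summaries:
        return None
    total_d1 = sum(s[1].sum() for s in summaries)
    total_d0 = sum((s[0] - s[1]).sum() for s in summaries)
    if total_d1 == 0 or total_d0 == 0:
        # all usable events in one arm: MLE diverges
        beta = np.sign(total_d1 - total_d0) * 20.0
        est = EffectEstimate.from_log_hr(beta, np.inf, target_id=target_id,
                                         comparator_id=comparator_id, outcome_id=outcome_id,
                                         database_id=database_id, tar_variant=tar_variant, **counts)
        est.converged = False
        return est

    beta = 0.0
    ll = stratified_cox_loglik(beta, summaries)
    converged = False
    for _ in range(max_iter):
        score, info = _score_info(beta, summaries)
        if info <= 0:
            break
        step = score / info
        # step-halving to guarantee ascent
        for _ in range(30):
            new_beta = beta + step
            new_ll = stratified_cox_loglik(new_beta, summaries)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll = new_beta, new_ll
        if abs(score) <= tol * max(1.0, abs(total_d1)):
            converged = True
            break
    _, info = _score_info(beta, summaries)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    est = EffectEstimate.from_log_hr(beta, se, target_id=target_id,
                                     comparator_id=comparator_id, outcome_id=outcome_id,
                                     database_id=database_id, tar_variant=tar_variant, **counts)
    est.converged = converged
    if not converged:
        log.warning("stratified Cox did not converge (|score| at exit > tol)")
    return est


def estimate_cell(dataset, spec: StudySpec, database_id: str = "db", n_strata: int = 10,
                  min_covariate_count: int = 100, seed: int = 0,
                  reuse: dict | None = None) -> tuple[EffectEstimate | None, str | None]:
    """Run one cohort-to-estimate cell: cohorts, PS stratification, Cox.

    Returns (estimate, skip_reason); exactly one is non-None except when the
    Cox fit is flagged. ``reuse`` optionally carries a prefitted propensity
    stratification keyed by (target, comparator) so control outcomes share
    the comparison's propensity model.
    """
    pair = build_cohort_pair(dataset, spec)
    pair = compute_time_at_risk(pair, dataset, spec)
    if pair.is_empty:
        return None, "empty cohort"
    if not apply_min_cohort_size(pair, spec):
        return None, f"cohort below {spec.min_cohort_size} persons"
    key = (spec.target_id, spec.comparator_id, spec.tar_variant)
    if reuse is not None and key in reuse:
        ps_lookup, n_strata_cached = reuse[key]
        ps = pair.rows["person_id"].map(ps_lookup).to_numpy(float)
        if np.isnan(ps).any():
            return None, "propensity score unavailable for cohort member"
        strat = stratify_by_ps(pair, ps, n_strata_cached)
    else:
        matrix = build_covariates(dataset, pair, min_count=min_covariate_count)
        model = fit_propensity_model(matrix, seed=seed)
        ps = model.predict(matrix)
        strat = stratify_by_ps(pair, ps, n_strata)
        if reuse is not None:
            reuse[key] = (dict(zip(pair.rows["person_id"], ps)), n_strata)
    est = fit_stratified_cox(strat, target_id=spec.target_id, comparator_id=spec.comparator_id,
                             outcome_id=spec.outcome_id, database_id=database_id,
                             tar_variant=spec.tar_variant)
    if est is None:
        return None, "no informative events"
    return est, None


def enumerate_grid(treatment_ids, outcome_ids, **spec_kwargs) -> list[StudySpec]:
    """All ordered target/comparator pairs crossed with all outcomes."""
    return [StudySpec(target_id=t, comparator_id=c, outcome_id=o, **spec_kwargs)
            for t, c in itertools.permutations(treatment_ids, 2)
            for o in outcome_ids]


def run_estimation_grid(datasets: dict, specs: list[StudySpec], seed: int = 0,
                        n_strata: int = 10, min_covariate_count: int = 100) -> pd.DataFrame:
    """One row per TCO-by-database cell; skipped cells carry their reason.

    Every attempted analysis appears in the output — the anti-publication-bias
    contract: cells failing the minimum-cohort-size rule (or empty) are
    recorded as skips rather than silently omitted.
    """
    records = []
    for db_id, dataset in datasets.items():
        reuse: dict = {}
        for spec in specs:
            est, reason = estimate_cell(dataset, spec, database_id=db_id, seed=seed,
                                        n_strata=n_strata,
                                        min_covariate_count=min_covariate_count, reuse=reuse)
            if est is None:
                records.append({"target_id": spec.target_id, "comparator_id": spec.comparator_id,
                                "outcome_id": spec.outcome_id, "database_id": db_id,
                                "tar_variant": spec.tar_variant, "skip_reason": reason})
            else:
                row = est.to_row()
                row["skip_reason"] = None
                records.append(row)
    return pd.DataFrame.from_records(records)
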