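"""Orchestration of the full high-throughput study on synthetic data.

One call enumerates every ordered target-comparator pair crossed with every
outcome and every database, runs the cohort / propensity / Cox pipeline per
cell, estimates the comparison's negative and synthesized positive controls
with the *same* propensity stratification as its outcomes of interest, fits
the systematic-error model per comparison and database, calibrates the
outcome estimates, and computes result-set diagnostics (transitivity of
significant orderings, between-database I^2).

Every attempted cell appears in the output with either an estimate or a skip
reason; nothing is silently omitted. With a fixed configuration (seeds
included) the emitted tables are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, controls, synthesis
from .cohorts import StudySpec, apply_min_cohort_size, build_cohort_pair, compute_time_at_risk
from .estimation import EffectEstimate, fit_stratified_cox
from .propensity import build_covariates, fit_propensity_model, stratify_by_ps
from .simulate import SimulationConfig, simulate_population

__all__ = ["StudyConfig", "EvidenceBundle", "run_study"]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Everything needed to run one synthetic high-throughput study."""

    databases: dict[str, SimulationConfig]
    treatment_ids: list[int]
    outcome_ids: list[int]
    negative_control_ids: list[int] = field(default_factory=list)
    target_hrs: tuple[float, ...] = controls.POSITIVE_TARGET_HRS
    washout_days: int = 365
    era_gap_days: int = 30
    tar_variant: str = "on-treatment"
    min_cohort_size: int = 2500
    min_covariate_count: int = 100
    model_min: int = 100
    inject_min: int = 25
    n_strata: int = 10
    min_controls_for_calibration: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.databases or not self.treatment_ids or not self.outcome_ids:
            raise ValueError("databases, treatments and outcomes must be non-empty")
        for name, v in (("washout", self.washout_days), ("gap", self.era_gap_days),
                        ("min cohort", self.min_cohort_size), ("strata", self.n_strata)):
            if v < 0 or (name == "strata" and v < 1):
                raise ValueError(f"invalid {name} threshold: {v}")

    def spec_for(self, target: int, comparator: int, outcome: int) -> StudySpec:
        return StudySpec(target_id=target, comparator_id=comparator, outcome_id=outcome,
                         washout_days=self.washout_days, era_gap_days=self.era_gap_days,
                         tar_variant=self.tar_variant, min_cohort_size=self.min_cohort_size)


@dataclass
class EvidenceBundle:
    estimates: pd.DataFrame          # one row per T x C x O x DB cell (estimate or skip)
    control_estimates: pd.DataFrame  # control estimates per comparison and database
    error_models: dict               # (db, target, comparator) -> SystematicErrorModel
    heterogeneity: pd.DataFrame
    transitivity: list
    transitivity_fraction: float | None
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.csv", index=False)
        self.control_estimates.to_csv(out / "control_estimates.csv", index=False)
        self.heterogeneity.to_csv(out / "heterogeneity.csv", index=False)
        pd.DataFrame([t.__dict__ for t in self.transitivity]).to_csv(
            out / "transitivity.csv", index=False)
        models = {f"{db}:{t}-{c}": {
            "mean_intercept": m.mean_intercept, "mean_slope": m.mean_slope,
            "log_sd_intercept": m.log_sd_intercept, "log_sd_slope": m.log_sd_slope,
            "n_controls": m.n_controls}
            for (db, t, c), m in self.error_models.items()}
        (out / "error_models.json").write_text(json.dumps(models, indent=1, sort_keys=True))
        manifest = dict(self.manifest)
        manifest["artifacts"] = ["estimates.csv", "control_estimates.csv", "heterogeneity.csv",
                                 "transitivity.csv", "error_models.json"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _skip_row(spec: StudySpec, db: str, reason: str) -> dict:
    return {"target_id": spec.target_id, "comparator_id": spec.comparator_id,
            "outcome_id": spec.outcome_id, "database_id": db,
            "tar_variant": spec.tar_variant, "skip_reason": reason}


def _estimate_with_shared_ps(dataset, spec, db, config, shared):
    """One cell using (and populating) the comparison's shared propensity scores."""
    pair = build_cohort_pair(dataset, spec)
    pair = compute_time_at_risk(pair, dataset, spec)
    if pair.is_empty:
        return None, None, "empty cohort"
    if not apply_min_cohort_size(pair, spec):
        return None, None, f"cohort below {spec.min_cohort_size} persons"
    key = (spec.target_id, spec.comparator_id)
    if key not in shared:
        # one propensity model per pair of exposures: fit on the comparison's
        # base cohort (entry rules without the outcome-specific exclusion),
        # of which every outcome- or control-specific cohort is a subset
        base_spec = dataclasses.replace(spec, outcome_id=-1)
        base_pair = build_cohort_pair(dataset, base_spec)
        matrix = build_covariates(dataset, base_pair, min_count=config.min_covariate_count)
        model = fit_propensity_model(matrix, seed=config.seed)
        ps_base = model.predict(matrix)
        shared[key] = dict(zip(base_pair.rows["person_id"], ps_base))
    ps = pair.rows["person_id"].map(shared[key]).to_numpy(float)
    if np.isnan(ps).any():
        # safety net: score stragglers with a fresh model on this pair
        matrix = build_covariates(dataset, pair, min_count=config.min_covariate_count)
        model = fit_propensity_model(matrix, seed=config.seed)
        ps = model.predict(matrix)
    strat = stratify_by_ps(pair, ps, config.n_strata)
    est = fit_stratified_cox(strat, target_id=spec.target_id, comparator_id=spec.comparator_id,
                             outcome_id=spec.outcome_id, database_id=db,
                             tar_variant=spec.tar_variant)
    if est is None:
        return None, (pair, strat), "no informative events"
    return est, (pair, strat), None


def run_study(config: StudyConfig, out_dir=None) -> EvidenceBundle:
    datasets = {db: simulate_population(cfg) for db, cfg in config.databases.items()}

    outcome_rows: list[dict] = []
    control_rows: list[dict] = []
    error_models: dict = {}

    for db, dataset in datasets.items():
        shared_ps: dict = {}
        for target, comparator in itertools.permutations(config.treatment_ids, 2):
            control_pairs: list[tuple[EffectEstimate, float]] = []

            # negative controls, sharing the comparison's propensity model
            for nc in config.negative_control_ids:
                spec = config.spec_for(target, comparator, nc)
                est, ctx, reason = _estimate_with_shared_ps(dataset, spec, db, config, shared_ps)
                if est is not None:
                    control_pairs.append((est, 0.0))
                    row = est.to_row()
                    row.update(kind="negative", true_hr=1.0, parent_outcome_id=None)
                    control_rows.append(row)
                # positive controls by injection into the target arm
                if ctx is None:
                    continue
                pair, strat = ctx
                events_total = int(pair.rows["outcome_date"].notna().sum())
                events_target = int(pair.rows.loc[pair.rows["arm"] == "target",
                                                  "outcome_date"].notna().sum())
                model_ok, inject_ok = controls.eligible_for_synthesis(
                    events_total, events_target, config.model_min, config.inject_min)
                if not (model_ok and inject_ok):
                    continue
                matrix = build_covariates(dataset, pair, min_count=config.min_covariate_count)
                try:
                    rate_model = controls.fit_outcome_rate_model(matrix, pair)
                except ValueError:
                    continue
                rates = rate_model.predict_rate(matrix)
                for hr in config.target_hrs:
                    inj_seed = (config.seed * 1_000_003 + nc * 101 + int(hr * 10)) % (2**31)
                    injected, cdef = controls.inject_outcomes(
                        pair, rates, hr, seed=inj_seed, parent_outcome_id=nc)
                    strat_inj = stratify_by_ps(injected, strat.rows["ps"].to_numpy(),
                                               config.n_strata)
                    est_pos = fit_stratified_cox(
                        strat_inj, target_id=target, comparator_id=comparator,
                        outcome_id=nc, database_id=db, tar_variant=config.tar_variant)
                    if est_pos is not None and np.isfinite(est_pos.se_log_hr):
                        control_pairs.append((est_pos, float(np.log(hr))))
                        row = est_pos.to_row()
                        row.update(kind="positive", true_hr=hr, parent_outcome_id=nc,
                                   achieved_hr=cdef.achieved_hr)
                        control_rows.append(row)

            if len(control_pairs) >= config.min_controls_for_calibration:
                try:
                    error_models[(db, target, comparator)] = \
                        calibration.fit_systematic_error_model(control_pairs, seed=config.seed)
                except (ValueError, RuntimeError) as exc:
                    log.warning("calibration model failed for %s %s-%s: %s",
                                db, target, comparator, exc)

            # outcomes of interest
            for outcome in config.outcome_ids:
                spec = config.spec_for(target, comparator, outcome)
                est, _, reason = _estimate_with_shared_ps(dataset, spec, db, config, shared_ps)
                if est is None:
                    outcome_rows.append(_skip_row(spec, db, reason))
                    continue
                row = est.to_row()
                row["skip_reason"] = None
                m = error_models.get((db, target, comparator))
                if m is not None and np.isfinite(est.se_log_hr):
                    try:
                        cal = calibration.calibrate_ci(est, m)
                        row["calibrated_log_hr"] = cal.calibrated_log_hr
                        row["calibrated_hr"] = cal.calibrated_hr
                        row["calibrated_ci95_lower"] = cal.calibrated_ci95[0]
                        row["calibrated_ci95_upper"] = cal.calibrated_ci95[1]
                    except ValueError as exc:
                        log.warning("calibration failed for cell %s: %s", row, exc)
                outcome_rows.append(row)

    estimates = pd.DataFrame.from_records(outcome_rows)
    control_estimates = pd.DataFrame.from_records(control_rows)
    for col in ("calibrated_log_hr", "calibrated_hr",
                "calibrated_ci95_lower", "calibrated_ci95_upper"):
        if col not in estimates.columns:
            estimates[col] = np.nan

    estimated = estimates[estimates["skip_reason"].isna()] if len(estimates) else estimates
    het = (synthesis.heterogeneity_table(estimated, require_all=len(config.databases))
           if len(estimated) else pd.DataFrame())
    triplets, fraction = (synthesis.find_transitivity_triplets(estimated)
                          if len(estimated) else ([], None))

    n_cells = (len(config.treatment_ids) * (len(config.treatment_ids) - 1)
               * len(config.outcome_ids) * len(config.databases))
    manifest = {
        "databases": list(config.databases), "n_treatments": len(config.treatment_ids),
        "n_outcomes": len(config.outcome_ids), "n_cells": n_cells,
        "n_rows": len(estimates), "n_estimated": int(estimates["skip_reason"].isna().sum()),
        "n_skipped": int(estimates["skip_reason"].notna().sum()),
        "n_control_estimates": len(control_estimates), "seed": config.seed,
    }
    assert manifest["n_rows"] == n_cells, "every cell must appear in the bundle"

    bundle = EvidenceBundle(estimates=estimates, control_estimates=control_estimates,
                            error_models=error_models, heterogeneity=het,
                            transitivity=triplets, transitivity_fraction=fraction,
                            manifest=manifest)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
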