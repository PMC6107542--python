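"""Negative-control registry and synthesis of positive controls by outcome injection.

Negative controls are outcomes believed to be caused by neither compared
treatment, so their true hazard ratio is 1; the curated list ships as a
packaged fixture. Positive controls are synthesized from a negative control by
injecting additional simulated occurrences of the outcome into one arm so that
the data-generating hazard ratio becomes a chosen target (1.5, 2 or 4). To
preserve measured confounding, injected events are sampled from a predictive
model of the outcome rate fitted on baseline covariates: a person's extra
events follow a Poisson process with rate ``(target_hr - 1)`` times the
person's predicted rate over their time-at-risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohorts import CohortPair
from .propensity import CovariateMatrix

__all__ = ["ControlDefinition", "OutcomeRateModel", "load_negative_controls",
           "positive_control_slots", "eligible_for_synthesis",
           "fit_outcome_rate_model", "inject_outcomes"]

log = logging.getLogger(__name__)

POSITIVE_TARGET_HRS = (1.5, 2.0, 4.0)


@dataclass(frozen=True)
class ControlDefinition:
    """A control hypothesis with known true hazard ratio.

    Negative controls have true_hr 1 and no parent; positive controls record
    the negative control they were synthesized from and the achieved
    (diagnostic) hazard ratio of expected events after injection.
    """

    outcome_id: int
    kind: str  # "negative" | "positive"
    true_hr: float
    name: str = ""
    parent_outcome_id: int | None = None
    achieved_hr: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "negative":
            if self.true_hr != 1.0 or self.parent_outcome_id is not None:
                raise ValueError("negative controls have true_hr 1 and no parent")
        elif self.kind == "positive":
            # registry-driven synthesis uses POSITIVE_TARGET_HRS; any HR > 1 is
            # a valid synthesized control (the limit HR -> 1 recovers the parent)
            if self.true_hr <= 1.0:
                raise ValueError("positive-control true_hr must exceed 1")
            if self.parent_outcome_id is None:
                raise ValueError("positive controls must reference a parent negative control")
        else:
            raise ValueError(f"unknown control kind {self.kind!r}")


def load_negative_controls(path=None) -> list[ControlDefinition]:
    """Load the negative-control registry (packaged fixture by default)."""
    if path is None:
        source = resources.files("evigrid.data") / "negative_controls.csv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if not {"concept_id", "name"} <= set(table.columns):
        raise ValueError("negative-control fixture must have concept_id and name columns")
    if table.empty:
        warnings.warn("negative-control registry is empty", stacklevel=2)
    return [ControlDefinition(outcome_id=int(r.concept_id), kind="negative",
                              true_hr=1.0, name=str(r.name_))
            for r in table.rename(columns={"name": "name_"}).itertuples(index=False)]


def positive_control_slots(registry: list[ControlDefinition],
                           target_hrs=POSITIVE_TARGET_HRS) -> list[tuple[int, float]]:
    """Every (parent negative control, target HR) synthesis slot for one comparison."""
    return [(c.outcome_id, hr) for c in registry if c.kind == "negative" for hr in target_hrs]


def eligible_for_synthesis(total_outcome_count: int, exposure_outcome_count: int,
                           model_min: int = 100, inject_min: int = 25) -> tuple[bool, bool]:
    """(model_ok, inject_ok) eligibility for positive-control synthesis.

    No outcome model is fitted below ``model_min`` persons with the outcome
    across all exposures (fitted models would be intercept-only); no injection
    is performed below ``inject_min`` persons with the outcome in the exposure
    receiving injection (to avoid rounding error in the true effect size).
    """
    if total_outcome_count < 0 or exposure_outcome_count < 0:
        raise ValueError("counts must be non-negative")
    return total_outcome_count >= model_min, exposure_outcome_count >= inject_min


@dataclass
class OutcomeRateModel:
    """Poisson model of a person's outcome rate per day at risk."""

    coefficients: dict[int, float]
    intercept: float

    def predict_rate(self, matrix: CovariateMatrix) -> np.ndarray:
        """Expected outcomes per person-day for each cohort row (constant over TAR)."""
        beta = np.zeros(matrix.n_covariates)
        ids = matrix.meta["covariate_id"].to_numpy()
        for j, cid in enumerate(ids):
            if cid in self.coefficients:
                beta[j] = self.coefficients[cid]
        return np.exp(np.clip(self.intercept + matrix.entries @ beta, -50.0, 0.0))


def _person_time_days(pair: CohortPair) -> np.ndarray:
    rows = pair.rows
    end = rows["outcome_date"].fillna(rows["tar_end"])
    return np.maximum((end - rows["tar_start"]).dt.days.to_numpy(float), 0.0)


def fit_outcome_rate_model(matrix: CovariateMatrix, pair: CohortPair,
                           alpha: float = 1e-4) -> OutcomeRateModel:
    """Fit the outcome-rate model on the comparison's own cohort.

    Uses the same baseline covariates as the propensity model; the response is
    the first-event count over each person's time-at-risk, fitted as a Poisson
    GLM with a log person-time offset. ``alpha`` is a small L2 penalty applied
    only if the unpenalized IRLS fit fails (separation or collinearity).
    """
    rows = pair.rows
    y_count = rows["outcome_date"].notna().to_numpy(float)
    exposure = _person_time_days(pair)
    usable = exposure > 0
    if y_count[usable].sum() == 0:
        raise ValueError("cannot fit an outcome rate model with zero events")
    x = np.asarray(matrix.entries[usable].todense())
    design = sm.add_constant(x, has_constant="add")
    glm = sm.GLM(y_count[usable], design, family=sm.families.Poisson(),
                 offset=np.log(exposure[usable]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = glm.fit(maxiter=200)
            params = np.asarray(res.params)
        except Exception:  # fall back to ridge-penalized fit
            res = glm.fit_regularized(alpha=alpha, L1_wt=0.0, maxiter=200)
            params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        res = glm.fit_regularized(alpha=alpha, L1_wt=0.0, maxiter=200)
        params = np.asarray(res.params)
    coefs = params[1:]
    nz = np.nonzero(coefs)[0]
    coefficients = {int(matrix.meta["covariate_id"].iloc[j]): float(coefs[j]) for j in nz}
    return OutcomeRateModel(coefficients=coefficients, intercept=float(params[0]))


def inject_outcomes(pair: CohortPair, rates_per_day: np.ndarray, target_hr: float,
                    seed: int, parent_outcome_id: int = -1, outcome_id: int | None = None,
                    arm: str = "target") -> tuple[CohortPair, ControlDefinition]:
    """Synthesize a positive control by injecting outcomes into one arm.

    For each person in the injected arm, extra events arrive as a Poisson
    process with rate ``(target_hr - 1) * rates_per_day[i]`` over the person's
    time-at-risk; the person's outcome date becomes the earliest of the
    original and injected events (first-event analysis; at most one injected
    event is retained, snapped to the day grid). The other arm is untouched,
    so covariate balance diagnostics are unchanged. When the rate model is
    correct the data-generating hazard ratio of the modified outcome equals
    ``target_hr``.
    """
    if target_hr <= 1.0:
        raise ValueError("target_hr must exceed 1")
    rows = pair.rows.copy()
    rates = np.asarray(rates_per_day, dtype=float)
    if len(rates) != len(rows):
        raise ValueError("one predicted rate per cohort row is required")
    rng = np.random.default_rng(seed)
    in_arm = (rows["arm"] == arm).to_numpy()
    tar_days = np.maximum((rows["tar_end"] - rows["tar_start"]).dt.days.to_numpy(float), 0.0)
    extra_rate = (target_hr - 1.0) * rates * tar_days
    n_extra = rng.poisson(np.where(in_arm, extra_rate, 0.0))
    inject = n_extra > 0
    # first arrival of a homogeneous Poisson process given N>=1 events in the
    # window: minimum of N uniforms
    u = rng.random(len(rows))
    first_frac = 1.0 - (1.0 - u) ** (1.0 / np.maximum(n_extra, 1))
    inj_day = np.ceil(first_frac * np.maximum(tar_days, 1.0)).astype(int)
    inj_date = rows["tar_start"] + pd.to_timedelta(inj_day, unit="D")
    new_outcome = rows["outcome_date"].copy()
    take = inject & (rows["outcome_date"].isna() | (inj_date < rows["outcome_date"])).to_numpy()
    new_outcome[take] = inj_date[take]
    rows["outcome_date"] = pd.to_datetime(np.minimum(
        new_outcome.to_numpy(dtype="datetime64[ns]"),
        rows["tar_end"].to_numpy(dtype="datetime64[ns]")))

    orig_events = float(pair.rows.loc[in_arm, "outcome_date"].notna().sum())
    injected_events = float((take & in_arm).sum())
    achieved = ((orig_events + injected_events) / orig_events) if orig_events > 0 else np.nan
    control = ControlDefinition(
        outcome_id=outcome_id if outcome_id is not None else parent_outcome_id,
        kind="positive", true_hr=float(target_hr), parent_outcome_id=parent_outcome_id,
        achieved_hr=float(achieved) if np.isfinite(achieved) else None)
    return CohortPair(rows=rows, spec=pair.spec), control
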