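"""Synthetic claims-data generation with known confounding and known true hazard ratios.

The generator emulates the raw material a comparative-cohort pipeline consumes:
an event-table bundle (persons with observation periods, drug eras, condition
occurrences) in the style of a common data model. Treatment choice depends on
binary baseline covariates through a (multinomial) logistic model, outcomes are
exponential time-to-event with covariate and treatment effects on the hazard,
and the same covariates are materialized as pre-index condition occurrences so
that a downstream covariate builder can rediscover them. Because the true
treatment effect of every outcome is configured, the generator provides ground
truth for evaluating confounder adjustment and confidence-interval calibration.

It also supports sampling control estimates directly from an assumed
systematic-error distribution, bypassing the cohort pipeline, for testing the
calibration machinery in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

def _dt(x):
    # day-granular values normalized to pandas' ns datetimes
    return pd.to_datetime(x).astype("datetime64[ns]")


__all__ = [
    "SimulationConfig",
    "ClaimsDataset",
    "simulate_population",
    "simulate_control_estimates",
    "default_confounded_config",
]

AGE_BANDS = ["20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
             "50-54", "55-59", "60-64", "65-69", "70-74", "75-79"]

#: condition_concept_id of baseline covariate j is COVARIATE_CONCEPT_OFFSET + j
COVARIATE_CONCEPT_OFFSET = 1000


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic claims "database".

    Covariates are independent Bernoulli indicators with prevalences drawn
    uniformly from ``covariate_prevalence``. ``treatment_coefficients`` act on
    the log-odds of receiving the first drug in ``drug_ids`` (the exposed /
    target drug); ``outcome_coefficients`` act on the log hazard of each
    outcome. Covariates appearing in both maps are confounders.
    ``true_log_hr`` is the causal log hazard ratio of the first drug versus
    the others (0 for negative-control outcomes). Hazards are per person-day.
    """

    n_subjects: int = 20_000
    n_covariates: int = 200
    covariate_prevalence: tuple[float, float] = (0.02, 0.30)
    drug_ids: tuple[int, ...] = (1, 2)
    treatment_intercepts: tuple[float, ...] | None = None
    treatment_coefficients: Mapping[int, float] = field(default_factory=dict)
    outcome_coefficients: Mapping[int, Mapping[int, float]] = field(default_factory=dict)
    true_log_hr: Mapping[int, float] = field(default_factory=dict)
    baseline_hazard: float = 1e-4
    observation_window: tuple[str, str] = ("2008-01-01", "2014-12-31")
    washout_range: tuple[int, int] = (365, 1095)
    era_duration_mean: float = 180.0
    gap_probability: float = 0.2
    gap_day_range: tuple[int, int] = (1, 60)
    censoring_rate: float = 1.0 / 730.0
    prior_outcome_probability: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.covariate_prevalence
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("covariate_prevalence must be a range within [0, 1]")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.n_covariates < 1:
            raise ConfigurationError("at least one covariate is required")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censoring_rate <= 0:
            raise ConfigurationError("censoring_rate must be positive")
        if len(self.drug_ids) < 2:
            raise ConfigurationError("at least two drugs are required")
        if not (0.0 <= self.gap_probability <= 1.0):
            raise ConfigurationError("gap_probability must be a probability")
        if not (0.0 <= self.prior_outcome_probability <= 1.0):
            raise ConfigurationError("prior_outcome_probability must be a probability")
        if self.treatment_intercepts is not None and len(self.treatment_intercepts) != len(self.drug_ids):
            raise ConfigurationError("one intercept per drug is required")

    @property
    def outcome_ids(self) -> list[int]:
        ids = set(self.true_log_hr) | set(self.outcome_coefficients)
        return sorted(ids)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        # JSON objects key on strings; round-trip restores int keys
        d["treatment_coefficients"] = {str(k): v for k, v in self.treatment_coefficients.items()}
        d["outcome_coefficients"] = {
            str(k): {str(j): v for j, v in m.items()} for k, m in self.outcome_coefficients.items()
        }
        d["true_log_hr"] = {str(k): v for k, v in self.true_log_hr.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        d["treatment_coefficients"] = {int(k): v for k, v in d["treatment_coefficients"].items()}
        d["outcome_coefficients"] = {
            int(k): {int(j): v for j, v in m.items()} for k, m in d["outcome_coefficients"].items()
        }
        d["true_log_hr"] = {int(k): v for k, v in d["true_log_hr"].items()}
        for key in ("covariate_prevalence", "drug_ids", "observation_window",
                    "washout_range", "gap_day_range"):
            d[key] = tuple(d[key])
        if d.get("treatment_intercepts") is not None:
            d["treatment_intercepts"] = tuple(d["treatment_intercepts"])
        return cls(**d)


@dataclass
class ClaimsDataset:
    """Three event tables mirroring the core roles of a claims common data model.

    ``persons``: person_id, age_group, gender, observation_start, observation_end.
    ``drug_eras``: person_id, drug_concept_id, era_start, era_end.
    ``condition_occurrences``: person_id, condition_concept_id, occurrence_date.
    All dates are day-granular pandas Timestamps. ``truth`` optionally carries
    the simulation ground truth (covariate matrix, assigned drug) for
    diagnostics; it is never serialized.
    """

    persons: pd.DataFrame
    drug_eras: pd.DataFrame
    condition_occurrences: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> None:
        p = self.persons.set_index("person_id")
        for table, start_col, end_col in (
            (self.drug_eras, "era_start", "era_end"),
            (self.condition_occurrences, "occurrence_date", "occurrence_date"),
        ):
            if not table["person_id"].isin(p.index).all():
                raise ValueError("event table references unknown person_id")
            obs_start = p.loc[table["person_id"], "observation_start"].to_numpy()
            obs_end = p.loc[table["person_id"], "observation_end"].to_numpy()
            if (table[start_col].to_numpy() < obs_start).any() or (
                table[end_col].to_numpy() > obs_end
            ).any():
                raise ValueError("event outside its person's observation period")
        if (self.drug_eras["era_start"] > self.drug_eras["era_end"]).any():
            raise ValueError("era_start after era_end")

    def write_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(directory / "persons.csv", index=False)
        self.drug_eras.to_csv(directory / "drug_eras.csv", index=False)
        self.condition_occurrences.to_csv(directory / "condition_occurrences.csv", index=False)

    @classmethod
    def read_csv(cls, directory: str | Path) -> "ClaimsDataset":
        directory = Path(directory)
        persons = pd.read_csv(directory / "persons.csv",
                              parse_dates=["observation_start", "observation_end"])
        eras = pd.read_csv(directory / "drug_eras.csv", parse_dates=["era_start", "era_end"])
        occ = pd.read_csv(directory / "condition_occurrences.csv", parse_dates=["occurrence_date"])
        return cls(persons=persons, drug_eras=eras, condition_occurrences=occ)


def simulate_population(config: SimulationConfig) -> ClaimsDataset:
    """Draw one synthetic claims database from ``config``.

    Treatment assignment: multinomial logit over ``config.drug_ids`` in which
    the covariate coefficients load on the first drug's utility; with two
    drugs this is exactly a logistic model for receiving the first drug.
    Outcome k has per-day hazard
    ``baseline_hazard * exp(x'beta_k + 1[first drug] * true_log_hr_k)``;
    the first event inside follow-up is materialized as a condition
    occurrence. Baseline covariates are materialized as condition occurrences
    on or before the index date, and follow-up ends at an exponentially
    distributed censoring time. Fixing ``config`` (including its seed) makes
    the output reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_covariates
    window_start = np.datetime64(config.observation_window[0], "D")
    window_end = np.datetime64(config.observation_window[1], "D")
    window_days = int((window_end - window_start) / np.timedelta64(1, "D"))
    if window_days < 1:
        raise ConfigurationError("observation_window must span at least two days")

    lo, hi = config.covariate_prevalence
    prevalence = rng.uniform(lo, hi, size=p)
    X = (rng.random((n, p)) < prevalence[None, :]).astype(np.int8)

    beta_t = np.zeros(p)
    for j, v in config.treatment_coefficients.items():
        beta_t[j] = v
    k = len(config.drug_ids)
    intercepts = np.asarray(config.treatment_intercepts if config.treatment_intercepts is not None
                            else np.zeros(k), dtype=float)
    utilities = np.tile(intercepts, (n, 1))
    utilities[:, 0] += X @ beta_t
    utilities -= utilities.max(axis=1, keepdims=True)
    probs = np.exp(utilities)
    probs /= probs.sum(axis=1, keepdims=True)
    # inverse-CDF draw keeps a single uniform per subject (reproducibility)
    u = rng.random(n)
    drug_index = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    drug = np.asarray(config.drug_ids)[drug_index]
    exposed = drug_index == 0

    index_offset = rng.integers(0, window_days + 1, size=n)
    index_date = window_start + index_offset.astype("timedelta64[D]")
    washout = rng.integers(config.washout_range[0], config.washout_range[1] + 1, size=n)
    obs_start = index_date - washout.astype("timedelta64[D]")
    follow_days = np.maximum(1, np.ceil(rng.exponential(1.0 / config.censoring_rate, size=n))).astype(int)
    obs_end = index_date + follow_days.astype("timedelta64[D]")

    persons = pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "age_group": rng.choice(AGE_BANDS, size=n),
        "gender": rng.choice(["F", "M"], size=n),
        "observation_start": _dt(obs_start),
        "observation_end": _dt(obs_end),
    })

    # drug eras relative to index, optionally split by a gap
    dur1 = np.maximum(1, np.round(rng.exponential(config.era_duration_mean, size=n))).astype(int)
    has_gap = rng.random(n) < config.gap_probability
    gap = rng.integers(config.gap_day_range[0], config.gap_day_range[1] + 1, size=n)
    dur2 = np.maximum(1, np.round(rng.exponential(config.era_duration_mean, size=n))).astype(int)

    era_rows = []
    e1_end = np.minimum(dur1, follow_days)
    era_rows.append(pd.DataFrame({
        "person_id": persons["person_id"],
        "drug_concept_id": drug,
        "era_start": _dt(index_date),
        "era_end": _dt(index_date + e1_end.astype("timedelta64[D]")),
    }))
    second = has_gap & (dur1 + gap < follow_days)
    if second.any():
        s2 = (dur1 + gap)[second]
        e2 = np.minimum(dur1 + gap + dur2, follow_days)[second]
        era_rows.append(pd.DataFrame({
            "person_id": persons["person_id"].to_numpy()[second],
            "drug_concept_id": drug[second],
            "era_start": _dt(index_date[second] + s2.astype("timedelta64[D]")),
            "era_end": _dt(index_date[second] + e2.astype("timedelta64[D]")),
        }))
    drug_eras = (pd.concat(era_rows, ignore_index=True)
                 .sort_values(["person_id", "era_start"], kind="stable")
                 .reset_index(drop=True))

    occ_frames = []
    # baseline covariates as pre-index condition occurrences
    subj, cov = np.nonzero(X)
    offsets = rng.integers(0, washout[subj] + 1)
    occ_frames.append(pd.DataFrame({
        "person_id": subj + 1,
        "condition_concept_id": COVARIATE_CONCEPT_OFFSET + cov,
        "occurrence_date": _dt(index_date[subj] - offsets.astype("timedelta64[D]")),
    }))

    for outcome_id in config.outcome_ids:
        beta_o = np.zeros(p)
        for j, v in config.outcome_coefficients.get(outcome_id, {}).items():
            beta_o[j] = v
        theta = config.true_log_hr.get(outcome_id, 0.0)
        lam = config.baseline_hazard * np.exp(X @ beta_o + theta * exposed)
        t = rng.exponential(1.0 / lam)
        day = np.floor(t).astype(int) + 1  # first full day after index
        hit = day <= follow_days
        if hit.any():
            occ_frames.append(pd.DataFrame({
                "person_id": persons["person_id"].to_numpy()[hit],
                "condition_concept_id": outcome_id,
                "occurrence_date": _dt(index_date[hit] + day[hit].astype("timedelta64[D]")),
            }))
        prior = rng.random(n) < config.prior_outcome_probability
        if prior.any():
            back = rng.integers(1, washout[prior] + 1)
            occ_frames.append(pd.DataFrame({
                "person_id": persons["person_id"].to_numpy()[prior],
                "condition_concept_id": outcome_id,
                "occurrence_date": _dt(index_date[prior] - back.astype("timedelta64[D]")),
            }))

    condition_occurrences = (pd.concat(occ_frames, ignore_index=True)
                             .sort_values(["person_id", "condition_concept_id", "occurrence_date"],
                                          kind="stable")
                             .reset_index(drop=True))

    truth = {"covariates": X, "prevalence": prevalence, "drug": drug,
             "exposed": exposed, "index_date": _dt(index_date)}
    return ClaimsDataset(persons=persons, drug_eras=drug_eras,
                         condition_occurrences=condition_occurrences, truth=truth)


def simulate_control_estimates(model, true_log_hrs: Sequence[float],
                               standard_errors: Sequence[float], seed: int):
    """Sample control effect estimates from an assumed systematic-error model.

    Each observed log hazard ratio is drawn as
    ``theta + Normal(mean(theta), sd(theta)^2) + Normal(0, se^2)`` where the
    systematic-error mean and log-SD are linear in the true log HR ``theta``
    (see :class:`evigrid.calibration.SystematicErrorModel`). Returns a list of
    :class:`evigrid.estimation.EffectEstimate` carrying the observed log HR
    and its nominal standard error.
    """
    from .estimation import EffectEstimate

    theta = np.asarray(true_log_hrs, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if theta.shape != se.shape:
        raise ValueError("true_log_hrs and standard_errors must have equal length")
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    rng = np.random.default_rng(seed)
    mean = model.mean_intercept + model.mean_slope * theta
    sd = np.exp(model.log_sd_intercept + model.log_sd_slope * theta)
    observed = theta + rng.normal(mean, sd) + rng.normal(0.0, se)
    out = []
    for i, (y, s) in enumerate(zip(observed, se)):
        out.append(EffectEstimate.from_log_hr(
            log_hr=float(y), se_log_hr=float(s),
            target_id=-1, comparator_id=-1, outcome_id=i, database_id="simulated"))
    return out


def default_confounded_config(n_subjects: int = 20_000, n_covariates: int = 200,
                              n_confounders: int = 20, outcome_ids: Sequence[int] = (218,),
                              true_log_hr: Mapping[int, float] | None = None,
                              effect: float = float(np.log(2.0)),
                              seed: int = 0, **overrides) -> SimulationConfig:
    """A confounded two-arm study configuration used throughout the tests.

    The first ``n_confounders`` covariates carry log-odds effects of
    alternating sign and magnitude ``effect`` on treatment choice and the same
    pattern of log-hazard effects on every outcome, so unadjusted comparisons
    are biased while the confounding is fully measured.
    """
    signs = np.where(np.arange(n_confounders) % 2 == 0, 1.0, -1.0)
    t_coef = {j: float(effect * signs[j]) for j in range(n_confounders)}
    o_coef = {oid: {j: float(effect * signs[j]) for j in range(n_confounders)}
              for oid in outcome_ids}
    hr = dict(true_log_hr or {oid: 0.0 for oid in outcome_ids})
    return SimulationConfig(
        n_subjects=n_subjects, n_covariates=n_covariates,
        treatment_coefficients=t_coef, outcome_coefficients=o_coef,
        true_log_hr=hr, seed=seed, **overrides)
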