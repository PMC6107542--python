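import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import evigrid as eg

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def confounded_dataset():
    """Small confounded two-arm claims database with one true-HR-2 outcome
    (id 218), one confounded null outcome (301), and a second null (302)."""
    cfg = eg.simulate.default_confounded_config(
        n_subjects=4000, n_covariates=25, n_confounders=8,
        outcome_ids=(218, 301, 302),
        true_log_hr={218: float(np.log(2)), 301: 0.0, 302: 0.0},
        baseline_hazard=8e-4, seed=11)
    return cfg, eg.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_spec():
    return eg.StudySpec(target_id=1, comparator_id=2, outcome_id=218, min_cohort_size=100)


@pytest.fixture(scope="session")
def small_pair(confounded_dataset, small_spec):
    _, ds = confounded_dataset
    pair = eg.build_cohort_pair(ds, small_spec)
    return eg.compute_time_at_risk(pair, ds, small_spec)


def make_pair(times, events, arms, strata=None, start="2010-01-01"):
    """Build a StratifiedCohort directly from day-granular survival data."""
    start = pd.Timestamp(start)
    times = np.asarray(times)
    events = np.asarray(events, dtype=bool)
    rows = pd.DataFrame({
        "person_id": np.arange(1, len(times) + 1),
        "arm": np.where(np.asarray(arms) == 1, "target", "comparator"),
        "index_date": start,
        "tar_start": start,
        "tar_end": start + pd.to_timedelta(times, unit="D"),
        "outcome_date": pd.Series(
            [start + pd.Timedelta(days=int(t)) if e else pd.NaT
             for t, e in zip(times, events)]),
    })
    rows["ps"] = 0.5
    rows["stratum"] = 1 if strata is None else np.asarray(strata)
    from evigrid.propensity import StratifiedCohort
    return StratifiedCohort(rows=rows, n_strata=int(rows["stratum"].max()))
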