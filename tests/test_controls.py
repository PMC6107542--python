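import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import evigrid as eg
from evigrid import controls
from evigrid.propensity import CovariateMatrix


class TestRegistry:
    def test_packaged_registry_has_52_negative_controls(self):
        registry = eg.load_negative_controls()
        assert len(registry) == 52
        assert all(c.kind == "negative" and c.true_hr == 1.0 for c in registry)
        assert len({c.outcome_id for c in registry}) == 52

    def test_positive_control_slots_three_per_negative(self):
        registry = eg.load_negative_controls()
        slots = controls.positive_control_slots(registry)
        assert len(slots) == 52 * 3 == 156
        assert {hr for _, hr in slots} == {1.5, 2.0, 4.0}

    def test_empty_fixture_warns(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("concept_id,name\n")
        with pytest.warns(UserWarning):
            registry = eg.load_negative_controls(p)
        assert registry == []

    def test_malformed_fixture_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError):
            eg.load_negative_controls(p)

    def test_control_definition_invariants(self):
        with pytest.raises(ValueError):
            controls.ControlDefinition(outcome_id=1, kind="negative", true_hr=2.0)
        with pytest.raises(ValueError):
            controls.ControlDefinition(outcome_id=1, kind="positive", true_hr=2.0)
        with pytest.raises(ValueError):
            controls.ControlDefinition(outcome_id=1, kind="positive", true_hr=0.8,
                                       parent_outcome_id=2)


@pytest.mark.parametrize("total,exposure,expected", [
    (99, 50, (False, True)),
    (150, 24, (True, False)),
    (150, 25, (True, True)),
    (100, 25, (True, True)),
])
def test_synthesis_eligibility_thresholds(total, exposure, expected):
    assert controls.eligible_for_synthesis(total, exposure) == expected


def _uniform_pair(n, tar_days, p_outcome=0.0, seed=0, arm_frac=0.5):
    rng = np.random.default_rng(seed)
    start = pd.Timestamp("2010-01-01")
    arms = np.where(np.arange(n) < int(n * arm_frac), "target", "comparator")
    outcome = rng.random(n) < p_outcome
    rows = pd.DataFrame({
        "person_id": np.arange(1, n + 1), "arm": arms,
        "index_date": start, "tar_start": start,
        "tar_end": start + pd.Timedelta(days=tar_days),
        "outcome_date": pd.Series([
            start + pd.Timedelta(days=int(d)) if o else pd.NaT
            for o, d in zip(outcome, rng.integers(1, tar_days + 1, n))]),
    })
    return eg.CohortPair(rows=rows)


def _matrix(pair, x):
    meta = pd.DataFrame({"covariate_id": np.arange(x.shape[1]),
                         "name": [f"c{j}" for j in range(x.shape[1])], "domain": "condition"})
    return CovariateMatrix(entries=sp.csr_matrix(np.asarray(x, float)), meta=meta, pair=pair)


class TestOutcomeRateModel:
    def test_covariate_free_outcome_rate_recovered(self):
        n, days, p = 4000, 365, 0.05
        pair = _uniform_pair(n, days, p_outcome=p, seed=1)
        matrix = _matrix(pair, np.zeros((n, 1)))
        model = controls.fit_outcome_rate_model(matrix, pair)
        rates = model.predict_rate(matrix)
        # hazard implied by p events uniform over the window
        implied = pair.rows["outcome_date"].notna().sum() / (
            (pair.rows["outcome_date"].fillna(pair.rows["tar_end"])
             - pair.rows["tar_start"]).dt.days.sum())
        assert rates.std() < 1e-12
        assert rates.mean() == pytest.approx(implied, rel=0.05)

    def test_rate_ratio_for_carrier_covariate(self):
        """Outcome rate doubled for carriers of covariate 0: Poisson-regression
        closed form gives a predicted rate ratio of ~2."""
        n, days = 6000, 365
        rng = np.random.default_rng(2)
        carrier = rng.random(n) < 0.5
        base = 3e-4
        lam = np.where(carrier, 2 * base, base) * days
        outcome = rng.random(n) < 1 - np.exp(-lam)
        pair = _uniform_pair(n, days)
        rows = pair.rows.copy()
        day = rng.integers(1, days + 1, n)
        rows["outcome_date"] = pd.Series([
            pd.Timestamp("2010-01-01") + pd.Timedelta(days=int(d)) if o else pd.NaT
            for o, d in zip(outcome, day)])
        pair = eg.CohortPair(rows=rows)
        matrix = _matrix(pair, carrier[:, None].astype(float))
        model = controls.fit_outcome_rate_model(matrix, pair)
        rates = model.predict_rate(matrix)
        ratio = rates[carrier].mean() / rates[~carrier].mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_all_zero_outcomes_rejected(self):
        pair = _uniform_pair(100, 30, p_outcome=0.0)
        with pytest.raises(ValueError):
            controls.fit_outcome_rate_model(_matrix(pair, np.zeros((100, 1))), pair)


class TestInjection:
    def test_poisson_expectation_of_injected_events(self):
        """1000 target persons, 1 person-year each, rate 0.01/yr, target HR 2:
        expectation 10 injected events."""
        pair = _uniform_pair(1000, 365, p_outcome=0.0, arm_frac=1.0)
        rates = np.full(1000, 0.01 / 365)
        injected, cdef = controls.inject_outcomes(pair, rates, 2.0, seed=0)
        n_inj = injected.rows["outcome_date"].notna().sum()
        assert abs(n_inj - 10) <= 3 * np.sqrt(10)

    def test_continuity_near_hr_one(self):
        pair = _uniform_pair(2000, 365, p_outcome=0.05, seed=3)
        rates = np.full(2000, 0.05 / 365)
        injected, _ = controls.inject_outcomes(pair, rates, 1.0 + 1e-9, seed=0)
        pd.testing.assert_series_equal(injected.rows["outcome_date"],
                                       pair.rows["outcome_date"])

    def test_target_hr_at_most_one_rejected(self):
        pair = _uniform_pair(10, 30)
        with pytest.raises(ValueError):
            controls.inject_outcomes(pair, np.zeros(10), 1.0, seed=0)

    def test_comparator_arm_untouched(self):
        pair = _uniform_pair(1000, 365, p_outcome=0.05, seed=4)
        rates = np.full(1000, 0.05 / 365)
        injected, _ = controls.inject_outcomes(pair, rates, 4.0, seed=1)
        comp = pair.rows["arm"] == "comparator"
        pd.testing.assert_series_equal(injected.rows.loc[comp, "outcome_date"],
                                       pair.rows.loc[comp, "outcome_date"])

    def test_injection_preserves_covariate_balance(self, confounded_dataset, small_pair):
        """Injection touches only outcome dates, so balance diagnostics are
        byte-identical before and after."""
        _, ds = confounded_dataset
        matrix = eg.build_covariates(ds, small_pair, min_count=50)
        ps = eg.fit_propensity_model(matrix, seed=0).predict(matrix)
        rates = np.full(len(small_pair.rows), 1e-4)
        injected, _ = controls.inject_outcomes(
            eg.CohortPair(rows=matrix.pair.rows, spec=small_pair.spec), rates, 2.0, seed=2)
        strat_before = eg.stratify_by_ps(eg.CohortPair(rows=matrix.pair.rows), ps, 10)
        strat_after = eg.stratify_by_ps(injected, ps, 10)
        before = eg.compute_balance(matrix, strat_before).table
        after = eg.compute_balance(matrix, strat_after).table
        pd.testing.assert_frame_equal(before, after)

    def test_injected_first_event_ratio_converges_to_target(self):
        """With uniform rates and no original events in the comparator scale,
        the per-person-time first-event ratio approaches the target HR."""
        n, days, base = 20_000, 365, 2e-4
        rng = np.random.default_rng(5)
        pair = _uniform_pair(n, days, p_outcome=0.0)
        # original events at rate `base` in both arms
        t = rng.exponential(1 / base, n)
        has = t < days
        rows = pair.rows.copy()
        rows.loc[has, "outcome_date"] = (pd.Timestamp("2010-01-01")
                                         + pd.to_timedelta(np.ceil(t[has]), unit="D"))
        pair = eg.CohortPair(rows=rows)
        injected, _ = controls.inject_outcomes(pair, np.full(n, base), 2.0, seed=6)
        out = injected.rows
        tmask = (out["arm"] == "target").to_numpy()
        ptime = (out["outcome_date"].fillna(out["tar_end"]) - out["tar_start"]).dt.days
        rate_t = out.loc[tmask, "outcome_date"].notna().sum() / ptime[tmask].sum()
        rate_c = out.loc[~tmask, "outcome_date"].notna().sum() / ptime[~tmask].sum()
        assert rate_t / rate_c == pytest.approx(2.0, rel=0.1)
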