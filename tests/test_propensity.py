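import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import evigrid as eg
from evigrid.propensity import (BalanceReport, CovariateMatrix, compute_balance,
                                fit_propensity_model, stratify_by_ps)
from evigrid.simulate import COVARIATE_CONCEPT_OFFSET


@pytest.fixture(scope="module")
def small_matrix(confounded_dataset, small_pair):
    _, ds = confounded_dataset
    return eg.build_covariates(ds, small_pair, min_count=50)


def _matrix_from_dense(x, arms):
    rows = pd.DataFrame({
        "person_id": np.arange(1, len(x) + 1),
        "arm": np.where(np.asarray(arms) == 1, "target", "comparator"),
        "index_date": pd.Timestamp("2010-01-01"),
        "tar_start": pd.Timestamp("2010-01-01"),
        "tar_end": pd.Timestamp("2010-12-31"),
        "outcome_date": pd.NaT,
    })
    meta = pd.DataFrame({"covariate_id": np.arange(x.shape[1]),
                         "name": [f"c{j}" for j in range(x.shape[1])],
                         "domain": "condition"})
    return CovariateMatrix(entries=sp.csr_matrix(np.asarray(x, float)), meta=meta,
                           pair=eg.CohortPair(rows=rows))


class TestBuildCovariates:
    @pytest.mark.parametrize("n_carriers,present", [(99, False), (100, True)])
    def test_low_count_covariates_discarded_at_threshold(self, confounded_dataset,
                                                         small_pair, n_carriers, present):
        _, ds = confounded_dataset
        rare_id = 999_999
        carriers = small_pair.rows["person_id"].head(n_carriers)
        extra = pd.DataFrame({
            "person_id": carriers,
            "condition_concept_id": rare_id,
            "occurrence_date": pd.Timestamp("2005-01-02"),
        })
        ds2 = eg.ClaimsDataset(
            persons=ds.persons.assign(
                observation_start=ds.persons["observation_start"].clip(
                    upper=pd.Timestamp("2005-01-01"))),
            drug_eras=ds.drug_eras,
            condition_occurrences=pd.concat([ds.condition_occurrences, extra]))
        matrix = eg.build_covariates(ds2, small_pair, min_count=100)
        assert (rare_id in set(matrix.meta["covariate_id"])) is present

    def test_treatment_drugs_never_included(self, small_matrix, small_spec):
        drug_covs = small_matrix.meta[small_matrix.meta["domain"] == "drug"]
        assert small_spec.target_id not in set(drug_covs["covariate_id"])
        assert small_spec.comparator_id not in set(drug_covs["covariate_id"])

    def test_values_predate_index(self, confounded_dataset, small_matrix):
        """A person with no pre-index events has only demographic indicators."""
        _, ds = confounded_dataset
        demo = (small_matrix.meta["domain"] == "demographics").to_numpy()
        x = small_matrix.entries.toarray()
        # demographic one-hots: every row has an age band, gender, year, month
        assert (x[:, demo].sum(axis=1) >= 4).all()

    def test_confounders_recovered_from_event_tables(self, confounded_dataset, small_matrix):
        """The simulated covariates reappear as condition indicators whose
        prevalence matches the generating truth."""
        cfg, ds = confounded_dataset
        cond = small_matrix.meta["covariate_id"] == COVARIATE_CONCEPT_OFFSET  # covariate 0
        assert cond.sum() == 1
        j = int(np.nonzero(cond.to_numpy())[0][0])
        persons = small_matrix.pair.rows["person_id"].to_numpy() - 1
        truth = ds.truth["covariates"][persons, 0]
        got = small_matrix.entries[:, j].toarray().ravel()
        assert np.array_equal(got > 0, truth > 0)


class TestPropensityModel:
    def test_uninformative_covariates_give_flat_scores(self):
        rng = np.random.default_rng(0)
        x = rng.random((800, 10)) < 0.3
        arms = rng.random(800) < 0.5
        m = _matrix_from_dense(x, arms)
        model = fit_propensity_model(m, seed=0)
        ps = model.predict(m)
        # AUC near one half: covariates carry no information about the arm
        from sklearn.metrics import roc_auc_score
        assert abs(roc_auc_score(arms, ps) - 0.5) < 0.08

    def test_deterministic_assignment_is_separable(self):
        rng = np.random.default_rng(1)
        x = (rng.random((400, 5)) < 0.5).astype(float)
        arms = x[:, 2] == 1
        m = _matrix_from_dense(x, arms)
        ps = fit_propensity_model(m, seed=0).predict(m)
        # exhaustive rank check: every arm-1 subject scores above every arm-0
        assert ps[arms].min() > ps[~arms].max()

    def test_duplicated_column_leaves_predictions_invariant(self):
        rng = np.random.default_rng(2)
        x = (rng.random((600, 6)) < 0.4).astype(float)
        logit = x[:, 0] - x[:, 1]
        arms = rng.random(600) < 1 / (1 + np.exp(-logit))
        m1 = _matrix_from_dense(x, arms)
        m2 = _matrix_from_dense(np.hstack([x, x[:, [0]]]), arms)
        p1 = fit_propensity_model(m1, seed=0).predict(m1)
        p2 = fit_propensity_model(m2, seed=0).predict(m2)
        assert np.allclose(p1, p2, atol=0.02)

    def test_single_arm_rejected(self):
        x = np.ones((50, 2))
        m = _matrix_from_dense(x, np.ones(50))
        with pytest.raises(ValueError):
            fit_propensity_model(m)


class TestStratify:
    def test_uniform_scores_split_evenly(self):
        rows = _matrix_from_dense(np.ones((100, 1)), np.arange(100) % 2).pair
        ps = (np.arange(100) + 0.5) / 100
        strat = stratify_by_ps(rows, ps, 10)
        assert (strat.rows.groupby("stratum").size() == 10).all()

    def test_constant_scores_collapse_to_one_stratum(self):
        rows = _matrix_from_dense(np.ones((40, 1)), np.arange(40) % 2).pair
        strat = stratify_by_ps(rows, np.full(40, 0.5), 10)
        assert strat.rows["stratum"].nunique() == 1

    def test_stratification_preserves_rows(self):
        rows = _matrix_from_dense(np.ones((55, 1)), np.arange(55) % 2).pair
        ps = np.linspace(0.01, 0.99, 55)
        strat = stratify_by_ps(rows, ps, 7)
        assert len(strat.rows) == 55
        assert strat.rows["stratum"].between(1, 7).all()

    def test_invalid_strata_count_rejected(self):
        rows = _matrix_from_dense(np.ones((10, 1)), np.arange(10) % 2).pair
        with pytest.raises(ValueError):
            stratify_by_ps(rows, np.full(10, 0.5), 0)


class TestBalance:
    def _report(self, x, arms, strata):
        m = _matrix_from_dense(x, arms)
        strat = stratify_by_ps(m.pair, np.full(len(arms), 0.5), 1)
        strat.rows["stratum"] = strata
        return compute_balance(m, strat)

    def test_equal_prevalences_give_zero_sdm(self):
        x = np.zeros((100, 1))
        x[:15, 0] = 1   # 0.3 of target
        x[50:65, 0] = 1  # 0.3 of comparator
        arms = np.r_[np.ones(50), np.zeros(50)]
        rep = self._report(x, arms, np.ones(100))
        assert rep.table["sdm_before"].iloc[0] == pytest.approx(0.0)

    def test_closed_form_binary_sdm(self):
        """Prevalences 0.3 vs 0.2: SDM = 0.1/sqrt((0.21+0.16)/2) ~ 0.2325."""
        x = np.zeros((2000, 1))
        x[:300, 0] = 1       # 30% of 1000 target
        x[1000:1200, 0] = 1  # 20% of 1000 comparator
        arms = np.r_[np.ones(1000), np.zeros(1000)]
        rep = self._report(x, arms, np.ones(2000))
        expected = 0.1 / np.sqrt((0.3 * 0.7 + 0.2 * 0.8) / 2)
        assert rep.table["sdm_before"].iloc[0] == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(0.2325, abs=2e-4)

    def test_balanced_within_stratum_gives_zero_adjusted_sdm(self):
        # stratum 1 prevalence 0.8 in both arms, stratum 2 prevalence 0.2:
        # marginally imbalanced if arms occupy strata unevenly
        x = np.zeros((400, 1))
        arms = np.zeros(400)
        strata = np.r_[np.ones(200), np.full(200, 2)]
        arms[:150] = 1          # stratum 1: 150 target / 50 comparator
        arms[200:250] = 1       # stratum 2: 50 target / 150 comparator
        for s, prev in ((1, 0.8), (2, 0.2)):
            for arm in (0, 1):
                idx = np.nonzero((strata == s) & (arms == arm))[0]
                x[idx[:int(round(prev * len(idx)))], 0] = 1
        rep = self._report(x, arms, strata)
        assert abs(rep.table["sdm_after"].iloc[0]) < 1e-12
        assert abs(rep.table["sdm_before"].iloc[0]) > 0.1

    def test_sdm_antisymmetric_under_arm_swap(self):
        rng = np.random.default_rng(3)
        x = (rng.random((300, 4)) < 0.4).astype(float)
        arms = rng.random(300) < 0.5
        strata = rng.integers(1, 4, 300)
        a = self._report(x, arms, strata).table
        b = self._report(x, ~arms, strata).table
        assert np.allclose(a["sdm_before"], -b["sdm_before"])
        assert np.allclose(a["sdm_after"], -b["sdm_after"])

    def test_max_abs_helpers(self):
        rep = BalanceReport(table=pd.DataFrame({
            "covariate_id": [1, 2], "name": ["a", "b"],
            "sdm_before": [0.3, -0.5], "sdm_after": [0.01, -0.09], "flagged": False}))
        assert rep.max_abs_before == 0.5
        assert rep.max_abs_after == 0.09
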