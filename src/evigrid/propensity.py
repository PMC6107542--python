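"""Large-scale propensity modelling, decile stratification and balance diagnostics.

The propensity score is the probability of receiving the target rather than
the comparator drug given baseline covariates. Covariates are built from
everything observed on or before the index date — demographic buckets plus one
indicator per prior condition and drug concept — with low-count covariates
discarded. The score is fitted by L1-regularized logistic regression with the
penalty chosen by 10-fold cross-validated log-loss, and the pooled cohort is
stratified at the score's quantiles. Balance is reported as the standardized
difference of the mean (SDM) of every covariate before and after
stratification; |SDM| < 0.1 is the conventional adequacy criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .cohorts import CohortPair

__all__ = ["CovariateMatrix", "PropensityModel", "StratifiedCohort", "BalanceReport",
           "build_covariates", "fit_propensity_model", "stratify_by_ps", "compute_balance"]

log = logging.getLogger(__name__)


@dataclass
class CovariateMatrix:
    """Sparse person-by-covariate matrix anchored to a cohort pair.

    Row i corresponds to row i of ``pair.rows``. ``meta`` has one row per
    retained column: covariate_id, name, domain.
    """

    entries: sp.csr_matrix
    meta: pd.DataFrame
    pair: CohortPair

    @property
    def n_covariates(self) -> int:
        return self.entries.shape[1]

    def write_mtx(self, path) -> None:
        from scipy.io import mmwrite
        mmwrite(str(path), self.entries)


@dataclass
class PropensityModel:
    coefficients: dict[int, float]
    intercept: float
    selected_penalty: float
    estimator: object = field(repr=False, default=None)
    auc: float | None = None

    def predict(self, matrix: CovariateMatrix) -> np.ndarray:
        """Probability of target-arm membership for each cohort row."""
        return self.estimator.predict_proba(matrix.entries)[:, 1]


@dataclass
class StratifiedCohort:
    """Cohort rows augmented with the propensity score and stratum label (1-based)."""

    rows: pd.DataFrame  # CohortPair columns + ps + stratum
    n_strata: int


@dataclass
class BalanceReport:
    """Per-covariate standardized mean differences before/after stratification."""

    table: pd.DataFrame  # covariate_id, name, sdm_before, sdm_after, flagged

    @property
    def max_abs_before(self) -> float:
        return float(np.nanmax(np.abs(self.table["sdm_before"].to_numpy())))

    @property
    def max_abs_after(self) -> float:
        return float(np.nanmax(np.abs(self.table["sdm_after"].to_numpy())))


def build_covariates(dataset, pair: CohortPair, min_count: int = 100,
                     extra_numeric: pd.DataFrame | None = None) -> CovariateMatrix:
    """Construct baseline covariates for every cohort row.

    Demographics: one indicator per age band, gender, index year and index
    month. Event covariates: one indicator per condition concept occurring on
    or before index and per drug concept with an era starting before index
    (the compared treatments themselves are never included). Covariates with
    fewer than ``min_count`` non-zero values are discarded. ``extra_numeric``
    may supply precomputed numeric columns (e.g. risk scores) indexed like
    the cohort rows; they bypass nothing — the count filter applies equally.
    """
    rows = pair.rows.reset_index(drop=True)
    n = len(rows)
    row_of_person = pd.Series(np.arange(n), index=rows["person_id"].to_numpy())

    coo_r: list[np.ndarray] = []
    coo_c: list[np.ndarray] = []
    coo_v: list[np.ndarray] = []
    meta_rows: list[tuple[int, str, str]] = []

    def add_indicator(mask: np.ndarray, cov_id: int, name: str, domain: str) -> None:
        idx = np.nonzero(mask)[0]
        coo_r.append(idx)
        coo_c.append(np.full(len(idx), len(meta_rows)))
        coo_v.append(np.ones(len(idx)))
        meta_rows.append((cov_id, name, domain))

    persons = dataset.persons.set_index("person_id")
    age = persons.loc[rows["person_id"], "age_group"].to_numpy()
    gender = persons.loc[rows["person_id"], "gender"].to_numpy()
    next_id = 1
    for band in pd.unique(age):
        add_indicator(age == band, next_id, f"age {band}", "demographics"); next_id += 1
    for g in pd.unique(gender):
        add_indicator(gender == g, next_id, f"gender {g}", "demographics"); next_id += 1
    years = rows["index_date"].dt.year.to_numpy()
    for y in np.unique(years):
        add_indicator(years == y, next_id, f"index year {y}", "demographics"); next_id += 1
    months = rows["index_date"].dt.month.to_numpy()
    for m in np.unique(months):
        add_indicator(months == m, next_id, f"index month {m}", "demographics"); next_id += 1

    # prior condition occurrences (on or before index)
    occ = dataset.condition_occurrences
    occ = occ[occ["person_id"].isin(row_of_person.index)]
    occ = occ.merge(rows[["person_id", "index_date"]], on="person_id")
    occ = occ[occ["occurrence_date"] <= occ["index_date"]]
    for cid, grp in occ.groupby("condition_concept_id"):
        r = row_of_person.loc[grp["person_id"].unique()].to_numpy()
        coo_r.append(r)
        coo_c.append(np.full(len(r), len(meta_rows)))
        coo_v.append(np.ones(len(r)))
        meta_rows.append((int(cid), f"condition {cid}", "condition"))

    # prior drug eras, excluding the compared treatments
    excluded = set()
    if pair.spec is not None:
        excluded = {pair.spec.target_id, pair.spec.comparator_id}
    eras = dataset.drug_eras
    eras = eras[eras["person_id"].isin(row_of_person.index)
                & ~eras["drug_concept_id"].isin(excluded)]
    eras = eras.merge(rows[["person_id", "index_date"]], on="person_id")
    eras = eras[eras["era_start"] < eras["index_date"]]
    for did, grp in eras.groupby("drug_concept_id"):
        r = row_of_person.loc[grp["person_id"].unique()].to_numpy()
        coo_r.append(r)
        coo_c.append(np.full(len(r), len(meta_rows)))
        coo_v.append(np.ones(len(r)))
        meta_rows.append((int(did), f"drug {did}", "drug"))

    if extra_numeric is not None:
        for name in extra_numeric.columns:
            v = extra_numeric[name].to_numpy(dtype=float)
            idx = np.nonzero(v)[0]
            coo_r.append(idx)
            coo_c.append(np.full(len(idx), len(meta_rows)))
            coo_v.append(v[idx])
            meta_rows.append((-(len(meta_rows) + 1), name, "score"))

    m = len(meta_rows)
    mat = sp.coo_matrix(
        (np.concatenate(coo_v) if coo_v else np.array([]),
         (np.concatenate(coo_r) if coo_r else np.array([], dtype=int),
          np.concatenate(coo_c) if coo_c else np.array([], dtype=int))),
        shape=(n, m)).tocsr()

    nnz = mat.getnnz(axis=0)
    keep = nnz >= min_count
    meta = pd.DataFrame(meta_rows, columns=["covariate_id", "name", "domain"])
    return CovariateMatrix(entries=mat[:, keep], meta=meta[keep].reset_index(drop=True),
                           pair=CohortPair(rows=rows, spec=pair.spec))


def fit_propensity_model(matrix: CovariateMatrix, arms: np.ndarray | None = None,
                         n_folds: int = 10, n_penalties: int = 8,
                         seed: int = 0) -> PropensityModel:
    """Fit the L1 propensity model with cross-validated penalty selection.

    ``arms`` defaults to the anchored pair's arm labels (target = 1). The
    penalty grid is log-spaced; the value minimizing cross-validated log-loss
    is selected. Complete separation is absorbed by the penalty.
    """
    if arms is None:
        arms = (matrix.pair.rows["arm"] == "target").to_numpy()
    y = np.asarray(arms).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both arms must be present to fit a propensity model")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    est = LogisticRegressionCV(
        penalty="l1", solver="liblinear", Cs=np.logspace(-3, 2, n_penalties),
        cv=cv, scoring="neg_log_loss", max_iter=2000, refit=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter on tiny folds
        est.fit(matrix.entries, y)
    coefs = est.coef_.ravel()
    nz = np.nonzero(coefs)[0]
    coefficients = {int(matrix.meta["covariate_id"].iloc[j]): float(coefs[j]) for j in nz}
    return PropensityModel(
        coefficients=coefficients, intercept=float(est.intercept_[0]),
        selected_penalty=float(1.0 / est.C_[0]), estimator=est)


def stratify_by_ps(pair: CohortPair, ps: np.ndarray, n_strata: int = 10) -> StratifiedCohort:
    """Assign every cohort row to a stratum by pooled propensity-score quantiles.

    Boundaries sit at the k/n_strata quantiles of the pooled score; ties share
    a stratum, so a degenerate (constant) score yields a single stratum.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be at least 1")
    ps = np.asarray(ps, dtype=float)
    rows = pair.rows.reset_index(drop=True)
    if len(ps) != len(rows):
        raise ValueError("one propensity score per cohort row is required")
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("propensity scores must lie in [0, 1]")
    boundaries = np.quantile(ps, np.arange(1, n_strata) / n_strata)
    stratum = np.searchsorted(boundaries, ps, side="left") + 1
    rows = rows.copy()
    rows["ps"] = ps
    rows["stratum"] = stratum
    return StratifiedCohort(rows=rows, n_strata=n_strata)


def _arm_moments(x: sp.csr_matrix, mask: np.ndarray):
    sub = x[mask]
    n = sub.shape[0]
    mean = np.asarray(sub.mean(axis=0)).ravel()
    meansq = np.asarray(sub.power(2).mean(axis=0)).ravel()
    var = (meansq - mean ** 2) * (n / max(n - 1, 1))
    return mean, var, n


def compute_balance(matrix: CovariateMatrix, strat: StratifiedCohort) -> BalanceReport:
    """Standardized differences of the mean before and after stratification.

    sdm_before = (mean_T - mean_C) / sqrt((var_T + var_C)/2). sdm_after uses
    stratum-specific arm means weighted by each stratum's share of the pooled
    cohort, over the same pooled-variance denominator. Strata containing a
    single arm contribute nothing (logged). Zero-variance covariates get
    SDM 0 when the arm means agree and are flagged otherwise.
    """
    x = matrix.entries.tocsr()
    rows = strat.rows
    t_mask = (rows["arm"] == "target").to_numpy()
    c_mask = ~t_mask
    mean_t, var_t, _ = _arm_moments(x, t_mask)
    mean_c, var_c, _ = _arm_moments(x, c_mask)
    denom = np.sqrt((var_t + var_c) / 2.0)

    n_total = len(rows)
    adj_t = np.zeros(x.shape[1])
    adj_c = np.zeros(x.shape[1])
    used_weight = 0.0
    strata = rows["stratum"].to_numpy()
    for s in np.unique(strata):
        in_s = strata == s
        ts, cs = in_s & t_mask, in_s & c_mask
        if ts.sum() == 0 or cs.sum() == 0:
            log.warning("stratum %d contains a single arm; dropped from balance", s)
            continue
        w = in_s.sum() / n_total
        used_weight += w
        adj_t += w * np.asarray(x[ts].mean(axis=0)).ravel()
        adj_c += w * np.asarray(x[cs].mean(axis=0)).ravel()
    if used_weight > 0:
        adj_t /= used_weight
        adj_c /= used_weight

    with np.errstate(divide="ignore", invalid="ignore"):
        sdm_before = (mean_t - mean_c) / denom
        sdm_after = (adj_t - adj_c) / denom
    zero_var = denom == 0
    equal_before = np.isclose(mean_t, mean_c)
    equal_after = np.isclose(adj_t, adj_c)
    sdm_before[zero_var & equal_before] = 0.0
    sdm_after[zero_var & equal_after] = 0.0
    flagged = zero_var & ~(equal_before & equal_after)

    table = matrix.meta[["covariate_id", "name"]].copy()
    table["sdm_before"] = sdm_before
    table["sdm_after"] = sdm_after
    table["flagged"] = flagged
    return BalanceReport(table=table)
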