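"""Result-set consistency diagnostics: transitivity and between-database heterogeneity.

Transitivity: if drug A shows a statistically significant higher risk than
drug B for some outcome, and B shows a significant higher risk than C, then A
should show a significant higher risk than C. Significance defaults to the
calibrated 95% CI lower bound exceeding 1 (configurable to the nominal CI).

Heterogeneity: for a target-comparator-outcome question estimated in several
databases, Cochran's Q with inverse-variance weights and
I^2 = max(0, (Q - df)/Q), df = n_databases - 1; I^2 = 0 means no
between-database heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TripletResult", "HeterogeneityResult", "find_transitivity_triplets",
           "compute_i2", "heterogeneity_table"]


@dataclass(frozen=True)
class TripletResult:
    drug_a: int
    drug_b: int
    drug_c: int
    outcome_id: int
    database_id: str
    ac_exists: bool
    holds: bool | None  # defined only when ac_exists


@dataclass(frozen=True)
class HeterogeneityResult:
    target_id: int
    comparator_id: int
    outcome_id: int
    q: float
    df: int
    i2: float


def find_transitivity_triplets(estimates: pd.DataFrame, lower_col: str = "calibrated_ci95_lower"
                               ) -> tuple[list[TripletResult], float | None]:
    """Enumerate ordered triples (A, B, C) with A>B and B>C significant.

    ``estimates`` needs columns target_id, comparator_id, outcome_id,
    database_id and ``lower_col`` (CI lower bound on the HR scale). A pair is
    significant when its lower bound exceeds 1. Returns the triplet list and
    the fraction holding among triples whose A-vs-C estimate exists (None when
    no such triple exists).
    """
    results: list[TripletResult] = []
    for (outcome, db), grp in estimates.groupby(["outcome_id", "database_id"]):
        grp_sig = grp.dropna(subset=[lower_col])
        sig = {(int(r.target_id), int(r.comparator_id))
               for r in grp_sig.itertuples() if getattr(r, lower_col) > 1.0}
        exists = {(int(r.target_id), int(r.comparator_id)): getattr(r, lower_col)
                  for r in grp_sig.itertuples()}
        for (a, b) in sig:
            for (b2, c) in sig:
                if b2 != b or c == a:
                    continue
                ac = (a, c) in exists
                holds = (exists[(a, c)] > 1.0) if ac else None
                results.append(TripletResult(a, b, c, int(outcome), str(db), ac, holds))
    evaluable = [t for t in results if t.ac_exists]
    fraction = (sum(t.holds for t in evaluable) / len(evaluable)) if evaluable else None
    return results, fraction


def compute_i2(log_hrs, ses, target_id: int = -1, comparator_id: int = -1,
               outcome_id: int = -1) -> HeterogeneityResult:
    """Cochran's Q and I^2 for one question across databases (fixed-effect weights)."""
    theta = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(se) & (se > 0)
    theta, se = theta[ok], se[ok]
    if len(theta) < 2:
        raise ValueError("I^2 requires at least two finite estimates")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    i2 = 0.0 if q == 0.0 else max(0.0, (q - df) / q)
    return HeterogeneityResult(target_id=target_id, comparator_id=comparator_id,
                               outcome_id=outcome_id, q=q, df=df, i2=i2)


def heterogeneity_table(estimates: pd.DataFrame, log_hr_col: str = "log_hr",
                        se_col: str = "se_log_hr", require_all: int | None = None
                        ) -> pd.DataFrame:
    """I^2 per target-comparator-outcome question across databases.

    With ``require_all`` set, only questions estimated in exactly that many
    databases (the "sufficient data in all databases" rule) are kept.
    """
    records = []
    cols = ["target_id", "comparator_id", "outcome_id"]
    for key, grp in estimates.dropna(subset=[log_hr_col, se_col]).groupby(cols):
        if require_all is not None and grp["database_id"].nunique() != require_all:
            continue
        if len(grp) < 2:
            continue
        r = compute_i2(grp[log_hr_col], grp[se_col], *map(int, key))
        records.append({"target_id": r.target_id, "comparator_id": r.comparator_id,
                        "outcome_id": r.outcome_id, "q": r.q, "df": r.df, "i2": r.i2})
    return pd.DataFrame.from_records(
        records, columns=["target_id", "comparator_id", "outcome_id", "q", "df", "i2"])
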