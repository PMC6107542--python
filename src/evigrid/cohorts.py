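"""New-user cohort construction and time-at-risk definition.

Implements the comparative-cohort entry rules: new users of the target or
comparator drug (first-ever era is the index), a required washout of
continuous observation before index, exclusion of people ever exposed to both
drugs and of people with the outcome before index, and restriction of index
dates to the calendar interval when both drugs were recorded. Time-at-risk is
either on-treatment (eras stitched across gaps of at most ``era_gap_days``)
or intent-to-treat (until end of observation). All intervals are closed on
both ends and day-granular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StudySpec", "CohortPair", "build_cohort_pair",
           "compute_time_at_risk", "apply_min_cohort_size", "merge_eras"]


@dataclass(frozen=True)
class StudySpec:
    """One target-comparator-outcome research question with its design rules."""

    target_id: int
    comparator_id: int
    outcome_id: int
    washout_days: int = 365
    era_gap_days: int = 30
    tar_variant: str = "on-treatment"  # or "intent-to-treat"
    min_cohort_size: int = 2500

    def __post_init__(self) -> None:
        if self.target_id == self.comparator_id:
            raise ValueError("target and comparator must differ")
        if self.washout_days < 0:
            raise ValueError("washout_days must be non-negative")
        if self.tar_variant not in ("on-treatment", "intent-to-treat"):
            raise ValueError(f"unknown tar_variant {self.tar_variant!r}")


@dataclass
class CohortPair:
    """Row-per-person cohort table for one target/comparator comparison.

    Columns: person_id, arm ('target'/'comparator'), index_date, tar_start,
    tar_end, outcome_date (NaT when no outcome inside the time-at-risk).
    """

    rows: pd.DataFrame
    spec: StudySpec | None = None

    COLUMNS = ["person_id", "arm", "index_date", "tar_start", "tar_end", "outcome_date"]

    @property
    def n_target(self) -> int:
        return int((self.rows["arm"] == "target").sum())

    @property
    def n_comparator(self) -> int:
        return int((self.rows["arm"] == "comparator").sum())

    @property
    def is_empty(self) -> bool:
        return self.n_target == 0 or self.n_comparator == 0

    def write_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, spec: StudySpec | None = None) -> "CohortPair":
        rows = pd.read_csv(path, parse_dates=["index_date", "tar_start", "tar_end", "outcome_date"])
        return cls(rows=rows, spec=spec)


def _first_eras(drug_eras: pd.DataFrame, drug_id: int) -> pd.DataFrame:
    eras = drug_eras[drug_eras["drug_concept_id"] == drug_id]
    first = (eras.sort_values(["person_id", "era_start"], kind="stable")
             .groupby("person_id", as_index=False).first())
    return first


def build_cohort_pair(dataset, spec: StudySpec) -> CohortPair:
    """Apply the new-user entry rules; an empty arm is a signal, not an error.

    Exclusions (order-invariant): persons ever exposed to both drugs; persons
    with less than ``washout_days`` of observation before index; persons with
    an occurrence of the outcome strictly before index; persons whose index
    date falls outside the calendar interval during which both drugs have
    recorded era starts.
    """
    eras = dataset.drug_eras
    target_first = _first_eras(eras, spec.target_id)
    comparator_first = _first_eras(eras, spec.comparator_id)

    both = set(target_first["person_id"]) & set(comparator_first["person_id"])

    frames = []
    for arm, first in (("target", target_first), ("comparator", comparator_first)):
        f = first[~first["person_id"].isin(both)].copy()
        f["arm"] = arm
        f = f.rename(columns={"era_start": "index_date"})
        frames.append(f[["person_id", "arm", "index_date"]])
    rows = pd.concat(frames, ignore_index=True)

    # calendar overlap of the two drugs' recorded era starts
    starts_t = eras.loc[eras["drug_concept_id"] == spec.target_id, "era_start"]
    starts_c = eras.loc[eras["drug_concept_id"] == spec.comparator_id, "era_start"]
    if len(starts_t) and len(starts_c):
        overlap_lo = max(starts_t.min(), starts_c.min())
        overlap_hi = min(starts_t.max(), starts_c.max())
        rows = rows[(rows["index_date"] >= overlap_lo) & (rows["index_date"] <= overlap_hi)]
    else:
        rows = rows.iloc[0:0]

    persons = dataset.persons.set_index("person_id")
    obs_start = persons.loc[rows["person_id"], "observation_start"].to_numpy()
    obs_end = persons.loc[rows["person_id"], "observation_end"].to_numpy()
    observed_days = (rows["index_date"].to_numpy() - obs_start) / np.timedelta64(1, "D")
    rows = rows[(observed_days >= spec.washout_days)
                & (rows["index_date"].to_numpy() <= obs_end)]

    occ = dataset.condition_occurrences
    outcome_occ = occ[occ["condition_concept_id"] == spec.outcome_id]
    first_outcome = outcome_occ.groupby("person_id")["occurrence_date"].min()
    prior = pd.Series(first_outcome.reindex(rows["person_id"]).to_numpy(), index=rows.index)
    had_prior = (prior < rows["index_date"]).fillna(False).to_numpy()
    rows = rows[~had_prior]

    rows = rows.reset_index(drop=True)
    rows["tar_start"] = rows["index_date"]
    rows["tar_end"] = rows["index_date"]
    rows["outcome_date"] = pd.NaT
    return CohortPair(rows=rows[CohortPair.COLUMNS], spec=spec)


def merge_eras(starts: np.ndarray, ends: np.ndarray, gap_days: int):
    """Merge sorted closed day-granular intervals separated by <= gap_days.

    Idempotent; returns non-overlapping (starts, ends). Inputs must be sorted
    by start.
    """
    if len(starts) == 0:
        return starts, ends
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - out_e[-1]) / np.timedelta64(1, "D") <= gap_days:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def compute_time_at_risk(pair: CohortPair, dataset, spec: StudySpec | None = None) -> CohortPair:
    """Fill tar_end and outcome_date for every cohort row.

    On-treatment: tar_end is the end of the stitched era chain containing the
    index era (successive eras of the person's own drug merged when separated
    by at most ``era_gap_days``), truncated at observation end. Intent-to-treat:
    tar_end is the observation end. outcome_date is the first occurrence of
    the outcome inside [tar_start, tar_end]. Zero-length rows are retained.
    """
    spec = spec or pair.spec
    if spec is None:
        raise ValueError("a StudySpec is required")
    rows = pair.rows.copy()
    persons = dataset.persons.set_index("person_id")
    obs_end = pd.Series(persons.loc[rows["person_id"], "observation_end"].to_numpy(),
                        index=rows.index)

    if spec.tar_variant == "intent-to-treat":
        rows["tar_end"] = obs_end
    else:
        drug_of_arm = {"target": spec.target_id, "comparator": spec.comparator_id}
        eras = dataset.drug_eras
        tar_end = obs_end.copy()
        for arm, drug_id in drug_of_arm.items():
            idx = rows.index[rows["arm"] == arm]
            if len(idx) == 0:
                continue
            sub = eras[(eras["drug_concept_id"] == drug_id)
                       & eras["person_id"].isin(rows.loc[idx, "person_id"])]
            sub = sub.sort_values(["person_id", "era_start"], kind="stable")
            # index = first era of the drug, so the chain containing it is the
            # first run of eras not separated by more than era_gap_days
            run_end = sub.groupby("person_id", sort=False)["era_end"].cummax()
            prev_end = run_end.groupby(sub["person_id"], sort=False).shift(1)
            gap_days = (sub["era_start"] - prev_end).dt.days
            brk = (gap_days > spec.era_gap_days).fillna(False)
            in_first_chain = brk.groupby(sub["person_id"], sort=False).cumsum() == 0
            chain_end = sub[in_first_chain].groupby("person_id")["era_end"].max()
            ends = rows.loc[idx, "person_id"].map(chain_end)
            tar_end.loc[idx] = np.minimum(pd.to_datetime(ends).to_numpy(),
                                          obs_end.loc[idx].to_numpy())
        rows["tar_end"] = pd.to_datetime(tar_end)

    rows["tar_end"] = np.maximum(rows["tar_end"].to_numpy(), rows["tar_start"].to_numpy())

    occ = dataset.condition_occurrences
    outcome_occ = occ[occ["condition_concept_id"] == spec.outcome_id]
    merged = rows[["person_id", "tar_start", "tar_end"]].merge(outcome_occ, on="person_id")
    inside = merged[(merged["occurrence_date"] >= merged["tar_start"])
                    & (merged["occurrence_date"] <= merged["tar_end"])]
    first = inside.groupby("person_id")["occurrence_date"].min()
    rows["outcome_date"] = pd.to_datetime(rows["person_id"].map(first))
    return CohortPair(rows=rows[CohortPair.COLUMNS], spec=spec)


def apply_min_cohort_size(pair: CohortPair, spec: StudySpec | None = None) -> bool:
    """True iff both arms reach the minimum cohort size (boundary inclusive)."""
    spec = spec or pair.spec
    if spec is None:
        raise ValueError("a StudySpec is required")
    return pair.n_target >= spec.min_cohort_size and pair.n_comparator >= spec.min_cohort_size
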