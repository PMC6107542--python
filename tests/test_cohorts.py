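import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import evigrid as eg
from evigrid.cohorts import CohortPair, StudySpec, merge_eras
from evigrid.simulate import ClaimsDataset

D = pd.Timestamp
TARGET, COMPARATOR, OUTCOME = 1, 2, 50


def _dataset(persons, eras, occurrences=()):
    return ClaimsDataset(
        persons=pd.DataFrame(persons, columns=["person_id", "age_group", "gender",
                                               "observation_start", "observation_end"]),
        drug_eras=pd.DataFrame(eras, columns=["person_id", "drug_concept_id",
                                              "era_start", "era_end"]),
        condition_occurrences=pd.DataFrame(
            list(occurrences) or None,
            columns=["person_id", "condition_concept_id", "occurrence_date"]),
    )


@pytest.fixture()
def toy_dataset():
    """Six persons: p3 exposed to both drugs, p4 with a prior outcome, p5 with
    only 100 days of washout; p1, p2, p6 survive the entry rules."""
    persons = [
        (1, "40-44", "F", D("2009-01-01"), D("2011-12-31")),
        (2, "40-44", "M", D("2009-01-01"), D("2011-12-31")),
        (3, "40-44", "F", D("2008-06-01"), D("2011-12-31")),
        (4, "40-44", "M", D("2009-01-01"), D("2011-12-31")),
        (5, "40-44", "F", D("2010-04-23"), D("2011-12-31")),  # 100-day washout
        (6, "40-44", "M", D("2009-01-01"), D("2011-12-31")),
    ]
    eras = [
        (1, TARGET, D("2010-06-01"), D("2010-08-01")),
        (2, COMPARATOR, D("2010-05-01"), D("2010-07-01")),
        (3, TARGET, D("2010-01-01"), D("2010-03-01")),
        (3, COMPARATOR, D("2010-12-01"), D("2010-12-31")),
        (4, TARGET, D("2010-06-15"), D("2010-08-15")),
        (5, COMPARATOR, D("2010-08-01"), D("2010-09-01")),
        (6, TARGET, D("2010-09-01"), D("2010-10-01")),
    ]
    occurrences = [(4, OUTCOME, D("2010-02-01"))]  # prior outcome for p4
    return _dataset(persons, eras, occurrences)


def test_entry_rules_hand_traced(toy_dataset):
    spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME)
    pair = eg.build_cohort_pair(toy_dataset, spec)
    got = dict(zip(pair.rows["person_id"], pair.rows["arm"]))
    assert got == {1: "target", 2: "comparator", 6: "target"}


def test_entry_rule_order_invariance(toy_dataset):
    """The surviving set is determined by the conjunction of exclusions, so it
    must match recomputing each exclusion independently on the raw tables."""
    spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME)
    pair = eg.build_cohort_pair(toy_dataset, spec)
    # independent recomputation: all first-era users minus each rule's casualties
    survivors = {1, 2, 6}
    assert set(pair.rows["person_id"]) == survivors


def test_calendar_overlap_empty_when_drugs_disjoint():
    persons = [(1, "a", "F", D("2009-01-01"), D("2012-12-31")),
               (2, "a", "M", D("2009-01-01"), D("2012-12-31"))]
    eras = [(1, TARGET, D("2010-01-01"), D("2010-03-01")),
            (2, COMPARATOR, D("2011-01-01"), D("2011-03-01"))]  # after A's last era
    spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME)
    pair = eg.build_cohort_pair(_dataset(persons, eras), spec)
    assert len(pair.rows) == 0 and pair.is_empty


def test_vacuous_filters_retain_all_first_era_users():
    persons = [(i, "a", "F", D("2010-01-01"), D("2012-12-31")) for i in (1, 2, 3, 4)]
    eras = [(1, TARGET, D("2010-06-01"), D("2010-07-01")),
            (2, TARGET, D("2010-08-01"), D("2010-09-01")),
            (3, COMPARATOR, D("2010-06-01"), D("2010-07-15")),
            (4, COMPARATOR, D("2010-08-01"), D("2010-09-15"))]
    spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME,
                     washout_days=0)
    pair = eg.build_cohort_pair(_dataset(persons, eras), spec)
    assert len(pair.rows) == 4


class TestTimeAtRisk:
    def _one_person(self, eras_rel, gap, variant="on-treatment"):
        base = D("2010-06-01")
        persons = [(1, "a", "F", D("2009-01-01"), D("2011-12-31")),
                   (2, "a", "F", D("2009-01-01"), D("2011-12-31"))]
        eras = [(1, TARGET, base + pd.Timedelta(days=s), base + pd.Timedelta(days=e))
                for s, e in eras_rel]
        eras.append((2, COMPARATOR, base, base + pd.Timedelta(days=10)))
        ds = _dataset(persons, eras)
        spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME,
                         era_gap_days=gap, tar_variant=variant)
        pair = eg.compute_time_at_risk(eg.build_cohort_pair(ds, spec), ds, spec)
        row = pair.rows[pair.rows["person_id"] == 1].iloc[0]
        return (row["tar_end"] - row["tar_start"]).days

    def test_gap_within_limit_merges_eras(self):
        # eras day 0-30 and 55-80: the 25-day gap merges under a 30-day rule
        assert self._one_person([(0, 30), (55, 80)], gap=30) == 80

    def test_gap_beyond_limit_stops_time_at_risk(self):
        assert self._one_person([(0, 30), (55, 80)], gap=20) == 30

    def test_intent_to_treat_runs_to_observation_end(self):
        days = self._one_person([(0, 30), (55, 80)], gap=20, variant="intent-to-treat")
        assert days == (D("2011-12-31") - D("2010-06-01")).days

    def test_outcome_date_is_first_event_inside_tar(self):
        base = D("2010-06-01")
        persons = [(1, "a", "F", D("2009-01-01"), D("2011-12-31")),
                   (2, "a", "F", D("2009-01-01"), D("2011-12-31"))]
        eras = [(1, TARGET, base, base + pd.Timedelta(days=60)),
                (2, COMPARATOR, base, base + pd.Timedelta(days=10))]
        occ = [(1, OUTCOME, base + pd.Timedelta(days=40)),
               (1, OUTCOME, base + pd.Timedelta(days=50)),
               (1, OUTCOME, base + pd.Timedelta(days=400))]  # outside TAR
        ds = _dataset(persons, eras, occ)
        spec = StudySpec(target_id=TARGET, comparator_id=COMPARATOR, outcome_id=OUTCOME)
        pair = eg.compute_time_at_risk(eg.build_cohort_pair(ds, spec), ds, spec)
        row = pair.rows[pair.rows["person_id"] == 1].iloc[0]
        assert row["outcome_date"] == base + pd.Timedelta(days=40)


@pytest.mark.parametrize("n_target,n_comparator,expected", [
    (2500, 2500, True),   # boundary inclusive
    (2499, 10_000, False),
    (0, 0, False),
])
def test_min_cohort_size_rule(n_target, n_comparator, expected):
    rows = pd.DataFrame({
        "person_id": np.arange(n_target + n_comparator),
        "arm": ["target"] * n_target + ["comparator"] * n_comparator,
    })
    for col in ("index_date", "tar_start", "tar_end", "outcome_date"):
        rows[col] = pd.NaT
    pair = CohortPair(rows=rows)
    spec = StudySpec(target_id=1, comparator_id=2, outcome_id=3)
    assert eg.apply_min_cohort_size(pair, spec) is expected


intervals = st.lists(
    st.tuples(st.integers(0, 300), st.integers(0, 60)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=1, max_size=6,
).map(lambda xs: sorted(xs))


@given(intervals, st.integers(0, 45))
def test_merge_eras_idempotent_and_disjoint(eras, gap):
    base = np.datetime64("2010-01-01")
    starts = np.array([base + np.timedelta64(s, "D") for s, _ in eras])
    ends = np.array([base + np.timedelta64(e, "D") for _, e in eras])
    s1, e1 = merge_eras(starts, ends, gap)
    s2, e2 = merge_eras(s1, e1, gap)
    assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
    # merged intervals are separated by more than the gap
    assert all((s1[i + 1] - e1[i]) / np.timedelta64(1, "D") > gap for i in range(len(s1) - 1))
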