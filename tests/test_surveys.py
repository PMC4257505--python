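"""Tests for the roach presence/absence classifier."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealacid.surveys import (
    ClassificationCriteria,
    LakeSurveyHistory,
    Override,
    Period,
    Status,
    SurveyRecord,
    SurveyValidationError,
    assign_period,
    classify_biological,
    summarize_periods,
)


def history(records, lake_id="L1", override=Override.NONE):
    return LakeSurveyHistory(
        lake_id=lake_id,
        records=[
            SurveyRecord(lake_id=lake_id, year=y, present=p) for y, p in records
        ],
        expert_override=override,
    )


class TestPeriods:
    @pytest.mark.parametrize(
        "year,period",
        [
            (1890, Period.P1),
            (1959, Period.P1),
            (1960, Period.P2),
            (1990, Period.P2),
            (1991, Period.P3),
            (2012, Period.P3),
        ],
    )
    def test_boundaries(self, year, period):
        assert assign_period(year) is period

    @pytest.mark.parametrize("year", [1889, 2013])
    def test_out_of_bounds_rejected(self, year):
        with pytest.raises(SurveyValidationError):
            assign_period(year)

    def test_summaries_hand_tally(self):
        h = history(
            [(1950, True), (1955, True), (1970, False), (1980, False),
             (1990, True), (1995, True), (2000, False)]
        )
        s = summarize_periods(h)
        assert (s[Period.P1].n_surveys, s[Period.P1].n_present) == (2, 2)
        assert (s[Period.P2].n_surveys, s[Period.P2].n_present) == (3, 1)
        assert (s[Period.P3].n_surveys, s[Period.P3].n_present) == (2, 1)

    def test_empty_history_all_zero(self):
        s = summarize_periods(history([]))
        assert all(v.n_surveys == 0 for v in s.values())
        assert all(math.isnan(v.fraction) for v in s.values())


class TestClassifier:
    def test_clear_extirpation_is_acidified(self):
        h = history([(1950, True)] * 4 + [(1970, False)] * 3)
        assert classify_biological(h).status is Status.ACIDIFIED

    def test_persistent_presence_is_nonacidified(self):
        h = history([(1950, True)] * 3 + [(1970, True)] * 4)
        assert classify_biological(h).status is Status.NONACIDIFIED

    def test_single_p1_observation_excluded(self):
        h = history([(1950, True)] + [(1970, False)] * 5)
        res = classify_biological(h)
        assert res.status is Status.EXCLUDED
        assert "P1" in res.exclusion_reason

    def test_empty_period_excluded(self):
        h = history([(1950, True), (1955, True)])  # no P2 surveys at all
        assert classify_biological(h).status is Status.EXCLUDED

    def test_mixed_record_indeterminate(self):
        # P1 3/4 = 0.75 passes, P2 2/4 = 0.5 meets neither rule
        h = history(
            [(1950, True), (1951, True), (1952, True), (1953, False),
             (1970, True), (1971, True), (1972, False), (1973, False)]
        )
        assert classify_biological(h).status is Status.INDETERMINATE

    def test_acid_thresholds_inclusive(self):
        # P1 exactly 75%, P2 exactly 25% -> acidified
        h = history(
            [(1950, True), (1951, True), (1952, True), (1953, False),
             (1970, True), (1971, False), (1972, False), (1973, False)]
        )
        assert classify_biological(h).status is Status.ACIDIFIED

    def test_nonacid_threshold_strict(self):
        # exactly 90% presence in P1 must NOT classify as nonacidified
        h = history(
            [(1940 + i, i != 0) for i in range(10)]  # P1 9/10 = 0.90
            + [(1970, True)] * 4                      # P2 1.0
        )
        res = classify_biological(h)
        assert res.status is Status.INDETERMINATE

    def test_recolonization_flag(self):
        h = history([(1950, True)] * 3 + [(1970, False)] * 3 + [(2000, True)])
        res = classify_biological(h)
        assert res.status is Status.ACIDIFIED
        assert res.recolonized and res.recolonized_low_confidence

    def test_expert_override_forces_status(self):
        h = history(
            [(1950, True)] * 3 + [(1970, False)] * 3,
            override=Override.FORCE_PRESENT,
        )
        assert classify_biological(h).status is Status.NONACIDIFIED

    def test_both_period_exclusion_mode(self):
        crit = ClassificationCriteria(exclude_single_either_period=False)
        h = history([(1950, True)] + [(1970, False)] * 5)
        assert classify_biological(h, crit).status is not Status.EXCLUDED


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(1890, 2012), st.booleans()), min_size=0, max_size=30
    ),
    seed=st.integers(0, 2**16),
)
def test_order_invariance_and_partition(data, seed):
    """Classification ignores record order; every lake gets one status."""
    import random

    h1 = history(data)
    shuffled = list(data)
    random.Random(seed).shuffle(shuffled)
    h2 = history(shuffled)
    r1, r2 = classify_biological(h1), classify_biological(h2)
    assert r1.status is r2.status
    assert r1.recolonized == r2.recolonized
    assert r1.status in set(Status)
    # periods partition the records
    s = summarize_periods(h1)
    assert sum(v.n_surveys for v in s.values()) == len(data)
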