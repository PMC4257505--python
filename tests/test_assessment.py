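"""Tests for the chemical/biological consistency assessment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealacid.assessment import (
    AssessmentError,
    ChemicalStatus,
    Consistency,
    Quadrant,
    assess_lake,
    chemical_status,
    consistency_category,
    overall_chemical_acidified,
    quadrant,
    summarize_ensemble,
)
from borealacid.surveys import (
    LakeSurveyHistory,
    Status,
    SurveyRecord,
    classify_biological,
)


def bio(lake_id, status_records):
    h = LakeSurveyHistory(
        lake_id=lake_id,
        records=[SurveyRecord(lake_id, y, p) for y, p in status_records],
    )
    return classify_biological(h)


ROACH_ABSENT = [(1950, True)] * 3 + [(1970, False)] * 3
ROACH_PRESENT = [(1950, True)] * 3 + [(1970, True)] * 3
ROACH_SPARSE = [(1950, True)]


class TestChemicalStatus:
    def test_ovre_skarsjon_1980(self):
        s = chemical_status(6.6, 4.7)
        assert s.acidified and s.below_threshold
        assert s.delta_ph == pytest.approx(1.9)

    def test_vastra_solsjon_2010(self):
        s = chemical_status(7.2, 7.1)
        assert not s.acidified and not s.below_threshold

    def test_delta_exactly_at_threshold_not_acidified(self):
        assert not chemical_status(6.0, 5.6).acidified

    def test_antisymmetry(self):
        assert chemical_status(6.4, 5.1).delta_ph == -chemical_status(5.1, 6.4).delta_ph

    def test_out_of_range_rejected(self):
        with pytest.raises(AssessmentError):
            chemical_status(2.0, 6.0)


class TestConsistency:
    def test_four_way_mapping(self):
        absent = bio("a", ROACH_ABSENT)
        present = bio("p", ROACH_PRESENT)
        acid = chemical_status(6.6, 4.7)
        nonacid = chemical_status(7.2, 7.1)
        assert consistency_category(acid, absent) is Consistency.II_ACID_BOTH
        assert consistency_category(acid, present) is Consistency.III_CHEM_ACID_ROACH_PRESENT
        assert consistency_category(nonacid, absent) is Consistency.IV_CHEM_NONACID_ROACH_ABSENT
        assert consistency_category(nonacid, present) is Consistency.I_NONACID_BOTH

    def test_indefinite_biological_status_rejected(self):
        sparse = bio("s", ROACH_SPARSE)
        assert sparse.status is Status.EXCLUDED
        with pytest.raises(AssessmentError):
            consistency_category(chemical_status(6.6, 4.7), sparse)

    def test_overall_rule_requires_persistence_or_threshold(self):
        # transient exceedance, never biologically relevant -> recovered
        peak = chemical_status(6.8, 5.9)       # delta 0.9, above 5.5
        recovered = chemical_status(6.8, 6.6)  # delta 0.2
        assert not overall_chemical_acidified(peak, recovered)
        # crossed the species threshold at the peak -> acidified
        deep_peak = chemical_status(6.8, 5.2)
        assert overall_chemical_acidified(deep_peak, recovered)
        # persistent significant deviation -> acidified
        still_acid = chemical_status(6.8, 6.0)
        assert overall_chemical_acidified(peak, still_acid)


class TestQuadrant:
    @pytest.mark.parametrize(
        "ref,assess,expected",
        [
            (6.6, 4.7, Quadrant.B),   # crossed the species threshold
            (7.0, 6.0, Quadrant.A),   # large change, no threshold crossing
            (5.2, 4.6, Quadrant.C),   # reference already below threshold
            (7.2, 7.1, Quadrant.D),   # within accepted deviation
            (5.3, 5.1, Quadrant.D),   # ambiguous corner: D takes precedence
        ],
    )
    def test_examples(self, ref, assess, expected):
        assert quadrant(ref, assess) is expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ref=st.floats(3.0, 10.0), assess=st.floats(3.0, 10.0))
def test_quadrant_partition(ref, assess):
    """Every pH pair maps to exactly one quadrant."""
    assert quadrant(ref, assess) in set(Quadrant)


class TestEnsemble:
    def test_single_lake_no_reduction(self):
        a = assess_lake("L", 6.8, {1980: 5.0, 2010: 5.2}, bio("L", ROACH_ABSENT))
        s = summarize_ensemble([a])
        assert s.percent_reduction == 0
        assert s.categories[Consistency.II_ACID_BOTH] == 1

    def test_empty_list_rejected(self):
        with pytest.raises(AssessmentError):
            summarize_ensemble([])

    def test_category_counts_sum_to_definite_lakes(self):
        lakes = [
            assess_lake("a", 6.8, {1980: 5.0, 2010: 5.2}, bio("a", ROACH_ABSENT)),
            assess_lake("b", 7.0, {1980: 6.8, 2010: 6.9}, bio("b", ROACH_PRESENT)),
            assess_lake("c", 7.0, {1980: 6.8, 2010: 6.9}, bio("c", ROACH_SPARSE)),
        ]
        s = summarize_ensemble(lakes)
        assert sum(s.categories.values()) + s.n_indefinite == s.n_lakes
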