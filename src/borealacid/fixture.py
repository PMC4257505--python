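"""Deterministic 85-lake assessment fixture.

A seedless, fully reproducible ensemble of 85 lakes — pH trajectories for
1860/1980/2010 plus survey histories — constructed so that running the
assessment pipeline on it yields, simultaneously:

* 28 lakes ΔpH-acidified in 1980 and 14 in 2010 (a 50% reduction);
* 14 lakes at/below pH 5.5 in 1980, roach absent in 11 of them;
  7 below in 2010, roach absent in 5;
* consistency categories i/ii/iii/iv = 64/14/3/4 (78 coherent);
* 14 of the 28 peak-era acidified lakes with at least one heavy-period
  survey reporting roach presence;
* 5 of the 14 category-ii lakes recolonized after 1990 (36%).

The eight named lakes carry their published pH values; values that were
never published (the 1980 pH of the three nonacidified named lakes, and
everything about the unnamed filler lakes) are synthetic, generated by a
documented deterministic rule (evenly spaced values within each category's
constraint bounds; marked ``synthetic=True``).

Unnamed filler lakes are grouped by the constraints they must satisfy:

========  ==  =======================================================
group     n   constraint
========  ==  =======================================================
ii-deep    5  acid both years, below 5.5 both years, roach absent
ii-mid     1  acid both years, below 5.5 only in 1980
ii-trans   3  acid 1980 below 5.5, chemically recovered by 2010
ii-high    3  acid both years but never below 5.5
iii        1  (Rattsjön) acid both years, below 5.5, roach present
iv         2  no significant ΔpH, roach absent
i-recov   11  acid 1980 above 5.5, recovered by 2010, roach present
i-plain   51  never significantly acidified, roach present
========  ==  =======================================================

Construction runs the real survey classifier and assessment code and
raises :class:`FixtureError` naming the first violated marginal if the
constraints are not met, so the fixture can never silently drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assessment import (
    Consistency,
    LakeAssessment,
    assess_lake,
    summarize_ensemble,
)
from .surveys import (
    LakeSurveyHistory,
    SurveyMethod,
    SurveyRecord,
    classify_biological,
)

__all__ = ["FixtureLake", "FixtureError", "build_results_fixture", "assess_fixture"]


class FixtureError(RuntimeError):
    """The constructed fixture violates one of its published marginals."""


@dataclass(frozen=True)
class FixtureLake:
    """Inputs for one fixture lake: pH trajectory plus survey history."""

    lake_id: str
    ph_1860: float
    ph_1980: float
    ph_2010: float
    surveys: LakeSurveyHistory
    synthetic: bool = True  # False only for fully published named values

    @property
    def ph_by_year(self) -> dict:
        return {1980: self.ph_1980, 2010: self.ph_2010}


def _history(lake_id: str, records: list[tuple[int, bool]]) -> LakeSurveyHistory:
    recs = [
        SurveyRecord(
            lake_id=lake_id,
            year=year,
            present=present,
            method=SurveyMethod.INTERVIEW if year < 1960 else SurveyMethod.GILLNET,
            source="fixture",
        )
        for year, present in records
    ]
    return LakeSurveyHistory(lake_id=lake_id, records=recs)


# Survey templates.  Presence proportions are what the classifier needs:
# persistent lakes show presence in every period; extirpated lakes show
# early presence, consistent absence through the heavy period, and a
# recovery-era record that is present only for restocked lakes.
def _persistent(lake_id: str) -> LakeSurveyHistory:
    return _history(
        lake_id,
        [(1905, True), (1935, True), (1950, True),
         (1965, True), (1975, True), (1985, True),
         (1995, True)],
    )


def _extirpated(lake_id: str, recolonized: bool) -> LakeSurveyHistory:
    p3: list[tuple[int, bool]] = [(1995, False)]
    if recolonized:
        p3.append((2005, True))
    return _history(
        lake_id,
        [(1905, True), (1935, True), (1950, True),
         (1965, False), (1975, False), (1985, False)] + p3,
    )


def build_results_fixture() -> list[FixtureLake]:
    """Build the deterministic 85-lake fixture (seedless; always identical)."""
    lakes: list[FixtureLake] = []

    def add(lake_id, ph60, ph80, ph10, surveys, synthetic=True):
        lakes.append(FixtureLake(lake_id, ph60, ph80, ph10, surveys, synthetic))

    # --- named lakes, published trajectories -------------------------------
    add("Övre Skärsjön", 6.6, 4.7, 5.9,
        _history("Övre Skärsjön",
                 [(1930, True), (1940, True), (1950, True),
                  (1970, False), (1975, False), (1985, False),
                  (1995, False)]),
        synthetic=False)
    add("Bäen", 6.9, 4.4, 5.5,
        _history("Bäen",
                 [(1935, True), (1950, True),
                  (1965, False), (1980, False),
                  (1994, False), (2009, True)]),
        synthetic=False)
    add("Rotehogstjärnen", 6.5, 4.4, 5.1,
        _history("Rotehogstjärnen",
                 [(1896, True), (1950, True),
                  (1970, True), (1985, True),
                  (1995, True)]),
        synthetic=False)
    add("Ulvsjön", 6.9, 5.0, 6.4,
        _history("Ulvsjön",
                 [(1900, True), (1950, True),
                  (1965, True), (1985, True),
                  (2000, True)]),
        synthetic=False)
    # 1980 pH never published for the three nonacidified named lakes: the
    # value is synthetic, placed within the no-significant-deviation bound.
    add("Västra Solsjön", 7.2, 7.0, 7.1,
        _history("Västra Solsjön",
                 [(1902, True), (1935, True), (1950, True),
                  (1965, True), (1975, True), (1985, True),
                  (1995, True)]))
    add("Bysjön", 6.8, 6.6, 6.7,
        _history("Bysjön",
                 [(1896, True), (1930, True), (1950, True),
                  (1965, True), (1975, True), (1985, True),
                  (1995, True)]))
    add("Granträsket", 6.8, 6.6, 6.7,
        _history("Granträsket",
                 [(1902, True), (1940, True),
                  (1977, False), (1983, False),
                  (1997, True)]))
    add("Falträsket", 7.1, 6.9, 7.0,
        _history("Falträsket",
                 [(1900, True), (1930, True),
                  (1980, False), (1985, False),
                  (1994, False)]))

    # --- category iii filler (Rattsjön: values never published) ------------
    add("Rattsjön", 6.7, 4.9, 5.3,
        _history("Rattsjön",
                 [(1900, True), (1950, True),
                  (1965, True), (1985, True),
                  (1995, True)]))

    # --- category ii filler -------------------------------------------------
    # ii-deep: below 5.5 at both assessments; two of them restocked.
    for i in range(5):
        add(f"ii-deep-{i + 1:02d}", 6.4 + 0.1 * i, 4.5 + 0.1 * i, 4.9 + 0.1 * i,
            _extirpated(f"ii-deep-{i + 1:02d}", recolonized=i < 2))
    # ii-mid: below 5.5 at the peak only; still acidified in 2010; restocked.
    add("ii-mid-01", 6.6, 5.0, 5.9, _extirpated("ii-mid-01", recolonized=True))
    # ii-trans: crossed 5.5 at the peak but chemically recovered by 2010;
    # one restocked.
    for i in range(3):
        add(f"ii-trans-{i + 1:02d}", 6.0 + 0.1 * i, 5.1 + 0.1 * i, 5.8 + 0.1 * i,
            _extirpated(f"ii-trans-{i + 1:02d}", recolonized=i == 0))
    # ii-high: significantly acidified at both assessments yet never below
    # 5.5 (roach loss without a modeled threshold crossing).
    for i in range(3):
        add(f"ii-high-{i + 1:02d}", 6.9 + 0.1 * i, 5.6 + 0.1 * i, 6.3 + 0.1 * i,
            _extirpated(f"ii-high-{i + 1:02d}", recolonized=False))

    # --- category iv filler (roach absent, no significant ΔpH) --------------
    add("iv-filler-01", 7.0, 6.8, 6.9, _extirpated("iv-filler-01", recolonized=False))
    add("iv-filler-02", 6.5, 6.3, 6.4, _extirpated("iv-filler-02", recolonized=True))

    # --- category i filler ---------------------------------------------------
    # i-recov: significantly acidified at the 1980 peak (but above 5.5),
    # chemically recovered by 2010, roach present throughout.
    for i in range(11):
        ref = 6.6 + 0.1 * i
        add(f"i-recov-{i + 1:02d}", round(ref, 2), round(ref - 0.9, 2),
            round(ref - 0.25, 2), _persistent(f"i-recov-{i + 1:02d}"))
    # i-plain: never significantly acidified; references evenly spaced over
    # the circumneutral-to-alkaline range the monitoring data span.
    for i in range(51):
        ref = 5.9 + 2.3 * i / 50.0
        add(f"i-plain-{i + 1:02d}", round(ref, 3), round(ref - 0.3, 3),
            round(ref - 0.15, 3), _persistent(f"i-plain-{i + 1:02d}"))

    _verify(lakes)
    return lakes


def assess_fixture(lakes: list[FixtureLake] | None = None):
    """Run the full assessment pipeline on the fixture.

    Returns ``(assessments, summary)``.
    """
    if lakes is None:
        lakes = build_results_fixture()
    assessments: list[LakeAssessment] = []
    for lake in lakes:
        bio = classify_biological(lake.surveys)
        assessments.append(
            assess_lake(lake.lake_id, lake.ph_1860, lake.ph_by_year, bio)
        )
    return assessments, summarize_ensemble(assessments)


def acidification_era_presence(lake: FixtureLake) -> bool:
    """Any heavy-acidification-period survey reporting roach presence."""
    return any(1960 <= r.year <= 1990 and r.present for r in lake.surveys.records)


_EXPECTED = {
    "n_lakes": 85,
    "acidified_1980": 28,
    "acidified_2010": 14,
    "below_1980": 14,
    "absent_below_1980": 11,
    "below_2010": 7,
    "absent_below_2010": 5,
    "cat_i": 64,
    "cat_ii": 14,
    "cat_iii": 3,
    "cat_iv": 4,
    "coherent": 78,
    "recolonized": 5,
    "percent_recolonized": 36,
    "percent_reduction": 50,
    "presence_among_peak_acidified": 14,
}


def _verify(lakes: list[FixtureLake]) -> None:
    assessments, summary = assess_fixture(lakes)
    by_id = {lk.lake_id: lk for lk in lakes}
    peak_acid = [
        a for a in assessments if a.chemical[1980].acidified
    ]
    observed = {
        "n_lakes": summary.n_lakes,
        "acidified_1980": summary.n_acidified[1980],
        "acidified_2010": summary.n_acidified[2010],
        "below_1980": summary.n_below_threshold[1980],
        "absent_below_1980": summary.n_roach_absent_below_threshold[1980],
        "below_2010": summary.n_below_threshold[2010],
        "absent_below_2010": summary.n_roach_absent_below_threshold[2010],
        "cat_i": summary.categories[Consistency.I_NONACID_BOTH],
        "cat_ii": summary.categories[Consistency.II_ACID_BOTH],
        "cat_iii": summary.categories[Consistency.III_CHEM_ACID_ROACH_PRESENT],
        "cat_iv": summary.categories[Consistency.IV_CHEM_NONACID_ROACH_ABSENT],
        "coherent": summary.n_coherent,
        "recolonized": summary.n_recolonized,
        "percent_recolonized": summary.percent_recolonized,
        "percent_reduction": summary.percent_reduction,
        "presence_among_peak_acidified": sum(
            acidification_era_presence(by_id[a.lake_id]) for a in peak_acid
        ),
    }
    for key, expected in _EXPECTED.items():
        if observed[key] != expected:
            raise FixtureError(
                f"fixture marginal {key!r}: expected {expected}, got {observed[key]}"
            )
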