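"""Historical roach presence/absence classification.

Roach (*Rutilus rutilus*) is ubiquitous in boreal lakes above pH ~6 and is
extirpated below pH ~5.5, which makes its disappearance from the historical
record a biological acidification signal.  Survey outcomes (interviews,
postal questionnaires, gillnet surveys, 1890–2012) are grouped into three
periods — before the onset of heavy deposition, the heavy-acidification
decades, and the recovery era — and a lake is called acidified when a
well-documented early presence gives way to consistent absence.

Because individual surveys can miss low-density populations (false
absences), the classification is probabilistic: proportions of surveys
reporting presence are compared against thresholds rather than requiring
unanimous records, and lakes with too few surveys to form the
before/after contrast are excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Period",
    "SurveyMethod",
    "Status",
    "SurveyRecord",
    "PeriodSummary",
    "LakeSurveyHistory",
    "ClassificationCriteria",
    "BiologicalStatus",
    "SurveyValidationError",
    "assign_period",
    "summarize_periods",
    "classify_biological",
]


class Period(str, enum.Enum):
    P1 = "P1"  # beginning of acidification, before 1960
    P2 = "P2"  # heavy acidification, 1960-1990
    P3 = "P3"  # recovery, after 1990


class SurveyMethod(str, enum.Enum):
    INTERVIEW = "interview"
    QUESTIONNAIRE = "questionnaire"
    GILLNET = "gillnet"
    OTHER = "other"


class Status(str, enum.Enum):
    ACIDIFIED = "acidified"
    NONACIDIFIED = "nonacidified"
    EXCLUDED = "excluded"
    INDETERMINATE = "indeterminate"


class Override(str, enum.Enum):
    """Expert-consultation override recorded in the input, never inferred."""

    NONE = "none"
    FORCE_PRESENT = "force-present"
    FORCE_ABSENT = "force-absent"


class SurveyValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SurveyRecord:
    """One survey outcome for one lake."""

    lake_id: str
    year: int
    present: bool
    method: SurveyMethod = SurveyMethod.OTHER
    source: str = ""


@dataclass(frozen=True)
class ClassificationCriteria:
    """Tunable thresholds of the presence/absence classifier.

    Defaults are the published criteria: acidified when presence proportion
    is >=75% before 1960 and <=25% in 1960-1990 (inclusive thresholds);
    nonacidified when strictly more than 90% of surveys in both periods
    report presence.  ``exclude_single_either_period`` excludes a lake if
    either of the first two periods has <=1 survey (both are needed for the
    before/after contrast); set False to require both periods sparse.
    """

    p1_end: int = 1960          # P1 is strictly before this year
    p2_end: int = 1990          # P2 runs p1_end..p2_end inclusive
    year_min: int = 1890
    year_max: int = 2012
    acid_p1_min: float = 0.75   # inclusive
    acid_p2_max: float = 0.25   # inclusive
    nonacid_min: float = 0.90   # strict, both periods
    min_surveys: int = 2        # per period; fewer -> excluded
    exclude_single_either_period: bool = True


DEFAULT_CRITERIA = ClassificationCriteria()


@dataclass(frozen=True)
class PeriodSummary:
    n_surveys: int
    n_present: int

    @property
    def fraction(self) -> float:
        """Proportion of surveys reporting presence; NaN when no surveys."""
        if self.n_surveys == 0:
            return math.nan
        return self.n_present / self.n_surveys


@dataclass
class LakeSurveyHistory:
    """All survey records for one lake, with per-period summaries."""

    lake_id: str
    records: list[SurveyRecord] = field(default_factory=list)
    expert_override: Override = Override.NONE

    def summaries(
        self, criteria: ClassificationCriteria = DEFAULT_CRITERIA
    ) -> dict[Period, PeriodSummary]:
        return summarize_periods(self, criteria)


def assign_period(
    year: int, criteria: ClassificationCriteria = DEFAULT_CRITERIA
) -> Period:
    """Map a survey year to its analysis period.

    Years strictly before 1960 are P1; 1960 through 1990 inclusive are P2
    (both boundary years belong to the heavy-acidification period); later
    years are P3.  Years outside the configured bounds are rejected.
    """
    if not (criteria.year_min <= year <= criteria.year_max):
        raise SurveyValidationError(
            f"survey year {year} outside bounds "
            f"[{criteria.year_min}, {criteria.year_max}]"
        )
    if year < criteria.p1_end:
        return Period.P1
    if year <= criteria.p2_end:
        return Period.P2
    return Period.P3


def summarize_periods(
    history: LakeSurveyHistory,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> dict[Period, PeriodSummary]:
    """Count surveys and presences per period; the periods partition all records."""
    counts = {p: [0, 0] for p in Period}
    for rec in history.records:
        period = assign_period(rec.year, criteria)
        counts[period][0] += 1
        if rec.present:
            counts[period][1] += 1
    return {p: PeriodSummary(n_surveys=c[0], n_present=c[1]) for p, c in counts.items()}


@dataclass(frozen=True)
class BiologicalStatus:
    """Classifier output for one lake."""

    lake_id: str
    status: Status
    p1: PeriodSummary
    p2: PeriodSummary
    p3: PeriodSummary
    recolonized: bool
    recolonized_low_confidence: bool = False
    exclusion_reason: str = ""

    @property
    def p1_fraction(self) -> float:
        return self.p1.fraction

    @property
    def p2_fraction(self) -> float:
        return self.p2.fraction

    @property
    def p3_fraction(self) -> float:
        return self.p3.fraction


def classify_biological(
    history: LakeSurveyHistory,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> BiologicalStatus:
    """Classify one lake from its survey history.

    Order of evaluation: expert override, exclusion for sparse data, then
    the acidified / nonacidified proportion rules; anything that meets
    neither rule is indeterminate.  ``recolonized`` is set for acidified
    lakes with any recovery-period presence record; with a single P3 record
    it is additionally flagged low-confidence.
    """
    sums = summarize_periods(history, criteria)
    p1, p2, p3 = sums[Period.P1], sums[Period.P2], sums[Period.P3]

    def result(status: Status, reason: str = "") -> BiologicalStatus:
        recol = status is Status.ACIDIFIED and p3.n_present > 0
        return BiologicalStatus(
            lake_id=history.lake_id,
            status=status,
            p1=p1,
            p2=p2,
            p3=p3,
            recolonized=recol,
            recolonized_low_confidence=recol and p3.n_surveys == 1,
            exclusion_reason=reason,
        )

    if history.expert_override is Override.FORCE_PRESENT:
        return result(Status.NONACIDIFIED)
    if history.expert_override is Override.FORCE_ABSENT:
        return result(Status.ACIDIFIED)

    sparse = [
        p.value
        for p, s in ((Period.P1, p1), (Period.P2, p2))
        if s.n_surveys < criteria.min_surveys
    ]
    if criteria.exclude_single_either_period:
        excluded = bool(sparse)
    else:
        excluded = len(sparse) == 2
    if excluded:
        return result(
            Status.EXCLUDED,
            reason="too few surveys in " + ", ".join(sparse),
        )

    if p1.fraction >= criteria.acid_p1_min and p2.fraction <= criteria.acid_p2_max:
        return result(Status.ACIDIFIED)
    if p1.fraction > criteria.nonacid_min and p2.fraction > criteria.nonacid_min:
        return result(Status.NONACIDIFIED)
    return result(Status.INDETERMINATE)
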