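"""Chemical vs biological acidification assessment.

Combines the reference-deviation criterion (contemporary pH more than 0.4
units below the 1860 reference pH) with the roach presence/absence
classification into

* a per-lake **consistency category** — (i) nonacidified by both methods,
  (ii) acidified by both, (iii) chemically acidified but roach present,
  (iv) chemically nonacidified but roach absent;
* the **conceptual quadrant** A-D locating each lake against the accepted
  deviation (0.4 pH units) and the species tolerance threshold (pH 5.5);
* an **ensemble summary** with the acidified counts per assessment year,
  the contingency, and the recolonization fraction.

The overall (lake-level) chemical classification used for the contingency
requires a significant 1860->1980 deviation that either crossed the species
threshold at its peak or persisted to the 2010 recovery assessment: a lake
whose ΔpH exceedance was transient and never biologically relevant is
counted as recovered rather than acidified.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .surveys import BiologicalStatus, Status

__all__ = [
    "DELTA_PH_THRESHOLD",
    "SPECIES_PH_THRESHOLD",
    "ChemicalStatus",
    "Consistency",
    "Quadrant",
    "LakeAssessment",
    "EnsembleSummary",
    "AssessmentError",
    "chemical_status",
    "overall_chemical_acidified",
    "consistency_category",
    "quadrant",
    "assess_lake",
    "summarize_ensemble",
]

#: Accepted deviation from the 1860 reference pH (good ecological status).
DELTA_PH_THRESHOLD = 0.4

#: Roach mortality / reproduction-failure proxy threshold.
SPECIES_PH_THRESHOLD = 5.5

REFERENCE_YEAR = 1860
ASSESSMENT_YEARS = (1980, 2010)

#: Comparison guard for threshold tests: pH values carry at most a few
#: decimals, so a nano-pH guard absorbs binary round-off (6.0 - 5.6 is not
#: exactly 0.4 in floats) without ever flipping a genuine exceedance.
_EPS = 1e-9


class AssessmentError(ValueError):
    pass


class Consistency(str, enum.Enum):
    I_NONACID_BOTH = "i"
    II_ACID_BOTH = "ii"
    III_CHEM_ACID_ROACH_PRESENT = "iii"
    IV_CHEM_NONACID_ROACH_ABSENT = "iv"


class Quadrant(str, enum.Enum):
    A = "A"  # significant ΔpH but both reference and present above tolerance
    B = "B"  # significant ΔpH crossing the tolerance: biological effect
    C = "C"  # reference already below tolerance: species never expected
    D = "D"  # within the accepted deviation


@dataclass(frozen=True)
class ChemicalStatus:
    """ΔpH status of one lake for one assessment year."""

    ph_ref: float
    ph_assess: float
    delta_threshold: float = DELTA_PH_THRESHOLD
    species_threshold: float = SPECIES_PH_THRESHOLD

    def __post_init__(self):
        for name, value in (("ph_ref", self.ph_ref), ("ph_assess", self.ph_assess)):
            if not (3.0 <= value <= 10.0):
                raise AssessmentError(f"{name}={value} outside [3, 10]")

    @property
    def delta_ph(self) -> float:
        return self.ph_ref - self.ph_assess

    @property
    def acidified(self) -> bool:
        """Significant anthropogenic acidification (strict: ΔpH exactly at
        the threshold is still within the accepted deviation)."""
        return self.delta_ph > self.delta_threshold + _EPS

    @property
    def below_threshold(self) -> bool:
        return self.ph_assess < self.species_threshold


def chemical_status(
    ph_ref: float,
    ph_assess: float,
    delta_threshold: float = DELTA_PH_THRESHOLD,
    species_threshold: float = SPECIES_PH_THRESHOLD,
) -> ChemicalStatus:
    """Evaluate the reference-deviation criterion for one assessment year."""
    return ChemicalStatus(ph_ref, ph_assess, delta_threshold, species_threshold)


def overall_chemical_acidified(
    peak: ChemicalStatus, recovery: ChemicalStatus
) -> bool:
    """Lake-level chemical classification across both assessment years.

    True when the peak-era deviation was significant AND it either pushed
    the lake below the species threshold or was still significant at the
    recovery assessment; a transient exceedance that never became
    biologically relevant counts as recovered.
    """
    return peak.acidified and (peak.below_threshold or recovery.acidified)


def consistency_category(
    chemical: ChemicalStatus | bool, biological: BiologicalStatus
) -> Consistency:
    """Cross the chemical and biological classifications.

    ``chemical`` may be a single-year :class:`ChemicalStatus` or the
    lake-level boolean from :func:`overall_chemical_acidified`.  Lakes with
    an excluded or indeterminate biological status cannot be placed in the
    contingency and raise :class:`AssessmentError` (callers omit them with a
    logged reason).
    """
    if biological.status not in (Status.ACIDIFIED, Status.NONACIDIFIED):
        raise AssessmentError(
            f"lake {biological.lake_id!r} has biological status "
            f"{biological.status.value}; cannot enter the contingency"
        )
    chem_acid = chemical.acidified if isinstance(chemical, ChemicalStatus) else bool(chemical)
    roach_absent = biological.status is Status.ACIDIFIED
    if chem_acid and roach_absent:
        return Consistency.II_ACID_BOTH
    if chem_acid:
        return Consistency.III_CHEM_ACID_ROACH_PRESENT
    if roach_absent:
        return Consistency.IV_CHEM_NONACID_ROACH_ABSENT
    return Consistency.I_NONACID_BOTH


def quadrant(
    ph_ref: float,
    ph_assess: float,
    delta_threshold: float = DELTA_PH_THRESHOLD,
    species_threshold: float = SPECIES_PH_THRESHOLD,
) -> Quadrant:
    """Locate a (reference, assessment) pH pair in the conceptual model.

    D: within the accepted deviation (takes precedence even when the
    reference itself is below the species threshold).  Outside it: A when
    both reference and present pH are at or above the species threshold
    (chemical change without biological consequence), B when the change
    crossed the threshold (significant effect on the target organism), C
    when the reference was already below it (species never expected).
    """
    if ph_ref - ph_assess <= delta_threshold + _EPS:
        return Quadrant.D
    if ph_ref < species_threshold:
        return Quadrant.C
    if ph_assess < species_threshold:
        return Quadrant.B
    return Quadrant.A


@dataclass(frozen=True)
class LakeAssessment:
    """Joint chemical/biological assessment of one lake."""

    lake_id: str
    chemical: dict  # assessment year -> ChemicalStatus
    biological: BiologicalStatus
    chem_acidified_overall: bool
    consistency: Consistency | None  # None when biological status indefinite
    quadrant: Quadrant               # at the peak (1980) assessment
    quadrants: dict = field(default_factory=dict)  # year -> Quadrant


def assess_lake(
    lake_id: str,
    ph_ref: float,
    ph_by_year: dict,
    biological: BiologicalStatus,
    delta_threshold: float = DELTA_PH_THRESHOLD,
    species_threshold: float = SPECIES_PH_THRESHOLD,
) -> LakeAssessment:
    """Assess one lake from its pH trajectory and biological status.

    ``ph_by_year`` maps assessment years (typically 1980 and 2010) to the
    modeled pH.  The headline quadrant is taken at the earliest (peak
    impact) assessment year.
    """
    years = sorted(ph_by_year)
    if not years:
        raise AssessmentError(f"lake {lake_id!r}: no assessment years")
    chem = {
        y: chemical_status(ph_ref, ph_by_year[y], delta_threshold, species_threshold)
        for y in years
    }
    quads = {
        y: quadrant(ph_ref, ph_by_year[y], delta_threshold, species_threshold)
        for y in years
    }
    if len(years) >= 2:
        overall = overall_chemical_acidified(chem[years[0]], chem[years[-1]])
    else:
        overall = chem[years[0]].acidified
    try:
        consistency = consistency_category(overall, biological)
    except AssessmentError:
        consistency = None
    return LakeAssessment(
        lake_id=lake_id,
        chemical=chem,
        biological=biological,
        chem_acidified_overall=overall,
        consistency=consistency,
        quadrant=quads[years[0]],
        quadrants=quads,
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Counts and fractions over a set of assessed lakes.

    Percentages are reported rounded to the nearest integer; the exact
    values remain available via the count fields.
    """

    n_lakes: int
    n_acidified: dict            # assessment year -> count (ΔpH criterion)
    n_below_threshold: dict      # year -> count with pH below species threshold
    n_roach_absent_below_threshold: dict  # year -> of those, roach absent
    categories: dict             # Consistency -> count
    n_indefinite: int            # excluded/indeterminate biological status
    n_coherent: int              # categories i + ii
    percent_reduction: int       # acidified count change, first -> last year
    n_recolonized: int           # category-ii lakes with recovery-era presence
    percent_recolonized: int
    quadrants: dict              # Quadrant -> count at the peak assessment


def summarize_ensemble(assessments: list[LakeAssessment]) -> EnsembleSummary:
    """Aggregate per-lake assessments into the ensemble summary."""
    if not assessments:
        raise AssessmentError("cannot summarize an empty assessment list")
    years = sorted({y for a in assessments for y in a.chemical})
    n_acid = {y: 0 for y in years}
    n_below = {y: 0 for y in years}
    n_absent_below = {y: 0 for y in years}
    categories = {c: 0 for c in Consistency}
    quadrants = {q: 0 for q in Quadrant}
    n_indefinite = 0
    n_recolonized = 0
    for a in assessments:
        roach_absent = a.biological.status is Status.ACIDIFIED
        for y, chem in a.chemical.items():
            if chem.acidified:
                n_acid[y] += 1
            if chem.below_threshold:
                n_below[y] += 1
                if roach_absent:
                    n_absent_below[y] += 1
        if a.consistency is None:
            n_indefinite += 1
        else:
            categories[a.consistency] += 1
            if a.consistency is Consistency.II_ACID_BOTH and a.biological.recolonized:
                n_recolonized += 1
        quadrants[a.quadrant] += 1
    n_coherent = categories[Consistency.I_NONACID_BOTH] + categories[Consistency.II_ACID_BOTH]
    first, last = years[0], years[-1]
    if n_acid[first] > 0:
        reduction = 100.0 * (n_acid[first] - n_acid[last]) / n_acid[first]
    else:
        reduction = 0.0
    n_cat_ii = categories[Consistency.II_ACID_BOTH]
    recol_pct = 100.0 * n_recolonized / n_cat_ii if n_cat_ii else 0.0
    return EnsembleSummary(
        n_lakes=len(assessments),
        n_acidified=n_acid,
        n_below_threshold=n_below,
        n_roach_absent_below_threshold=n_absent_below,
        categories=categories,
        n_indefinite=n_indefinite,
        n_coherent=n_coherent,
        percent_reduction=round(reduction),
        n_recolonized=n_recolonized,
        percent_recolonized=round(recol_pct),
        quadrants=quadrants,
    )
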