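"""Delimited-text I/O, configuration and report writing.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal separator.  Outputs are written with fixed float formatting so two
runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .assessment import Consistency, EnsembleSummary, LakeAssessment, Quadrant
from .speciation import EquilibriumConstants, IonComposition, SpeciationResult
from .surveys import (
    LakeSurveyHistory,
    Override,
    SurveyMethod,
    SurveyRecord,
)

__all__ = [
    "ChemistryRecord",
    "InputError",
    "read_chemistry",
    "read_surveys",
    "read_trajectories",
    "load_constants",
    "write_speciation",
    "write_report",
]

log = logging.getLogger("borealacid")

CHEMISTRY_COLUMNS = [
    "lake_id", "year", "ca", "mg", "na", "k", "nh4",
    "so4", "cl", "no3", "f", "toc",
]
OPTIONAL_CHEMISTRY_COLUMNS = ["ph_observed", "temperature"]


class InputError(ValueError):
    pass


class ChemistryRecord:
    """One parsed chemistry row: (lake_id, year, composition, observed pH?)."""

    __slots__ = ("lake_id", "year", "composition", "observed_ph")

    def __init__(self, lake_id, year, composition, observed_ph=None):
        self.lake_id = lake_id
        self.year = year
        self.composition = composition
        self.observed_ph = observed_ph


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path)


def read_chemistry(path) -> list[ChemistryRecord]:
    """Read a lake-chemistry table (μeq/L ions, mg/L TOC).

    Rejects negative concentrations (naming the offending row), warns on
    unknown columns, and treats missing optional columns as absent values,
    never as zeros.
    """
    df = _read_table(path)
    missing = [c for c in CHEMISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    unknown = [
        c for c in df.columns
        if c not in CHEMISTRY_COLUMNS + OPTIONAL_CHEMISTRY_COLUMNS
    ]
    if unknown:
        log.warning("%s: ignoring unknown columns %s", path, unknown)
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based with header
        try:
            comp = IonComposition(
                ca=row["ca"], mg=row["mg"], na=row["na"], k=row["k"],
                nh4=row["nh4"], so4=row["so4"], cl=row["cl"],
                no3=row["no3"], f=row["f"], toc=row["toc"],
                temperature=(
                    float(row["temperature"])
                    if "temperature" in df.columns and pd.notna(row["temperature"])
                    else None
                ),
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}, line {line}: {exc}") from exc
        observed = None
        if "ph_observed" in df.columns and pd.notna(row["ph_observed"]):
            observed = float(row["ph_observed"])
        records.append(
            ChemistryRecord(str(row["lake_id"]), int(row["year"]), comp, observed)
        )
    return records


def read_surveys(path) -> list[LakeSurveyHistory]:
    """Read a survey table (lake_id, year, present, method, source[, expert_override])."""
    df = _read_table(path)
    required = ["lake_id", "year", "present"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    histories: dict[str, LakeSurveyHistory] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        lake_id = str(row["lake_id"])
        try:
            present = bool(int(row["present"]))
            method = SurveyMethod(str(row.get("method", "other")))
            rec = SurveyRecord(
                lake_id=lake_id,
                year=int(row["year"]),
                present=present,
                method=method,
                source=str(row.get("source", "")),
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}, line {line}: {exc}") from exc
        hist = histories.setdefault(lake_id, LakeSurveyHistory(lake_id=lake_id))
        hist.records.append(rec)
        if "expert_override" in df.columns and pd.notna(row["expert_override"]):
            hist.expert_override = Override(str(row["expert_override"]))
    return list(histories.values())


def read_trajectories(path) -> pd.DataFrame:
    """Read a pH trajectory table (lake_id, ph_1860, ph_1980, ph_2010)."""
    df = _read_table(path)
    required = ["lake_id", "ph_1860", "ph_1980", "ph_2010"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def load_constants(path=None, **overrides) -> EquilibriumConstants:
    """Build equilibrium constants from an optional YAML file plus overrides."""
    values = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"{path}: constants file must be a mapping")
        values.update(loaded)
    values.update(overrides)
    if "al_hydrolysis" in values:
        values["al_hydrolysis"] = tuple(values["al_hydrolysis"])
    try:
        return EquilibriumConstants(**values)
    except TypeError as exc:
        raise InputError(f"invalid constants: {exc}") from exc


def write_speciation(results: list[tuple[str, int, SpeciationResult]], path) -> None:
    """Write solved speciation rows mirroring the result fields."""
    rows = [
        {"lake_id": lake_id, "year": year, **asdict(res)}
        for lake_id, year, res in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def assessments_frame(assessments: list[LakeAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        row = {
            "lake_id": a.lake_id,
            "biological_status": a.biological.status.value,
            "p1_fraction": a.biological.p1.fraction,
            "p2_fraction": a.biological.p2.fraction,
            "p3_fraction": a.biological.p3.fraction,
            "recolonized": int(a.biological.recolonized),
            "chem_acidified_overall": int(a.chem_acidified_overall),
            "consistency": a.consistency.value if a.consistency else "",
            "quadrant": a.quadrant.value,
            "exclusion_reason": a.biological.exclusion_reason,
        }
        for year, chem in sorted(a.chemical.items()):
            row[f"ph_{year}"] = chem.ph_assess
            row["ph_ref"] = chem.ph_ref
            row[f"delta_ph_{year}"] = chem.delta_ph
            row[f"acidified_{year}"] = int(chem.acidified)
            row[f"below_threshold_{year}"] = int(chem.below_threshold)
            row[f"quadrant_{year}"] = a.quadrants[year].value
        rows.append(row)
    return pd.DataFrame(rows)


def summary_dict(summary: EnsembleSummary) -> dict:
    return {
        "n_lakes": summary.n_lakes,
        "n_acidified": {str(y): v for y, v in summary.n_acidified.items()},
        "n_below_threshold": {str(y): v for y, v in summary.n_below_threshold.items()},
        "n_roach_absent_below_threshold": {
            str(y): v for y, v in summary.n_roach_absent_below_threshold.items()
        },
        "categories": {c.value: n for c, n in summary.categories.items()},
        "n_indefinite": summary.n_indefinite,
        "n_coherent": summary.n_coherent,
        "percent_reduction": summary.percent_reduction,
        "n_recolonized": summary.n_recolonized,
        "percent_recolonized": summary.percent_recolonized,
        "quadrants": {q.value: n for q, n in summary.quadrants.items()},
    }


def _summary_text(summary: EnsembleSummary) -> str:
    cats = summary.categories
    lines = [
        "Acidification assessment summary",
        "================================",
        f"lakes assessed:              {summary.n_lakes}",
    ]
    for year in sorted(summary.n_acidified):
        lines.append(
            f"acidified (dpH > 0.4) {year}:  {summary.n_acidified[year]}"
            f"   below species threshold: {summary.n_below_threshold[year]}"
            f" (roach absent: {summary.n_roach_absent_below_threshold[year]})"
        )
    lines += [
        f"reduction in acidified lakes: {summary.percent_reduction}%",
        "",
        "consistency contingency:",
        f"  i   nonacidified by both:            {cats[Consistency.I_NONACID_BOTH]}",
        f"  ii  acidified by both:               {cats[Consistency.II_ACID_BOTH]}",
        f"  iii chemically acid, roach present:  {cats[Consistency.III_CHEM_ACID_ROACH_PRESENT]}",
        f"  iv  chemically nonacid, roach absent:{cats[Consistency.IV_CHEM_NONACID_ROACH_ABSENT]}",
        f"  coherently classified:               {summary.n_coherent}",
        f"  indefinite biological status:        {summary.n_indefinite}",
        "",
        f"recolonized (of category ii): {summary.n_recolonized}"
        f" ({summary.percent_recolonized}%)",
        "",
        "conceptual quadrants (peak assessment): "
        + ", ".join(f"{q.value}={n}" for q, n in summary.quadrants.items()),
        "",
    ]
    return "\n".join(lines)


def write_report(
    summary: EnsembleSummary,
    assessments: list[LakeAssessment],
    outdir,
) -> dict[str, Path]:
    """Write the per-lake table, machine-readable summary and text report.

    Deterministic: identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lakes": outdir / "lake_assessments.csv",
        "summary_json": outdir / "summary.json",
        "summary_txt": outdir / "summary.txt",
    }
    assessments_frame(assessments).to_csv(
        paths["lakes"], index=False, float_format="%.4f"
    )
    paths["summary_json"].write_text(
        json.dumps(summary_dict(summary), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    paths["summary_txt"].write_text(_summary_text(summary), encoding="utf-8")
    return paths
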