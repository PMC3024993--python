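"""End-to-end orchestration: validated records → cohort → all report tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .ascertainment import AscertainmentResult, AscertainmentTable, classify, tabulate
from .cohort import CohortSpec, DeathAttachmentLog, build_cohort
from .records import (
    AdmissionRecord,
    DeathRecord,
    LinkedPerson,
    ValidationReport,
    read_admissions,
    read_deaths,
)
from .stats import CrossTab, death_cross_tab
from .stratified import (
    FACTORS,
    build_person_frame,
    completeness_by_stratum,
    summaries_to_frame,
    underestimation_by_factor,
)

__all__ = ["AnalysisResult", "analyse", "analyse_files"]


@dataclass
class AnalysisResult:
    """Everything one analysis run produces, ready to export."""

    persons: list[LinkedPerson]
    results: list[AscertainmentResult]
    table: AscertainmentTable
    cross_tab: CrossTab | None
    person_frame: pd.DataFrame
    strata: dict[str, pd.DataFrame]
    completeness: pd.DataFrame
    death_log: DeathAttachmentLog
    conf_level: float

    @property
    def n_deaths(self) -> int:
        return sum(1 for r in self.results if r.death_flag is not None)

    def estimates_frame(self) -> pd.DataFrame:
        """Headline ratio estimates as exportable rows."""
        rows = []
        if self.cross_tab is not None and self.cross_tab.union_positive_total > 0:
            for name, est in [
                ("death_record_underascertainment_pct",
                 self.cross_tab.underascertainment(self.conf_level)),
                ("missingness_rr", self.cross_tab.missingness_rr(self.conf_level)),
            ]:
                rows.append(
                    {
                        "quantity": name,
                        "estimate": est.point,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "conf_level": est.conf_level,
                        "method": est.method.value,
                        "cells": ";".join(f"{k}={v}" for k, v in est.cells.items()),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["table1"] = outdir / "table1.csv"
        self.table.to_frame().to_csv(paths["table1"])

        if self.cross_tab is not None:
            paths["table2"] = outdir / "table2.csv"
            self.cross_tab.to_frame().to_csv(paths["table2"])

        table3 = pd.concat(self.strata.values(), ignore_index=True)
        paths["table3"] = outdir / "table3.csv"
        table3.to_csv(paths["table3"], index=False)

        paths["estimates"] = outdir / "estimates.csv"
        self.estimates_frame().to_csv(paths["estimates"], index=False)

        paths["completeness"] = outdir / "completeness.csv"
        self.completeness.to_csv(paths["completeness"], index=False)
        return paths


def analyse(
    admissions: Iterable[AdmissionRecord],
    deaths: Iterable[DeathRecord] = (),
    spec: CohortSpec | None = None,
    conf_level: float = 0.95,
) -> AnalysisResult:
    """Run cohort assembly, classification and every summary table."""
    spec = spec or CohortSpec()
    admissions = list(admissions)
    persons, death_log = build_cohort(admissions, deaths, spec)
    results = [classify(p) for p in persons]
    table = tabulate(results)
    has_deaths = any(r.death_flag is not None for r in results)
    cross_tab = death_cross_tab(results) if has_deaths else None
    frame = build_person_frame(persons, results)
    strata = {
        factor: summaries_to_frame(underestimation_by_factor(frame, factor))
        for factor in FACTORS
    } if len(frame) else {}
    all_records = [rec for p in persons for rec in p.lookback]
    completeness = completeness_by_stratum(all_records) if all_records else pd.DataFrame()
    return AnalysisResult(
        persons=persons,
        results=results,
        table=table,
        cross_tab=cross_tab,
        person_frame=frame,
        strata=strata,
        completeness=completeness,
        death_log=death_log,
        conf_level=conf_level,
    )


def analyse_files(
    admissions_path: str | Path,
    deaths_path: str | Path | None = None,
    spec: CohortSpec | None = None,
    conf_level: float = 0.95,
    strict: bool = False,
) -> tuple[AnalysisResult, ValidationReport, ValidationReport]:
    """Read, validate and analyse CSV extracts; returns validation reports too."""
    admissions, adm_report = read_admissions(admissions_path, strict=strict)
    if deaths_path is None:
        deaths: list[DeathRecord] = []
        death_report = ValidationReport()
    else:
        deaths, death_report = read_deaths(deaths_path, strict=strict)
    return analyse(admissions, deaths, spec, conf_level), adm_report, death_report
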