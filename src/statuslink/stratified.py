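"""Completeness audits and under-ascertainment stratified by demography.

Two band presets exist because the source conventions differ: completeness
audits use 0-24 / 25-44 / 45-64 / 65+ while the under-ascertainment table
uses 0-34 / 35-64 / 65+.  Stratum attributes (sex, age, SEIFA quintile, ARIA
remoteness, region) are read from the index admission; persons with an absent
SEIFA or ARIA value appear as an explicit "unknown" level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ascertainment import AscertainmentResult
from .records import AdmissionRecord, IndigenousFlag, LinkedPerson, interpret_raw_code
from .stats import ChiSquareResult, chi_square, excess_pct

__all__ = [
    "COMPLETENESS_AGE_BANDS",
    "TABLE_AGE_BANDS",
    "StratumSummary",
    "age_band",
    "build_person_frame",
    "completeness_by_stratum",
    "underestimation_by_factor",
    "compare_strata",
]

# (label, inclusive lower bound) — upper bound implied by the next band
COMPLETENESS_AGE_BANDS: tuple[tuple[str, int], ...] = (
    ("0-24", 0),
    ("25-44", 25),
    ("45-64", 45),
    ("65+", 65),
)
TABLE_AGE_BANDS: tuple[tuple[str, int], ...] = (
    ("0-34", 0),
    ("35-64", 35),
    ("65+", 65),
)

FACTORS = ("sex", "age_band", "seifa", "aria", "region")


def age_band(age: int, bands: Sequence[tuple[str, int]] = TABLE_AGE_BANDS) -> str:
    label = bands[0][0]
    for name, lower in bands:
        if age >= lower:
            label = name
    return label


def _level(value) -> str:
    return "unknown" if value is None else str(value)


def build_person_frame(
    persons: Iterable[LinkedPerson],
    results: Iterable[AscertainmentResult],
    bands: Sequence[tuple[str, int]] = TABLE_AGE_BANDS,
) -> pd.DataFrame:
    """One row per person: determination outcomes joined with index attributes."""
    res_by_id = {r.person_id: r for r in results}
    rows = []
    for person in persons:
        res = res_by_id[person.person_id]
        idx = person.index
        rows.append(
            {
                "person_id": person.person_id,
                "sex": idx.sex.value,
                "age_years": idx.age_years,
                "age_band": age_band(idx.age_years, bands),
                "seifa": _level(idx.seifa_quintile),
                "aria": _level(idx.aria_category),
                "region": idx.region.value,
                "index_year": idx.admission_date.year,
                "index_pos": res.index_pos,
                "index_or_death_pos": res.index_or_death_pos,
                "majority_pos": res.majority_pos,
                "ever_pos": res.ever_pos,
                "has_death": res.death_flag is not None,
            }
        )
    return pd.DataFrame(rows)


def completeness_by_stratum(
    records: Iterable[AdmissionRecord],
    bands: Sequence[tuple[str, int]] = COMPLETENESS_AGE_BANDS,
    period_split_year: int = 2000,
) -> pd.DataFrame:
    """Missingness of the status flag per record, by region/age/sex/period.

    Returns a tidy frame (factor, level, n_records, n_missing, pct_complete)
    where the period factor splits records at ``period_split_year`` of the
    admission date (pre-period vs study period).
    """
    rows = []
    for rec in records:
        missing = interpret_raw_code(rec.raw_status) is IndigenousFlag.MISSING
        period = (
            f"{period_split_year}+"
            if rec.admission_date.year >= period_split_year
            else f"pre-{period_split_year}"
        )
        rows.append(
            {
                "region": rec.region.value,
                "age_group": age_band(rec.age_years, bands),
                "sex": rec.sex.value,
                "period": period,
                "missing": missing,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for factor in ("region", "age_group", "sex", "period"):
        grouped = df.groupby(factor, sort=True)["missing"].agg(["size", "sum"])
        for level, (n, n_missing) in grouped.iterrows():
            out.append(
                {
                    "factor": factor,
                    "level": str(level),
                    "n_records": int(n),
                    "n_missing_flag": int(n_missing),
                    "pct_complete": 100.0 * (1 - n_missing / n),
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class StratumSummary:
    """Index vs ever-identified counts for one level of one factor."""

    factor: str
    level: str
    index_count: int
    ever_count: int
    underestimate_pct: float | None  # excess of ever over index, percent

    def __post_init__(self) -> None:
        if not 0 <= self.index_count <= self.ever_count:
            raise ValueError("expected 0 <= index_count <= ever_count")


def underestimation_by_factor(
    person_frame: pd.DataFrame, factor: str
) -> list[StratumSummary]:
    """Per-level index-positive and ever-positive counts with the excess percent.

    The reported percentage is the increase of the ever-identified count over
    the index count relative to the index baseline, the convention of the
    demographic under-ascertainment table; a level with no index positives
    has an undefined percentage (None).
    """
    if factor not in person_frame.columns:
        raise KeyError(f"unknown stratification factor {factor!r}; have {FACTORS}")
    summaries = []
    for level, group in person_frame.groupby(factor, sort=True):
        index_count = int(group["index_pos"].sum())
        ever_count = int(group["ever_pos"].sum())
        pct = (
            excess_pct(index_count, ever_count - index_count, ndigits=None)
            if index_count > 0
            else None
        )
        summaries.append(StratumSummary(factor, str(level), index_count, ever_count, pct))
    return summaries


def summaries_to_frame(summaries: Iterable[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def compare_strata(summaries: Sequence[StratumSummary]) -> ChiSquareResult:
    """Chi-square test of heterogeneity of under-ascertainment across levels.

    Builds the levels × (newly-identified, index-identified) count table and
    tests independence; requires at least two levels.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two strata to compare")
    table = [
        [s.ever_count - s.index_count, s.index_count] for s in summaries
    ]
    return chi_square(table)
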