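"""Domain records for linked hospital-morbidity and death data.

The unit of analysis is a person assembled from administrative records that a
data-linkage system has already resolved to a common identifier: hospital
separations (admissions) carrying an Indigenous-status flag, and at most one
death registration.  The status field has two coding eras: a legacy binary
scheme (1 = not Aboriginal, 2 = Aboriginal) used before 2000, and a
four-category scheme (1 = Aboriginal, 2 = Torres Strait Islander, 3 = both,
4 = neither) with a 'not stated/inadequately described' provision.  WA public
hospitals record 'not stated' and 'neither' identically, so an absent code on
a WA public four-category record reads back as a stated negative — the
informative collapsing this package exists to quantify.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IndigenousFlag",
    "CodingEra",
    "RecordSource",
    "Sector",
    "Sex",
    "Region",
    "IcdVersion",
    "RawStatusCode",
    "AdmissionRecord",
    "DeathRecord",
    "LinkedPerson",
    "CodingError",
    "SchemaError",
    "DuplicatePersonError",
    "ValidationIssue",
    "ValidationReport",
    "interpret_raw_code",
    "recode_legacy",
    "read_admissions",
    "read_deaths",
    "write_admissions",
    "write_deaths",
    "admissions_from_frame",
    "deaths_from_frame",
    "admissions_to_frame",
    "deaths_to_frame",
]


class IndigenousFlag(enum.Enum):
    """Tri-state semantic interpretation of a raw status code."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class CodingEra(enum.Enum):
    LEGACY_BINARY = "LEGACY_BINARY"
    FOUR_CATEGORY = "FOUR_CATEGORY"


class RecordSource(enum.Enum):
    HOSPITAL_PUBLIC_WA = "HOSPITAL_PUBLIC_WA"
    HOSPITAL_OTHER = "HOSPITAL_OTHER"
    DEATH = "DEATH"


class Sector(enum.Enum):
    PUBLIC = "PUBLIC"
    PRIVATE = "PRIVATE"


class Sex(enum.Enum):
    M = "M"
    F = "F"


class Region(enum.Enum):
    METRO = "METRO"
    NON_METRO = "NON_METRO"


class IcdVersion(enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10AM = "ICD10AM"


class CodingError(ValueError):
    """A raw status code outside the documented domain of its coding era."""


class SchemaError(ValueError):
    """An input file is missing mandatory columns."""


class DuplicatePersonError(ValueError):
    """More than one death record for a person identifier."""


@dataclass(frozen=True, slots=True)
class RawStatusCode:
    """A status code as recorded, before semantic interpretation.

    ``code`` is the integer as written (``None`` when the field is empty),
    ``era`` the coding scheme in force when the record was created, and
    ``source`` the collection it came from — interpretation of an absent code
    depends on all three.
    """

    code: int | None
    era: CodingEra
    source: RecordSource


def interpret_raw_code(raw: RawStatusCode, *, tsi_positive: bool = True) -> IndigenousFlag:
    """Map a raw era-specific code to POSITIVE / NEGATIVE / MISSING.

    Legacy binary: 1 → NEGATIVE, 2 → POSITIVE; an empty field (seen only in
    the earliest records) → MISSING.  Four-category: 1/2/3 → POSITIVE,
    4 → NEGATIVE; an empty field → MISSING except on WA public hospital
    records, where 'not stated' is recorded identically to 'neither' and the
    absence therefore reads back as NEGATIVE.

    ``tsi_positive`` controls whether Torres-Strait-Islander-only (code 2 of
    the four-category scheme) counts as POSITIVE; the analysis treats the
    single Indigenous flag inclusively by convention.
    """
    if raw.era is CodingEra.LEGACY_BINARY:
        if raw.code is None:
            return IndigenousFlag.MISSING
        if raw.code == 1:
            return IndigenousFlag.NEGATIVE
        if raw.code == 2:
            return IndigenousFlag.POSITIVE
        raise CodingError(f"code {raw.code!r} invalid for LEGACY_BINARY era ({raw.source.value})")
    # four-category era
    if raw.code is None:
        if raw.source is RecordSource.HOSPITAL_PUBLIC_WA:
            return IndigenousFlag.NEGATIVE
        return IndigenousFlag.MISSING
    if raw.code in (1, 3):
        return IndigenousFlag.POSITIVE
    if raw.code == 2:
        return IndigenousFlag.POSITIVE if tsi_positive else IndigenousFlag.NEGATIVE
    if raw.code == 4:
        return IndigenousFlag.NEGATIVE
    raise CodingError(f"code {raw.code!r} invalid for FOUR_CATEGORY era ({raw.source.value})")


def recode_legacy(code: int) -> int:
    """Recode a legacy binary value to its four-category equivalent.

    The 1999 register-wide recode mapped old 1 (not Aboriginal) to new 4
    (neither) and old 2 (Aboriginal) to new 3 (both).
    """
    mapping = {1: 4, 2: 3}
    try:
        return mapping[code]
    except KeyError:
        raise CodingError(f"code {code!r} outside legacy binary domain {{1, 2}}") from None


@dataclass(frozen=True, slots=True)
class AdmissionRecord:
    person_id: str
    admission_date: dt.date
    separation_date: dt.date
    principal_dx: str
    icd_version: IcdVersion
    sector: Sector
    same_day: bool
    raw_status: RawStatusCode
    sex: Sex
    age_years: int
    region: Region
    seifa_quintile: int | None
    aria_category: int | None

    def flag(self, **kw) -> IndigenousFlag:
        return interpret_raw_code(self.raw_status, **kw)


@dataclass(frozen=True, slots=True)
class DeathRecord:
    person_id: str
    death_date: dt.date
    raw_status: RawStatusCode

    def flag(self, **kw) -> IndigenousFlag:
        return interpret_raw_code(self.raw_status, **kw)


@dataclass(frozen=True, slots=True)
class LinkedPerson:
    """One person's index admission, lookback history and optional death.

    ``lookback`` is chronological and contains the index record exactly once;
    every record shares ``person_id``.
    """

    person_id: str
    index: AdmissionRecord
    lookback: tuple[AdmissionRecord, ...]
    death: DeathRecord | None = None


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    row: int  # 1-based data row number (header excluded)
    field: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, row: int, fld: str, message: str) -> None:
        self.issues.append(ValidationIssue(row, fld, message))

    def summary(self) -> str:
        if self.ok:
            return "0 validation issues"
        head = "\n".join(
            f"  row {i.row}: [{i.field}] {i.message}" for i in self.issues[:20]
        )
        more = "" if len(self.issues) <= 20 else f"\n  ... and {len(self.issues) - 20} more"
        return f"{len(self.issues)} validation issue(s):\n{head}{more}"


ADMISSION_COLUMNS = [
    "person_id",
    "admission_date",
    "separation_date",
    "principal_dx",
    "icd_version",
    "sector",
    "same_day",
    "status_code",
    "status_era",
    "sex",
    "age_years",
    "region",
    "seifa_quintile",
    "aria_category",
]

DEATH_COLUMNS = ["person_id", "death_date", "status_code", "status_era"]


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text)


def _parse_optional_int(text: str, lo: int, hi: int, fld: str) -> int | None:
    if text == "":
        return None
    value = int(text)
    if not lo <= value <= hi:
        raise ValueError(f"{fld} {value} outside [{lo}, {hi}]")
    return value


def _status_source(sector: Sector) -> RecordSource:
    # All public admissions in scope are WA public hospitals; private and
    # interstate records retain a genuine 'not stated' state.
    return RecordSource.HOSPITAL_PUBLIC_WA if sector is Sector.PUBLIC else RecordSource.HOSPITAL_OTHER


def _parse_admission_row(row_no: int, row) -> AdmissionRecord:
    admission = _parse_date(row.admission_date)
    separation = _parse_date(row.separation_date)
    if separation < admission:
        raise ValueError(
            f"separation_date {separation} precedes admission_date {admission}"
        )
    same_day = row.same_day in ("1", "true", "True")
    if same_day != (admission == separation):
        raise ValueError("same_day flag inconsistent with admission/separation dates")
    sector = Sector(row.sector)
    era = CodingEra(row.status_era)
    code = None if row.status_code == "" else int(row.status_code)
    raw = RawStatusCode(code=code, era=era, source=_status_source(sector))
    interpret_raw_code(raw)  # raises CodingError for out-of-domain codes
    age = int(row.age_years)
    if age < 0:
        raise ValueError(f"age_years {age} negative")
    return AdmissionRecord(
        person_id=row.person_id,
        admission_date=admission,
        separation_date=separation,
        principal_dx=row.principal_dx,
        icd_version=IcdVersion(row.icd_version),
        sector=sector,
        same_day=same_day,
        raw_status=raw,
        sex=Sex(row.sex),
        age_years=age,
        region=Region(row.region),
        seifa_quintile=_parse_optional_int(row.seifa_quintile, 1, 5, "seifa_quintile"),
        aria_category=_parse_optional_int(row.aria_category, 1, 5, "aria_category"),
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing mandatory column(s): {', '.join(missing)}")


def admissions_from_frame(
    df: pd.DataFrame, *, strict: bool = False
) -> tuple[list[AdmissionRecord], ValidationReport]:
    """Parse a string-typed admissions frame; invalid rows go to the report.

    Administrative extracts are dirty, so the default collects row-level
    problems rather than failing; ``strict=True`` raises on the first issue.
    """
    _require_columns(df, ADMISSION_COLUMNS, "admissions")
    report = ValidationReport()
    records: list[AdmissionRecord] = []
    for i, row in enumerate(df.astype(str).itertuples(index=False), start=1):
        try:
            records.append(_parse_admission_row(i, row))
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(f"admissions row {i}: {exc}") from exc
            report.add(i, "row", str(exc))
    return records, report


def deaths_from_frame(
    df: pd.DataFrame, *, strict: bool = False
) -> tuple[list[DeathRecord], ValidationReport]:
    _require_columns(df, DEATH_COLUMNS, "deaths")
    report = ValidationReport()
    records: list[DeathRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.astype(str).itertuples(index=False), start=1):
        if row.person_id in seen:
            raise DuplicatePersonError(
                f"deaths row {i}: duplicate death record for person_id {row.person_id!r}"
            )
        seen.add(row.person_id)
        try:
            code = None if row.status_code == "" else int(row.status_code)
            raw = RawStatusCode(code=code, era=CodingEra(row.status_era), source=RecordSource.DEATH)
            interpret_raw_code(raw)
            records.append(
                DeathRecord(
                    person_id=row.person_id,
                    death_date=_parse_date(row.death_date),
                    raw_status=raw,
                )
            )
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(f"deaths row {i}: {exc}") from exc
            report.add(i, "row", str(exc))
    return records, report


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_admissions(
    path: str | Path, *, strict: bool = False
) -> tuple[list[AdmissionRecord], ValidationReport]:
    """Read and validate an admissions CSV (schema in :data:`ADMISSION_COLUMNS`)."""
    return admissions_from_frame(_read_csv(path), strict=strict)


def read_deaths(
    path: str | Path, *, strict: bool = False
) -> tuple[list[DeathRecord], ValidationReport]:
    return deaths_from_frame(_read_csv(path), strict=strict)


def _fmt_opt(value) -> str:
    return "" if value is None else str(value)


def admissions_to_frame(records: Iterable[AdmissionRecord]) -> pd.DataFrame:
    rows = [
        (
            r.person_id,
            r.admission_date.isoformat(),
            r.separation_date.isoformat(),
            r.principal_dx,
            r.icd_version.value,
            r.sector.value,
            "1" if r.same_day else "0",
            _fmt_opt(r.raw_status.code),
            r.raw_status.era.value,
            r.sex.value,
            str(r.age_years),
            r.region.value,
            _fmt_opt(r.seifa_quintile),
            _fmt_opt(r.aria_category),
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=ADMISSION_COLUMNS)


def deaths_to_frame(records: Iterable[DeathRecord]) -> pd.DataFrame:
    rows = [
        (r.person_id, r.death_date.isoformat(), _fmt_opt(r.raw_status.code), r.raw_status.era.value)
        for r in records
    ]
    return pd.DataFrame(rows, columns=DEATH_COLUMNS)


def write_admissions(records: Iterable[AdmissionRecord], path: str | Path) -> None:
    admissions_to_frame(records).to_csv(path, index=False)


def write_deaths(records: Iterable[DeathRecord], path: str | Path) -> None:
    deaths_to_frame(records).to_csv(path, index=False)
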