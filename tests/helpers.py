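"""Builders for hand-crafted linked persons used across the test modules."""

from __future__ import annotations

import datetime as dt

from statuslink.records import (
    AdmissionRecord,
    CodingEra,
    DeathRecord,
    IcdVersion,
    IndigenousFlag,
    LinkedPerson,
    RawStatusCode,
    RecordSource,
    Region,
    Sector,
    Sex,
)

INDEX_DATE = dt.date(2003, 5, 10)

_FOUR_CAT_CODE = {
    IndigenousFlag.POSITIVE: 1,
    IndigenousFlag.NEGATIVE: 4,
    IndigenousFlag.MISSING: None,
}


def make_admission(
    pid: str = "p1",
    adm: dt.date = INDEX_DATE,
    los: int = 1,
    dx: str = "I21",
    sector: Sector = Sector.PUBLIC,
    flag: IndigenousFlag = IndigenousFlag.NEGATIVE,
    sex: Sex = Sex.M,
    age: int = 60,
    region: Region = Region.METRO,
    seifa: int | None = 3,
    aria: int | None = 1,
    icd: IcdVersion = IcdVersion.ICD10AM,
) -> AdmissionRecord:
    # a MISSING flag needs a non-WA-public source to survive interpretation,
    # so missing-flag records are emitted as private-sector by default
    if flag is IndigenousFlag.MISSING and sector is Sector.PUBLIC:
        sector = Sector.PRIVATE
    source = (
        RecordSource.HOSPITAL_PUBLIC_WA
        if sector is Sector.PUBLIC
        else RecordSource.HOSPITAL_OTHER
    )
    return AdmissionRecord(
        person_id=pid,
        admission_date=adm,
        separation_date=adm + dt.timedelta(days=los),
        principal_dx=dx,
        icd_version=icd,
        sector=sector,
        same_day=los == 0,
        raw_status=RawStatusCode(_FOUR_CAT_CODE[flag], CodingEra.FOUR_CATEGORY, source),
        sex=sex,
        age_years=age,
        region=region,
        seifa_quintile=seifa,
        aria_category=aria,
    )


def make_death(
    pid: str = "p1",
    flag: IndigenousFlag = IndigenousFlag.NEGATIVE,
    date: dt.date = dt.date(2004, 8, 1),
) -> DeathRecord:
    return DeathRecord(
        person_id=pid,
        death_date=date,
        raw_status=RawStatusCode(
            _FOUR_CAT_CODE[flag], CodingEra.FOUR_CATEGORY, RecordSource.DEATH
        ),
    )


def make_person(
    flags: list[IndigenousFlag],
    death_flag: IndigenousFlag | None = None,
    pid: str = "p1",
) -> LinkedPerson:
    """A linked person whose lookback flags are ``flags`` (index is last)."""
    records = [
        make_admission(
            pid=pid,
            adm=INDEX_DATE - dt.timedelta(days=30 * (len(flags) - 1 - i)),
            flag=f,
            dx="I21" if i == len(flags) - 1 else "J18",
            sector=Sector.PUBLIC if i == len(flags) - 1 else Sector.PRIVATE,
        )
        for i, f in enumerate(flags)
    ]
    death = make_death(pid, death_flag) if death_flag is not None else None
    return LinkedPerson(person_id=pid, index=records[-1], lookback=tuple(records), death=death)
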