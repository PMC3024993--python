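"""Cohort assembly from validated admission and death records.

Selects each person's index admission (most recent qualifying cardiovascular
separation in the study window), assembles the 20-year lookback history with
the routine-dialysis exclusion, and attaches any subsequent in-window death.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import AdmissionRecord, DeathRecord, LinkedPerson, Sector

__all__ = [
    "CohortSpec",
    "select_index",
    "build_lookback",
    "attach_deaths",
    "build_cohort",
]


def _years_before(date: dt.date, years: int) -> dt.date:
    """The calendar date ``years`` before ``date`` (29 Feb falls back to 28)."""
    try:
        return date.replace(year=date.year - years)
    except ValueError:
        return date.replace(year=date.year - years, day=28)


def normalise_dx(code: str) -> str:
    """Normalise an ICD code for prefix matching (upper-case, dots stripped)."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility and window parameters for cohort construction.

    Defaults encode the study design: WA public-hospital cardiovascular
    separations (ICD-10-AM chapter I) during 2000–2005, ages 25–74, with a
    20-year any-cause lookback excluding same-day routine-dialysis episodes
    (ICD-9-CM V56 / ICD-10-AM Z49).
    """

    window_start: dt.date = dt.date(2000, 1, 1)
    window_end: dt.date = dt.date(2005, 12, 31)
    age_min: int = 25
    age_max: int = 74
    dx_prefixes: tuple[str, ...] = ("I",)
    index_sector: Sector = Sector.PUBLIC
    lookback_years: int = 20
    dialysis_exclusion_codes: tuple[str, ...] = ("V56", "Z49")

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start must not exceed window_end")
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["window_start"] = self.window_start.isoformat()
        payload["window_end"] = self.window_end.isoformat()
        payload["index_sector"] = self.index_sector.value
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        payload = json.loads(Path(path).read_text())
        payload["window_start"] = dt.date.fromisoformat(payload["window_start"])
        payload["window_end"] = dt.date.fromisoformat(payload["window_end"])
        payload["index_sector"] = Sector(payload["index_sector"])
        payload["dx_prefixes"] = tuple(payload["dx_prefixes"])
        payload["dialysis_exclusion_codes"] = tuple(payload["dialysis_exclusion_codes"])
        return cls(**payload)


def _qualifies_as_index(rec: AdmissionRecord, spec: CohortSpec) -> bool:
    if not (spec.window_start <= rec.separation_date <= spec.window_end):
        return False
    if rec.sector is not spec.index_sector:
        return False
    if not (spec.age_min <= rec.age_years <= spec.age_max):
        return False
    dx = normalise_dx(rec.principal_dx)
    return any(dx.startswith(p) for p in spec.dx_prefixes)


def select_index(
    admissions: Iterable[AdmissionRecord], spec: CohortSpec
) -> dict[str, AdmissionRecord]:
    """Pick each person's index admission.

    The index is the qualifying admission with the latest separation date;
    ties broken by latest admission date, then first seen in input order.
    Persons with no qualifying admission are absent from the result.
    """
    index: dict[str, AdmissionRecord] = {}
    for rec in admissions:
        if not _qualifies_as_index(rec, spec):
            continue
        best = index.get(rec.person_id)
        if best is None:
            index[rec.person_id] = rec
        elif (rec.separation_date, rec.admission_date) > (
            best.separation_date,
            best.admission_date,
        ):
            index[rec.person_id] = rec
    return index


def _is_excluded_dialysis(rec: AdmissionRecord, spec: CohortSpec) -> bool:
    # Exclusion requires BOTH conditions: a same-day separation AND a
    # routine-dialysis principal diagnosis.  Overnight dialysis stays in.
    if not rec.same_day:
        return False
    dx = normalise_dx(rec.principal_dx)
    return any(dx.startswith(c) for c in spec.dialysis_exclusion_codes)


def build_lookback(
    admissions: Iterable[AdmissionRecord],
    index_map: Mapping[str, AdmissionRecord],
    spec: CohortSpec,
) -> dict[str, list[AdmissionRecord]]:
    """Assemble each indexed person's chronological lookback history.

    Includes admissions of any cause and either sector with admission date in
    the half-open interval (index admission date − lookback_years, index
    admission date], minus same-day routine-dialysis separations.  The index
    record itself is always included.
    """
    lookback: dict[str, list[AdmissionRecord]] = {pid: [] for pid in index_map}
    for rec in admissions:
        idx = index_map.get(rec.person_id)
        if idx is None:
            continue
        window_left = _years_before(idx.admission_date, spec.lookback_years)
        if not (window_left < rec.admission_date <= idx.admission_date):
            continue
        if rec is not idx and _is_excluded_dialysis(rec, spec):
            continue
        lookback[rec.person_id].append(rec)
    for pid, recs in lookback.items():
        recs.sort(key=lambda r: (r.admission_date, r.separation_date))
        if index_map[pid] not in recs:  # defensive: index must be present once
            recs.append(index_map[pid])
            recs.sort(key=lambda r: (r.admission_date, r.separation_date))
    return lookback


@dataclass
class DeathAttachmentLog:
    """Anomalies noticed while attaching deaths (kept, not fatal)."""

    before_index: list[str] = field(default_factory=list)
    after_window: list[str] = field(default_factory=list)
    unindexed: int = 0


def attach_deaths(
    index_map: Mapping[str, AdmissionRecord],
    lookback_map: Mapping[str, Sequence[AdmissionRecord]],
    deaths: Iterable[DeathRecord],
    spec: CohortSpec,
) -> tuple[list[LinkedPerson], DeathAttachmentLog]:
    """Attach subsequent in-window deaths and emit the final linked persons.

    A death is attached iff it falls on or after the index separation and
    within the study window.  Deaths of persons without an index admission are
    ignored — dying in-window does not create a cohort member.  A death dated
    before the index separation is an anomaly: logged, not attached.
    """
    log = DeathAttachmentLog()
    death_by_person: dict[str, DeathRecord] = {}
    for death in deaths:
        idx = index_map.get(death.person_id)
        if idx is None:
            log.unindexed += 1
            continue
        if death.death_date < idx.separation_date:
            log.before_index.append(death.person_id)
            continue
        if death.death_date > spec.window_end:
            log.after_window.append(death.person_id)
            continue
        death_by_person[death.person_id] = death

    persons = [
        LinkedPerson(
            person_id=pid,
            index=idx,
            lookback=tuple(lookback_map.get(pid, (idx,))),
            death=death_by_person.get(pid),
        )
        for pid, idx in index_map.items()
    ]
    return persons, log


def build_cohort(
    admissions: Iterable[AdmissionRecord],
    deaths: Iterable[DeathRecord],
    spec: CohortSpec | None = None,
) -> tuple[list[LinkedPerson], DeathAttachmentLog]:
    """Convenience pipeline: select_index → build_lookback → attach_deaths."""
    spec = spec or CohortSpec()
    admissions = list(admissions)
    index_map = select_index(admissions, spec)
    lookback_map = build_lookback(admissions, index_map, spec)
    return attach_deaths(index_map, lookback_map, deaths, spec)
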