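"""The four person-level status-determination rules and their tabulation.

Each linked person is classified under four progressively less conservative
rules:

(i)   index — positive flag on the index admission only (baseline);
(ii)  index+death — index flag or a positive death-record flag;
(iii) majority+death — positive flag on at least 50% of flagged hospital
      records over the lookback (index included), or a positive death flag;
(iv)  ever+death — positive flag on any hospital record, or a positive death
      flag (ever identified).

Missing flags never count toward either side of a rule; a person with no
flagged hospital records is decided by the death record alone under (iii).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import IndigenousFlag, LinkedPerson, interpret_raw_code
from .stats import excess_pct, round_half_up, underestimation_pct

__all__ = ["AscertainmentResult", "AscertainmentTable", "METHODS", "classify", "tabulate"]

METHODS = ("index", "index_death", "majority_death", "ever_death")


@dataclass(frozen=True, slots=True)
class AscertainmentResult:
    """One person's status under each determination rule.

    ``n_flagged_records`` counts hospital records (index + lookback) with a
    non-missing flag; ``n_positive_records`` those flagged positive.
    """

    person_id: str
    index_pos: bool
    index_or_death_pos: bool
    majority_pos: bool
    ever_pos: bool
    n_flagged_records: int
    n_positive_records: int
    death_flag: IndigenousFlag | None

    @property
    def majority_morbidity_pos(self) -> bool:
        """The ≥50% rule over hospital records alone (no death OR-term)."""
        return self.n_flagged_records > 0 and 2 * self.n_positive_records >= self.n_flagged_records

    @property
    def ever_morbidity_pos(self) -> bool:
        """Any positive hospital record (no death OR-term)."""
        return self.n_positive_records >= 1


def classify(person: LinkedPerson) -> AscertainmentResult:
    """Apply the four determination rules to one linked person.

    The majority denominator is the flagged hospital records of the lookback
    history (which contains the index record); an exact 50% split counts as
    positive.  The death record enters rules (ii)–(iv) only as an OR-term,
    never the majority denominator.
    """
    n_flagged = 0
    n_positive = 0
    for rec in person.lookback:
        flag = interpret_raw_code(rec.raw_status)
        if flag is IndigenousFlag.MISSING:
            continue
        n_flagged += 1
        if flag is IndigenousFlag.POSITIVE:
            n_positive += 1

    index_pos = interpret_raw_code(person.index.raw_status) is IndigenousFlag.POSITIVE
    death_flag = interpret_raw_code(person.death.raw_status) if person.death else None
    death_pos = death_flag is IndigenousFlag.POSITIVE

    majority_morb = n_flagged > 0 and 2 * n_positive >= n_flagged
    return AscertainmentResult(
        person_id=person.person_id,
        index_pos=index_pos,
        index_or_death_pos=index_pos or death_pos,
        majority_pos=majority_morb or death_pos,
        ever_pos=n_positive >= 1 or death_pos,
        n_flagged_records=n_flagged,
        n_positive_records=n_positive,
        death_flag=death_flag,
    )


@dataclass(frozen=True)
class AscertainmentTable:
    """Counts of positive persons per method, split by identifying source.

    For each method, ``morbidity_alone`` counts persons positive under the
    method's hospital-records part, ``death_alone`` those positive only via
    the death-record OR-term, and ``combined`` their sum.  The baseline
    comparator for percentage rows is the index-admission count.
    """

    morbidity_alone: dict[str, int]
    death_alone: dict[str, int]

    def __post_init__(self) -> None:
        for mapping in (self.morbidity_alone, self.death_alone):
            if set(mapping) != set(METHODS):
                raise ValueError(f"counts must cover methods {METHODS}")

    @classmethod
    def from_counts(
        cls,
        index_morbidity: int,
        majority_morbidity: int,
        ever_morbidity: int,
        death_alone: Sequence[int],
    ) -> "AscertainmentTable":
        """Build from published-style counts.

        ``death_alone`` is the (index+death, majority+death, ever+death)
        triple of persons identified through the death record only.
        """
        d_index, d_majority, d_ever = death_alone
        return cls(
            morbidity_alone={
                "index": index_morbidity,
                "index_death": index_morbidity,
                "majority_death": majority_morbidity,
                "ever_death": ever_morbidity,
            },
            death_alone={
                "index": 0,
                "index_death": d_index,
                "majority_death": d_majority,
                "ever_death": d_ever,
            },
        )

    def combined(self, method: str) -> int:
        return self.morbidity_alone[method] + self.death_alone[method]

    @property
    def baseline(self) -> int:
        """Index-admission positives — the most conservative comparator."""
        return self.combined("index")

    def excess_over_baseline_pct(self, method: str, *, ndigits: int | None = 1) -> float:
        """Percent change of a method's combined count over the baseline.

        Negative when a rule identifies fewer persons than the index flag —
        possible for the majority rule, which is not nested with rule (ii).
        """
        diff = self.combined(method) - self.baseline
        if diff >= 0:
            return excess_pct(self.baseline, diff, ndigits=ndigits)
        value = diff / self.baseline * 100.0
        return value if ndigits is None else round_half_up(value, ndigits)

    def underestimate_pct(self, method: str, *, ndigits: int | None = 1) -> float:
        """Shortfall of the baseline relative to a method's combined count.

        Signed like :meth:`excess_over_baseline_pct`: negative when the
        method identifies fewer persons than the baseline.
        """
        combined = self.combined(method)
        if combined >= self.baseline:
            return underestimation_pct(self.baseline, combined, ndigits=ndigits)
        value = (1.0 - self.baseline / combined) * 100.0
        return value if ndigits is None else round_half_up(value, ndigits)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "morbidity_alone": [self.morbidity_alone[m] for m in METHODS],
            "death_alone": [self.death_alone[m] for m in METHODS],
            "combined": [self.combined(m) for m in METHODS],
        }
        df = pd.DataFrame(rows, index=list(METHODS)).T
        if self.baseline > 0:
            df.loc["excess_over_index_pct"] = [
                self.excess_over_baseline_pct(m) for m in METHODS
            ]
            df.loc["underestimate_index_pct"] = [
                self.underestimate_pct(m) for m in METHODS
            ]
        return df


def tabulate(results: Iterable[AscertainmentResult]) -> AscertainmentTable:
    """Count positive persons per method, split into morbidity vs death-only.

    ``combined = morbidity_alone + death_alone`` holds for every method by
    construction; an empty input gives an all-zero table.
    """
    morbidity = dict.fromkeys(METHODS, 0)
    death_only = dict.fromkeys(METHODS, 0)
    for res in results:
        parts = {
            "index": (res.index_pos, res.index_pos),
            "index_death": (res.index_pos, res.index_or_death_pos),
            "majority_death": (res.majority_morbidity_pos, res.majority_pos),
            "ever_death": (res.ever_morbidity_pos, res.ever_pos),
        }
        for method, (morb, comb) in parts.items():
            if morb:
                morbidity[method] += 1
            elif comb:
                death_only[method] += 1
    return AscertainmentTable(morbidity_alone=morbidity, death_alone=death_only)
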