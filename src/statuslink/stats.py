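"""Estimators for under-ascertainment and misclassification-bias statistics.

Three small estimators carry the headline numbers of this analysis:

* ``underestimation_pct`` — the shortfall of a single-source count relative
  to a linked revised count, |observed/revised − 1| × 100.
* ``wilson_interval`` — the Wilson score interval for a binomial proportion
  (the Wald interval does not reproduce the published bounds and is not
  offered).
* ``relative_risk`` — a two-group risk ratio with the Katz log-normal CI,
  used for the informative-missingness contrast: deaths with a missing status
  field are compared with stated deaths on the probability of being flagged
  Indigenous in hospital records.

``CrossTab`` holds the 3×2 death-record × hospital-derived contingency table
(death flag positive/negative/missing against hospital ever-positive/other)
and derives all of its headline statistics, so the same code path serves both
pipeline output and published counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .records import IndigenousFlag

if TYPE_CHECKING:  # pragma: no cover
    from .ascertainment import AscertainmentResult

__all__ = [
    "CiMethod",
    "RatioEstimate",
    "ChiSquareResult",
    "CrossTab",
    "round_half_up",
    "underestimation_pct",
    "excess_pct",
    "wilson_interval",
    "complement_pct",
    "relative_risk",
    "chi_square",
    "death_cross_tab",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables are conventionally set."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class CiMethod(enum.Enum):
    WILSON_PROPORTION = "wilson_proportion"
    LOGNORMAL_RR = "lognormal_rr"


@dataclass(frozen=True)
class RatioEstimate:
    """A point estimate with its confidence interval and provenance."""

    point: float
    ci_low: float
    ci_high: float
    conf_level: float
    method: CiMethod
    cells: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)):
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("confidence bounds must bracket the point estimate")

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.ci_low) or math.isnan(self.ci_high))

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.point, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def underestimation_pct(observed: int, revised: int, *, ndigits: int | None = 1) -> float:
    """Percentage shortfall of an observed count against a revised estimate.

    |observed/revised − 1| × 100, reported as a magnitude (the sign is by
    construction a shortfall since revised ≥ observed).  ``ndigits=None``
    returns full precision; the default rounds half-up to one decimal as in
    report tables.
    """
    if revised <= 0:
        raise ValueError("revised estimate must be positive")
    if not 0 <= observed <= revised:
        raise ValueError("expected 0 <= observed <= revised")
    value = abs(observed / revised - 1.0) * 100.0
    return value if ndigits is None else round_half_up(value, ndigits)


def excess_pct(baseline: int, added: int, *, ndigits: int | None = 1) -> float:
    """Percentage increase over a baseline count: added/baseline × 100.

    Equivalent to (revised/baseline − 1) × 100 with revised = baseline + added.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if added < 0:
        raise ValueError("added must be non-negative")
    value = added / baseline * 100.0
    return value if ndigits is None else round_half_up(value, ndigits)


def wilson_interval(k: int, n: int, conf: float = 0.95) -> RatioEstimate:
    """Wilson score interval for the binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("expected 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return RatioEstimate(
        point=k / n,
        ci_low=float(low),
        ci_high=float(high),
        conf_level=conf,
        method=CiMethod.WILSON_PROPORTION,
        cells={"k": k, "n": n},
    )


def complement_pct(estimate: RatioEstimate) -> RatioEstimate:
    """Transform a proportion estimate p to (1 − p) × 100, swapping bounds.

    Used to report under-ascertainment: if p is the fraction of linked-total
    cases captured by one source, (1 − p) × 100 is its percentage shortfall.
    """
    return RatioEstimate(
        point=(1.0 - estimate.point) * 100.0,
        ci_low=(1.0 - estimate.ci_high) * 100.0,
        ci_high=(1.0 - estimate.ci_low) * 100.0,
        conf_level=estimate.conf_level,
        method=estimate.method,
        cells=dict(estimate.cells),
    )


def relative_risk(a: int, n1: int, b: int, n2: int, conf: float = 0.95) -> RatioEstimate:
    """Risk ratio (a/n1)/(b/n2) with the Katz log-normal confidence interval.

    CI = exp(log RR ± z·sqrt(1/a − 1/n1 + 1/b − 1/n2)).  With a zero
    numerator in either group the interval is undefined and returned as NaN
    bounds (``RatioEstimate.defined`` is False).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("event counts must lie within their group sizes")
    cells = {"a": a, "n1": n1, "b": b, "n2": n2}
    if b == 0:
        return RatioEstimate(math.inf, math.nan, math.nan, conf, CiMethod.LOGNORMAL_RR, cells)
    rr = (a / n1) / (b / n2)
    if a == 0:
        return RatioEstimate(rr, math.nan, math.nan, conf, CiMethod.LOGNORMAL_RR, cells)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return RatioEstimate(
        point=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
        conf_level=conf,
        method=CiMethod.LOGNORMAL_RR,
        cells=cells,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected cell count < 5 — interpret with care


def chi_square(table: Sequence[Sequence[float]] | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square on an r×c count table, without continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("chi-square requires an r×c table with r, c >= 2")
    res = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        low_expected=bool((res.expected_freq < 5).any()),
    )


_ROW_ORDER = (IndigenousFlag.POSITIVE, IndigenousFlag.NEGATIVE, IndigenousFlag.MISSING)


@dataclass(frozen=True)
class CrossTab:
    """Death-record status × hospital-derived status contingency table.

    Rows: the death-record flag (positive / negative / missing a.k.a.
    unidentified).  Columns: ever flagged positive on any linked hospital
    record vs other.  All derived statistics — totals, the death-record
    under-ascertainment with its Wilson interval, row percentages and the
    missingness relative risk — are computed from the six cells, so published
    counts and pipeline output share one code path.
    """

    cells: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @classmethod
    def from_counts(
        cls,
        positive: tuple[int, int],
        negative: tuple[int, int],
        missing: tuple[int, int],
    ) -> "CrossTab":
        """Rows as (hospital-positive, hospital-other) pairs."""
        return cls(cells=(tuple(positive), tuple(negative), tuple(missing)))

    def row(self, flag: IndigenousFlag) -> tuple[int, int]:
        return self.cells[_ROW_ORDER.index(flag)]

    @property
    def n_deaths(self) -> int:
        return sum(a + b for a, b in self.cells)

    @property
    def death_positive_total(self) -> int:
        """Deaths flagged Indigenous on the death record itself."""
        return sum(self.cells[0])

    @property
    def hospital_positive_total(self) -> int:
        """Deaths ever flagged Indigenous on a linked hospital record."""
        return sum(r[0] for r in self.cells)

    @property
    def union_positive_total(self) -> int:
        """Deaths flagged Indigenous in either source (the revised estimate)."""
        return self.hospital_positive_total + self.cells[0][1]

    def underascertainment(self, conf: float = 0.95) -> RatioEstimate:
        """Death-record shortfall vs the two-source revised count, in percent.

        Point = |death_pos/union − 1| × 100 with a Wilson score interval on
        the captured proportion, complement-transformed to the percent scale.
        """
        observed, revised = self.death_positive_total, self.union_positive_total
        if revised == 0:
            raise ValueError("no positively identified deaths in either source")
        return complement_pct(wilson_interval(observed, revised, conf))

    def row_positive_pct(self, flag: IndigenousFlag, conf: float = 0.95) -> RatioEstimate:
        """Percent of a death-flag row that is hospital-positive, Wilson CI."""
        a, b = self.row(flag)
        est = wilson_interval(a, a + b, conf)
        return RatioEstimate(
            point=est.point * 100.0,
            ci_low=est.ci_low * 100.0,
            ci_high=est.ci_high * 100.0,
            conf_level=conf,
            method=est.method,
            cells=est.cells,
        )

    def stated_positive_pct(self, conf: float = 0.95) -> RatioEstimate:
        """Hospital-positive percent among deaths with a stated flag (pos+neg rows)."""
        a = self.cells[0][0] + self.cells[1][0]
        n = sum(self.cells[0]) + sum(self.cells[1])
        est = wilson_interval(a, n, conf)
        return RatioEstimate(
            est.point * 100.0, est.ci_low * 100.0, est.ci_high * 100.0,
            conf, est.method, est.cells,
        )

    def missingness_rr(self, conf: float = 0.95) -> RatioEstimate:
        """RR of hospital-positivity, missing-flag deaths vs stated-flag deaths.

        A ratio above 1 means deaths with an unidentified status field are
        enriched for persons flagged Indigenous in hospital data — the
        informative-missingness signature.
        """
        a, other_missing = self.row(IndigenousFlag.MISSING)
        n1 = a + other_missing
        b = self.cells[0][0] + self.cells[1][0]
        n2 = sum(self.cells[0]) + sum(self.cells[1])
        if n1 == 0 or n2 == 0:
            return RatioEstimate(math.nan, math.nan, math.nan, conf, CiMethod.LOGNORMAL_RR,
                                 {"a": a, "n1": n1, "b": b, "n2": n2})
        return relative_risk(a, n1, b, n2, conf)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            list(self.cells),
            index=[f.value for f in _ROW_ORDER],
            columns=["hospital_positive", "hospital_other"],
        )


def death_cross_tab(results: Iterable["AscertainmentResult"]) -> CrossTab:
    """Tabulate deceased persons by death flag × hospital-derived status.

    Hospital-derived status uses the ever rule restricted to hospital records
    (the death record is excluded from the column to avoid circularity).
    Results without a death record are skipped.
    """
    counts = {flag: [0, 0] for flag in _ROW_ORDER}
    for res in results:
        if res.death_flag is None:
            continue
        hosp_pos = res.n_positive_records >= 1
        counts[res.death_flag][0 if hosp_pos else 1] += 1
    return CrossTab(
        cells=tuple(tuple(counts[flag]) for flag in _ROW_ORDER)  # type: ignore[arg-type]
    )
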