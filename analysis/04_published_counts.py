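#!/usr/bin/env python
"""Headline statistics of the linked WA cardiovascular cohort.

The confidential unit-record data cannot be shipped, but every headline
statistic is a deterministic function of the published contingency counts;
this driver feeds those counts through the package's estimators and writes
results/published_stats.csv.
"""

from pathlib import Path

import pandas as pd

from statuslink.ascertainment import AscertainmentTable
from statuslink.records import IndigenousFlag
from statuslink.stats import CrossTab, excess_pct, round_half_up

OUT = Path(__file__).resolve().parents[1] / "results" / "published_stats.csv"

DEATH_CELLS = dict(positive=(654, 60), negative=(188, 18048), missing=(73, 786))
TABLE1 = dict(index_morbidity=3060, majority_morbidity=3094, ever_morbidity=3636,
              death_alone=(83, 78, 60))
STRATA = {"male": (1555, 1835), "female": (1505, 1806), "age 65+": (637, 943),
          "ARIA metropolitan": (623, 866), "ARIA very remote": (1070, 1134)}


def main() -> None:
    rows = []
    ct = CrossTab.from_counts(**DEATH_CELLS)
    under = ct.underascertainment()
    rr = ct.missingness_rr()
    rows.append(("deaths identified in any source", ct.union_positive_total, "", ""))
    rows.append(("death-record under-ascertainment %", *under.rounded(1)))
    rows.append(("missingness RR", *rr.rounded(1)))
    rows.append(("hospital-positive % of missing-flag deaths",
                 round_half_up(ct.row_positive_pct(IndigenousFlag.MISSING).point, 1), "", ""))
    rows.append(("hospital-positive % of stated-flag deaths",
                 round_half_up(ct.stated_positive_pct().point, 1), "", ""))

    table = AscertainmentTable.from_counts(**TABLE1)
    for method in ("index_death", "majority_death", "ever_death"):
        rows.append((f"{method}: combined count", table.combined(method), "", ""))
        rows.append((f"{method}: excess over index %",
                     table.excess_over_baseline_pct(method), "", ""))
        rows.append((f"{method}: index underestimate %",
                     table.underestimate_pct(method), "", ""))

    for label, (index_count, ever_count) in STRATA.items():
        pct = round_half_up(excess_pct(index_count, ever_count - index_count,
                                       ndigits=None), 0)
        rows.append((f"stratum underestimate % ({label})", pct, "", ""))

    df = pd.DataFrame(rows, columns=["quantity", "value", "ci_low", "ci_high"])
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
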