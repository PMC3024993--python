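#!/usr/bin/env python
"""Run the full ascertainment analysis on the synthetic linked cohort.

Reads the extracts written by 01_simulate_cohort.py (regenerating them if
absent), applies the four determination rules, and writes the method-ladder
table, the death cross-tabulation, the stratified summaries and the headline
estimates under results/synthetic/.
"""

import runpy
from pathlib import Path

from statuslink.pipeline import analyse_files

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
OUT = ROOT / "results" / "synthetic"


def main() -> None:
    if not (DATA / "admissions.csv").exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_cohort.py"), run_name="__main__")
    result, adm_report, death_report = analyse_files(
        DATA / "admissions.csv", DATA / "deaths.csv"
    )
    print(f"admission validation: {adm_report.summary()}")
    print(f"death validation: {death_report.summary()}")
    print(f"cohort: {len(result.persons)} persons, {result.n_deaths} deaths attached\n")

    print("method ladder (positive persons per rule):")
    print(result.table.to_frame().to_string(), "\n")

    ct = result.cross_tab
    print("death-record cross-tabulation:")
    print(ct.to_frame().to_string())
    under = ct.underascertainment()
    rr = ct.missingness_rr()
    print(f"death-record under-ascertainment: {under.rounded(1)[0]}% "
          f"(95% CI {under.rounded(1)[1]}-{under.rounded(1)[2]})")
    print(f"missingness RR: {rr.rounded(2)[0]} "
          f"(95% CI {rr.rounded(2)[1]}-{rr.rounded(2)[2]})\n")

    paths = result.write(OUT)
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
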