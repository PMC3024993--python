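#!/usr/bin/env python
"""Generate the synthetic linked cohort used by the downstream analyses.

Writes admissions.csv / deaths.csv / truth.csv under scratch/synthetic/
(20,000 persons, seed 2026) and prints the cohort's basic marginals.
"""

from pathlib import Path

from statuslink.simulate import SimulationParams, simulate

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
PARAMS = SimulationParams(n_persons=20_000, seed=2026)


def main() -> None:
    cohort = simulate(PARAMS)
    paths = cohort.write(OUT)
    n = PARAMS.n_persons
    n_true = int(cohort.truth["true_positive"].sum())
    print(f"simulated {n} persons -> {len(cohort.admissions)} admissions, "
          f"{len(cohort.deaths)} deaths")
    print(f"latent Indigenous prevalence: {n_true / n:.3%} ({n_true} persons)")
    print(f"records per person: {len(cohort.admissions) / n:.2f}")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
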