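# statuslink

Under-ascertainment of Indigenous status in linked hospital and death
records.

Administrative health data chronically under-record Indigenous status, which
biases disease burden and mortality statistics for Aboriginal Australians.
When a data-linkage system resolves hospital separations and death
registrations to the same person, the status flag can be read across the
person's entire record history rather than a single contact. `statuslink`
implements that analysis for epidemiologists working with linked extracts:

* **Cohort construction** — per person, the most recent qualifying
  cardiovascular public-hospital separation in a study window (the *index*
  record), a 20-year any-cause admission lookback excluding same-day routine
  dialysis, and any subsequent in-window death.
* **Four determination rules** of increasing reach — status positive on
  (i) the index admission; (ii) index or death record; (iii) ≥ 50% of
  flagged hospital records or death record; (iv) any record (*ever
  identified*). The shortfall of rule (i) against each wider rule is the
  under-ascertainment estimate.
* **Bias statistics** — under-ascertainment |observed/revised − 1| × 100
  with Wilson score intervals; the informative-missingness relative risk
  (Katz log-normal CI) comparing hospital-flag positivity between deaths
  with missing vs stated status fields; chi-square heterogeneity tests; and
  stratified shortfalls by sex, age band, SEIFA quintile and ARIA
  remoteness.
* **A seeded synthetic-cohort generator** with the misclassification
  structure the analysis assumes (era-specific coding, WA public-hospital
  collapsing of 'not stated' into negative, within-person flag correlation,
  status-dependent death-flag missingness), plus closed-form expectations
  for parameter-recovery testing — so the whole pipeline is testable without
  confidential unit-record data.

## Worked example

Published contingency counts fully determine the headline statistics, so
they serve as a compact worked example. Of 19,809 cohort deaths, 714 were
flagged Indigenous at death registration; linked hospital records identify
975 in at least one source:

```python
>>> from statuslink import CrossTab
>>> ct = CrossTab.from_counts(positive=(654, 60), negative=(188, 18048),
...                           missing=(73, 786))
>>> ct.union_positive_total
975
>>> ct.underascertainment().rounded(1)
(26.8, 24.1, 29.6)
>>> ct.missingness_rr().rounded(1)
(1.9, 1.5, 2.4)
```

Death records understate Indigenous deaths by 26.8% (95% CI 24.1–29.6%),
and deaths with a *missing* status field are 1.9× (1.5–2.4) as likely to be
hospital-flagged Indigenous as stated deaths — missingness is informative,
biased toward under-recording.

The same machinery runs end-to-end on data. With the bundled simulator:

```sh
statuslink simulate --out scratch/demo --seed 4 --n-persons 20000
statuslink analyse --admissions scratch/demo/admissions.csv \
    --deaths scratch/demo/deaths.csv --out results/demo
```

which prints, for example (seed 2026, 20,000 persons — the output of
`analysis/02_ascertainment_analysis.py`):

```
                         index  index_death  majority_death  ever_death
morbidity_alone          930.0        930.0           969.0      1138.0
death_alone                0.0         62.0            60.0        33.0
combined                 930.0        992.0          1029.0      1171.0
excess_over_index_pct      0.0          6.7            10.6        25.9
underestimate_index_pct    0.0          6.3             9.6        20.6
death-record under-ascertainment: 29.6% (95% CI 25.2-34.5)
missingness RR: 2.32 (95% CI 1.64-3.27)
```

Read: 930 persons are flagged on their index admission; the ever rule
lifts the count to 1,171, i.e. the index flag alone understates by 20.6%;
the death cross-tabulation shows the same informative-missingness signature
the estimator targets (configured expected RR 1.9; a single 20k replicate
is noisy, the recovery experiment averages replicates).

The numbered drivers under `analysis/` run the narrative end to end:
`01_simulate_cohort.py` (data), `02_ascertainment_analysis.py` (tables),
`03_recovery_experiment.py` (parameter recovery with Monte-Carlo SEs),
`04_published_counts.py` (headline statistics from published counts).
Tables land under `results/`, bulky synthetic data under `scratch/`.

## Layout

```
src/statuslink/   records, cohort, ascertainment, stats, stratified,
                  simulate, pipeline, cli
analysis/         numbered narrative drivers
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   model, assumptions, parameter choices, limitations
```
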