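# Methods

## Problem and data model

Administrative health collections under-record Indigenous status. When
hospital separations (admissions) and death registrations are linked at the
person level, the status flag can be read across a person's whole record
history instead of a single contact, and the shortfall of single-source
counts can be quantified. This package implements that analysis for the
design used in Western Australian linked data: a cohort of persons aged
25–74 with a public-hospital cardiovascular separation (principal diagnosis
in ICD-10-AM chapter I) during 2000–2005, each person's most recent
qualifying separation taken as the *index* record, a 20-year any-cause
admission lookback (public and private), and any subsequent in-window death.
Same-day separations for routine dialysis (ICD-9-CM V56, ICD-10-AM Z49) are
excluded from the lookback because they would otherwise dominate record
counts for a small group of patients; the exclusion requires *both*
conditions, so overnight dialysis admissions stay.

Status coding has two eras. Before 2000 the flag was binary
(1 = not Aboriginal, 2 = Aboriginal); from 2000 it has four categories
(1 = Aboriginal, 2 = Torres Strait Islander, 3 = both, 4 = neither) plus a
'not stated' provision. WA public hospitals record 'not stated' identically
to 'neither', so on those records an absent code is interpreted as a stated
negative — an informative collapse that depresses positive counts. Codes
1–3 all map to positive by the usual national convention; this is
configurable (`interpret_raw_code(..., tsi_positive=False)`) because the
choice is a convention, not a fact of the data. The 1999 register-wide
recode (old 1 → new 4, old 2 → new 3) is exposed as `recode_legacy` and
verified to preserve meaning under interpretation.

## The four determination rules

For each linked person, status is determined under four rules of increasing
reach: (i) index admission flag only (baseline); (ii) index or death-record
flag; (iii) positive flag on at least 50% of flagged hospital records over
the lookback (index included; exact ties count as positive), or death
record; (iv) any positive hospital record, or death record (*ever
identified*). Missing flags are excluded from both numerator and denominator
of rule (iii); a person with no flagged hospital records is decided by the
death record alone. The death record enters rules (ii)–(iv) only as an
OR-term, never the majority denominator.

A structural caveat: rules (ii) and (iii) are not nested. A person whose
index record is positive but whose history is minority-positive satisfies
(ii) and fails (iii), so the full count ladder
index ≤ index+death ≤ majority+death ≤ ever+death is an empirical pattern
(it holds in the published data, and with high probability when flags are
persistent within person), not a theorem. The provable partial order —
index ≤ index+death ≤ ever+death, and majority+death ≤ ever+death — is what
the property tests assert on arbitrary inputs; the tabulated
"underestimate" percentages are therefore signed, and can be negative for
the majority rule on small cohorts.

## Estimators

* Under-ascertainment of a source: |observed/revised − 1| × 100, where
  *revised* is the union count over linked sources. Report rounding is one
  decimal, half-up; computations keep full precision.
* The companion *excess* form added/baseline × 100 (equivalently
  revised/baseline − 1) is what the demographic table prints; the two are
  consistent, (1 − u/100)(1 + e/100) = 1.
* Binomial proportions carry **Wilson score** intervals
  (statsmodels' implementation, cross-checked against the closed form).
  Wilson, not Wald, reproduces the published interval for the death-record
  shortfall — 714/975 captured gives 26.8% (24.1–29.6) under Wilson while
  Wald gives (24.0–29.5) — so Wald is deliberately not offered.
* The informative-missingness contrast is a relative risk with the **Katz
  log-normal** interval, CI = exp(log RR ± z·√(1/a − 1/n1 + 1/b − 1/n2)).
  On the published cells (73/859 vs 842/18,950) this gives 1.9 (1.5–2.4).
* Heterogeneity across strata uses Pearson chi-square without continuity
  correction on the levels × (newly-identified, index-identified) table,
  with a low-expected-count warning below 5.

The death cross-tabulation defines "hospital-derived positive" as the ever
rule restricted to hospital records, excluding the death record itself, to
avoid circularity between the row and column classifications.

## Synthetic cohort generator

Because the unit-record data are confidential, a seeded generator emulates
the structure the pipeline assumes; its defaults are fixed once to mirror
the published cohort's marginals at full scale (n = 62,692) and are not
adjusted per experiment:

* **Records per person**: max(Poisson(12.4), 1) including the index,
  matching the published ratio 778,714/62,692 ≈ 12.4. A negative-binomial
  option covers over-dispersion.
* **Latent prevalence** 0.067, so that with the sensitivity defaults the
  index-positive rate lands near the published 4.9%.
* **Strata**: ARIA remoteness (5 levels), age band (0-34/35-64/65+ within
  25–74) and SEIFA quintile are drawn per person with status-dependent
  weights (Indigenous persons weighted toward remote, younger,
  more-disadvantaged strata). Record-level flag sensitivity is a
  multiplicative gradient over the stratum — high in remote/very-remote
  (0.90/0.95 base), lower in metropolitan/urban (0.72/0.62), reduced for
  ages 65+ (×0.75) and the least-disadvantaged quintile (×0.65) — clipped
  to [0.02, 0.98]. These are configuration expressing the qualitative
  published gradient, not empirical claims.
* **Within-person correlation** 0.90: each record copies the person's
  previous recorded flag with probability ρ, else redraws Bernoulli
  (sensitivity or false-positive rate). This models the shared
  patient-management system that perpetuates earlier classifications, and
  is what separates the modest majority-rule gain from the large ever-rule
  gain; ρ = 0.90 reproduces the published ever/index ratio ≈ 1.19. The
  false-positive rate is 0.001 (misclassification is overwhelmingly
  false-negative).
* **Coding eras**: records before 2000 are emitted in legacy binary coding
  (with an optional pre-2000 missingness probability, default 0 — observed
  hospital missingness was confined to the earliest records), later records
  in four-category coding, exercising both interpretation paths.
* **Deaths**: probability 0.27 (truly positive) / 0.32 (negative) of an
  in-window death after the index separation, giving ~32% crude mortality
  as published. The death flag is missing with probability 0.042 for truly
  negative persons and 0.0825 for positive persons — the latter solved (see
  below) so the *expected observable* missingness RR is exactly 1.9; when
  stated, it is positive with sensitivity 0.75 (false-positive 0.001).
* ~2% of lookback records are same-day routine dialysis, exercising the
  exclusion.

### Closed-form oracles

Under the copying chain the marginal positivity of every record is the
per-record sensitivity s (copying preserves the marginal), and the
probability that none of k records is positive is
(1−s)·[ρ + (1−ρ)(1−s)]^(k−1), giving `expected_ever_sensitivity` in closed
form; it is verified against brute-force enumeration of all flag chains.
`expected_rates` integrates these over the stratum mixture and the record-
count distribution, and derives the expected observable missingness RR by
conditioning on death via Bayes. `calibrate_missingness` inverts that
expression (Brent's method) for the positive-status missingness probability;
the shipped default is the calibrated value for target 1.9. The dialysis
exclusion is treated as Binomial thinning of the record count, which is
exact only at ρ = 0; at the default 2% rate and ρ = 0.9 the resulting error
in expected quantities is two orders of magnitude below Monte-Carlo noise
at the problem sizes used.

### What passing tests do and do not show

The generator reproduces the *mechanisms* (era coding, informative
collapsing, correlated within-person flags, status-dependent death-flag
missingness, stratum gradients) but not WA's true population structure,
service geography, or temporal trends in recording practice; parameter
recovery on synthetic data demonstrates that the pipeline measures what the
generative model encodes, not that the published point estimates are
externally valid.

## Problem sizes and numerical choices

Analysis drivers use 20,000-person cohorts; the recovery experiment runs
replicates of 50,000 persons in the acceptance suite (6 replicates, seeds
derived deterministically from the base seed) and 4 in the acceptance
script, comparing the mean estimate with its closed-form expectation via
Monte-Carlo standard errors. Published-count statistics are exact and
instantaneous. Dates are ISO-8601 calendar dates with closed
[admission, separation] intervals; the lookback window is half-open on the
left, (index admission − 20 years, index admission], anchored at the index
*admission* date (the design is silent between admission and separation;
this choice is configurable via `CohortSpec`). Age eligibility is evaluated
from the record's own age field (admission-time age). ICD prefix matching
strips dots and compares string prefixes, so chapter I reduces to prefix
"I" and the dialysis codes to "V56"/"Z49". Index ties (equal separation
dates) break by latest admission date, then first-seen input order.
Validation is report-collecting by default because administrative extracts
are dirty; strict mode raises on the first bad row. Duplicate death records
always raise — at most one death per person is structural, not dirt.

## Known limitations

* Stratum attributes are read from the index admission; persons whose
  residence or SEIFA changed over 20 years are classified by their index
  values. Absent SEIFA/ARIA appear as an explicit "unknown" level.
* Confidence intervals for the stratified integer-rounded shortfalls are
  not produced: the published table's interval method for those ratios is
  not reconstructible, so only point estimates are compared.
* No probabilistic linkage, geocoding, population denominators or
  capture-recapture modelling; person identifiers are taken as resolved and
  only the four deterministic rules are offered.
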