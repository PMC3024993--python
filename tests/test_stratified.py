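"""Completeness audits and stratified under-ascertainment."""

import dataclasses
import datetime as dt

import pytest

from helpers import make_admission, make_person
from statuslink.ascertainment import classify
from statuslink.records import IndigenousFlag, Sector
from statuslink.simulate import SimulationParams, simulate
from statuslink.stratified import (
    COMPLETENESS_AGE_BANDS,
    TABLE_AGE_BANDS,
    StratumSummary,
    age_band,
    build_person_frame,
    compare_strata,
    completeness_by_stratum,
    underestimation_by_factor,
)

POS, NEG, MISS = IndigenousFlag.POSITIVE, IndigenousFlag.NEGATIVE, IndigenousFlag.MISSING


def test_age_band_presets():
    assert [age_band(a) for a in (30, 35, 64, 65)] == ["0-34", "35-64", "35-64", "65+"]
    assert [age_band(a, COMPLETENESS_AGE_BANDS) for a in (10, 25, 45, 80)] == [
        "0-24",
        "25-44",
        "45-64",
        "65+",
    ]


def test_completeness_missing_flags_land_in_early_period():
    records = [
        make_admission("p1", adm=dt.date(2003, 1, 1), flag=NEG),
        make_admission("p2", adm=dt.date(1980, 6, 1), flag=MISS, sector=Sector.PRIVATE),
        make_admission("p3", adm=dt.date(1980, 7, 1), flag=MISS, sector=Sector.PRIVATE),
    ]
    out = completeness_by_stratum(records)
    period = out[out["factor"] == "period"].set_index("level")
    assert period.loc["pre-2000", "n_missing_flag"] == 2
    assert period.loc["2000+", "n_missing_flag"] == 0
    assert period.loc["2000+", "pct_complete"] == 100.0


def test_completeness_all_complete():
    records = [make_admission(f"p{i}", flag=NEG) for i in range(4)]
    out = completeness_by_stratum(records)
    assert (out["pct_complete"] == 100.0).all()


def test_completeness_recovers_configured_missingness():
    """A configured 10% pre-2000 missingness shows up in the period stratum."""
    params = SimulationParams(n_persons=1500, hmdc_missing_prob_pre2000=0.10, seed=7)
    sim = simulate(params)
    records, _ = sim.admission_records()
    out = completeness_by_stratum(records)
    period = out[out["factor"] == "period"].set_index("level")
    pct_missing = 100.0 - period.loc["pre-2000", "pct_complete"]
    n = period.loc["pre-2000", "n_records"]
    se = 100.0 * (0.1 * 0.9 / n) ** 0.5
    assert abs(pct_missing - 10.0) < 4 * se
    assert period.loc["2000+", "pct_complete"] == 100.0


def test_underestimation_by_factor_counts():
    from statuslink.records import Sex

    males = [
        make_person([POS, POS], pid="m1"),
        make_person([POS, NEG], pid="m2"),  # ever-positive, index-negative
    ]
    female_index = dataclasses.replace(make_admission("f1", flag=POS), sex=Sex.F)
    female = dataclasses.replace(
        make_person([POS, POS], pid="f1"), index=female_index, lookback=(female_index,)
    )
    people = males + [female]
    results = [classify(p) for p in people]
    frame = build_person_frame(people, results)
    by_sex = {s.level: s for s in underestimation_by_factor(frame, "sex")}
    assert by_sex["M"].index_count == 1 and by_sex["M"].ever_count == 2
    assert by_sex["M"].underestimate_pct == pytest.approx(100.0)
    assert by_sex["F"].index_count == 1 and by_sex["F"].ever_count == 1
    assert by_sex["F"].underestimate_pct == pytest.approx(0.0)


def test_unknown_levels_reported_not_dropped():
    rec = dataclasses.replace(make_admission("p1", flag=POS), seifa_quintile=None)
    person = dataclasses.replace(make_person([POS], pid="p1"), index=rec, lookback=(rec,))
    frame = build_person_frame([person], [classify(person)])
    levels = {s.level for s in underestimation_by_factor(frame, "seifa")}
    assert levels == {"unknown"}


def test_underestimation_invalid_factor():
    person = make_person([POS], pid="p1")
    frame = build_person_frame([person], [classify(person)])
    with pytest.raises(KeyError):
        underestimation_by_factor(frame, "postcode")


def test_compare_strata():
    identical = [
        StratumSummary("sex", "M", 10, 15, 50.0),
        StratumSummary("sex", "F", 10, 15, 50.0),
    ]
    res = compare_strata(identical)
    assert res.p_value == pytest.approx(1.0)

    five_levels = [
        StratumSummary("aria", str(i), 100 + 30 * i, 150 + 40 * i, None)
        for i in range(5)
    ]
    res = compare_strata(five_levels)
    assert res.df == 4 and res.statistic > 0

    with pytest.raises(ValueError):
        compare_strata(identical[:1])


def test_stratum_summary_rejects_inverted_counts():
    with pytest.raises(ValueError):
        StratumSummary("sex", "M", 10, 5, None)


def test_index_counts_partition_the_cohort(small_pipeline):
    """Summing index positives over any complete factor recovers the total."""
    persons, results = small_pipeline["persons"], small_pipeline["results"]
    frame = build_person_frame(persons, results)
    total = sum(r.index_pos for r in results)
    for factor in ("sex", "age_band", "aria", "region"):
        summaries = underestimation_by_factor(frame, factor)
        assert sum(s.index_count for s in summaries) == total


def test_lower_sensitivity_strata_show_higher_underestimates():
    """Directional gradient: metro recording sensitivity down, metro shortfall up."""
    table = {}
    for aria in (1, 2, 3, 4, 5):
        for band in ("0-34", "35-64", "65+"):
            for seifa in (1, 2, 3, 4, 5):
                table[(aria, band, seifa)] = 0.45 if aria == 1 else 0.95
    params = SimulationParams(
        n_persons=6000, sensitivity_by_stratum=table, seed=11,
        within_person_correlation=0.5,
    )
    sim = simulate(params)
    admissions, _ = sim.admission_records()
    deaths, _ = sim.death_records()
    from statuslink.cohort import build_cohort

    persons, _ = build_cohort(admissions, deaths)
    results = [classify(p) for p in persons]
    frame = build_person_frame(persons, results)
    by_aria = {s.level: s for s in underestimation_by_factor(frame, "aria")}
    assert by_aria["1"].underestimate_pct > by_aria["5"].underestimate_pct
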