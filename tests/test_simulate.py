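"""Synthetic-cohort generator: determinism, degenerate regimes, closed forms."""

import dataclasses
from itertools import product

import pytest

from statuslink.ascertainment import METHODS, classify, tabulate
from statuslink.cohort import build_cohort
from statuslink.simulate import (
    ConfigError,
    SimulationParams,
    calibrate_missingness,
    default_sensitivity_table,
    expected_ever_sensitivity,
    expected_missingness_rr,
    expected_rates,
    recovery_experiment,
    simulate,
)


def _uniform_sensitivity(value):
    return {k: value for k in default_sensitivity_table()}


def _pipeline(params):
    sim = simulate(params)
    admissions, adm_rep = sim.admission_records()
    deaths, death_rep = sim.death_records()
    assert adm_rep.ok and death_rep.ok
    persons, _ = build_cohort(admissions, deaths)
    results = [classify(p) for p in persons]
    return sim, persons, results


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_persons": 0},
        {"prop_true_positive": 1.5},
        {"false_positive_rate": -0.1},
        {"within_person_correlation": 2.0},
        {"death_prob_by_status": {True: 1.2, False: 0.3}},
    ],
)
def test_invalid_params_rejected(overrides):
    with pytest.raises(ConfigError):
        SimulationParams(**overrides).validate()


def test_fixed_seed_gives_byte_identical_output(tmp_path):
    params = SimulationParams(n_persons=300, seed=5)
    paths1 = simulate(params).write(tmp_path / "run1")
    paths2 = simulate(params).write(tmp_path / "run2")
    for name in paths1:
        assert paths1[name].read_bytes() == paths2[name].read_bytes()


def test_different_seed_changes_output():
    a = simulate(SimulationParams(n_persons=300, seed=5))
    b = simulate(SimulationParams(n_persons=300, seed=6))
    assert not a.admissions.equals(b.admissions)


def test_perfect_recording_collapses_all_methods():
    params = SimulationParams(
        n_persons=800,
        sensitivity_by_stratum=_uniform_sensitivity(1.0),
        false_positive_rate=0.0,
        death_flag_missing_prob_by_status={True: 0.0, False: 0.0},
        death_flag_sensitivity=1.0,
        death_flag_false_positive=0.0,
        seed=3,
    )
    sim, persons, results = _pipeline(params)
    table = tabulate(results)
    n_true = int(sim.truth["true_positive"].sum())
    assert {table.combined(m) for m in METHODS} == {n_true}
    assert table.underestimate_pct("ever_death") == 0.0


def test_zero_sensitivity_found_only_through_deaths():
    params = SimulationParams(
        n_persons=800,
        sensitivity_by_stratum=_uniform_sensitivity(0.0),
        false_positive_rate=0.0,
        death_flag_missing_prob_by_status={True: 0.0, False: 0.0},
        death_flag_sensitivity=1.0,
        death_flag_false_positive=0.0,
        seed=3,
    )
    sim, persons, results = _pipeline(params)
    table = tabulate(results)
    assert all(table.morbidity_alone[m] == 0 for m in METHODS)
    died_true = int((sim.truth["true_positive"] & sim.truth["died"]).sum())
    assert table.combined("ever_death") == died_true


def test_simulated_flags_exercise_both_coding_eras(small_sim):
    eras = set(small_sim.admissions["status_era"])
    assert eras == {"LEGACY_BINARY", "FOUR_CATEGORY"}


def test_expected_ever_sensitivity_independent_records():
    assert expected_ever_sensitivity(0.5, 1, 0.0) == pytest.approx(0.5)
    assert expected_ever_sensitivity(0.5, 3, 0.0) == pytest.approx(0.875)


def _ever_enumeration(s, k, rho):
    """Brute force over the 2^k flag sequences of the copying chain."""

    def bern(v):
        return s if v else 1 - s

    total = 0.0
    for values in product([True, False], repeat=k):
        prob = bern(values[0])
        for prev, cur in zip(values, values[1:]):
            prob *= rho * (cur == prev) + (1 - rho) * bern(cur)
        if any(values):
            total += prob
    return total


@pytest.mark.parametrize("s, k, rho", [(0.7, 4, 0.5), (0.3, 3, 0.8), (0.9, 5, 0.2)])
def test_expected_ever_sensitivity_matches_enumeration(s, k, rho):
    assert expected_ever_sensitivity(s, k, rho) == pytest.approx(
        _ever_enumeration(s, k, rho), abs=1e-12
    )


def test_ever_rate_converges_to_closed_form_without_correlation():
    """With independent records the ever rate approaches E[1 − (1−s)^K]."""
    params = SimulationParams(
        n_persons=15_000,
        within_person_correlation=0.0,
        dialysis_same_day_rate=0.0,
        seed=29,
    )
    sim, persons, results = _pipeline(params)
    expect = expected_rates(params)["ever_sensitivity_true_pos"]
    truth_pos = set(sim.truth.loc[sim.truth["true_positive"], "person_id"])
    hits = sum(1 for r in results if r.person_id in truth_pos and r.ever_morbidity_pos)
    n = len(truth_pos)
    se = (expect * (1 - expect) / n) ** 0.5
    assert abs(hits / n - expect) < 4 * se


def test_raising_sensitivity_lowers_underestimation():
    """Common random numbers: better recording, smaller ever-rule shortfall."""
    shortfalls = []
    for s in (0.5, 0.9):
        params = SimulationParams(
            n_persons=5000, sensitivity_by_stratum=_uniform_sensitivity(s), seed=17
        )
        _, _, results = _pipeline(params)
        shortfalls.append(tabulate(results).underestimate_pct("ever_death", ndigits=None))
    assert shortfalls[0] > shortfalls[1]


def test_calibration_hits_target_ratio():
    params = calibrate_missingness(SimulationParams(), target_rr=1.9)
    assert expected_missingness_rr(params) == pytest.approx(1.9, abs=1e-8)
    # defaults ship pre-calibrated to the same target
    assert expected_missingness_rr(SimulationParams()) == pytest.approx(1.9, abs=1e-6)


def test_seed_to_seed_stability_of_summary_rates():
    rates = []
    for seed in (1, 2, 3):
        sim = simulate(SimulationParams(n_persons=4000, seed=seed))
        admissions, _ = sim.admission_records()
        deaths, _ = sim.death_records()
        persons, _ = build_cohort(admissions, deaths)
        results = [classify(p) for p in persons]
        rates.append(sum(r.index_pos for r in results) / len(results))
    p = expected_rates(SimulationParams())["index_positive_rate"]
    se = (p * (1 - p) / 4000) ** 0.5
    for rate in rates:
        assert abs(rate - p) < 4 * se


def test_recovery_experiment_contract():
    with pytest.raises(ValueError):
        recovery_experiment(SimulationParams(n_persons=100), n_replicates=0)
    report = recovery_experiment(SimulationParams(n_persons=2000, seed=9), n_replicates=3)
    assert set(report.columns) >= {"quantity", "expected", "mean", "mc_se", "n_replicates"}
    assert (report["n_replicates"] == 3).all()
    rr = report.set_index("quantity").loc["missingness_rr"]
    assert rr["mean"] > 0 and rr["expected"] == pytest.approx(1.9, abs=1e-6)
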