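import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort shared across tests (4,000 persons)."""
    from statuslink.simulate import SimulationParams, simulate

    return simulate(SimulationParams(n_persons=4000, seed=123))


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Full pipeline output for the shared simulated cohort."""
    from statuslink.ascertainment import classify
    from statuslink.cohort import build_cohort

    admissions, adm_report = small_sim.admission_records()
    deaths, death_report = small_sim.death_records()
    assert adm_report.ok and death_report.ok
    persons, log = build_cohort(admissions, deaths)
    results = [classify(p) for p in persons]
    return {"sim": small_sim, "persons": persons, "results": results, "log": log}
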