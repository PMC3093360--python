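import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polyscreen as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def prostate_panel():
    return ps.packaged_panel("prostate")


@pytest.fixture(scope="session")
def breast_panel():
    return ps.packaged_panel("breast")


@pytest.fixture(scope="session")
def prostate_rates():
    return ps.packaged_rate_table("prostate")


@pytest.fixture(scope="session")
def breast_rates():
    return ps.packaged_rate_table("breast")


def make_table(
    ages,
    incidence,
    other_mortality=None,
    population=1_000_000.0,
    cancer="toy",
    sex="",
):
    """Build a small RateTable directly from hazards."""
    ages = np.asarray(ages, dtype=int)
    lam_c = np.broadcast_to(np.asarray(incidence, dtype=float), ages.shape)
    lam_o = (
        np.zeros_like(lam_c)
        if other_mortality is None
        else np.broadcast_to(np.asarray(other_mortality, dtype=float), ages.shape)
    )
    pop = np.full(ages.shape, float(population))
    cases = lam_c * pop
    other_deaths = lam_o * pop
    return ps.RateTable(
        cancer=cancer,
        sex=sex,
        ages=ages,
        population=pop,
        cancer_cases=cases,
        cancer_deaths=np.zeros_like(cases),
        all_cause_deaths=other_deaths,
    )


@pytest.fixture()
def toy_table():
    """10 bands, ages 50-59, varied hazards."""
    rng = np.random.default_rng(7)
    return make_table(
        ages=np.arange(50, 60),
        incidence=rng.uniform(0.001, 0.02, size=10),
        other_mortality=rng.uniform(0.002, 0.03, size=10),
    )
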