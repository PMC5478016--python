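import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hba1c_translator import (  # noqa: E402
    FixtureConfig,
    Population,
    costs_from_parameter_set,
    generate_evidence,
)


@pytest.fixture(scope="session")
def evidence():
    """Default synthetic evidence base at the suite's configured seed."""
    return generate_evidence(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def truth_params(evidence):
    return evidence.truth


@pytest.fixture(scope="session")
def germany_costs(evidence):
    return next(cs for cs in evidence.cost_sets if cs.country == "Germany")


@pytest.fixture(scope="session")
def embedded_costs(truth_params):
    return costs_from_parameter_set(truth_params)


@pytest.fixture
def pop1000():
    """The worked-example population: 1000 patients, 8.5% baseline, -0.5%."""
    return Population(n=1000, baseline_hba1c=8.5, delta_hba1c=0.5)
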