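import pytest

from dfnb1 import SimParams, default_registry, make_fixture, simulate_cohort
from dfnb1.fixtures import full_study_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def registry_borderline():
    return default_registry(borderline_pathogenic=True)


@pytest.fixture(scope="session")
def t8(registry):
    return make_fixture("T8", registry)


@pytest.fixture(scope="session")
def t9(registry):
    return make_fixture("T9", registry)


@pytest.fixture(scope="session")
def t10(registry):
    return make_fixture("T10", registry)


@pytest.fixture(scope="session")
def t13(registry):
    return make_fixture("T13", registry)


@pytest.fixture(scope="session")
def study(registry):
    return full_study_cohort(registry)


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderately sized simulated cohort with both mating types."""
    params = SimParams(
        population_size=2000, generations=3, q0=0.15, het_freqs=(0.05,),
        epsilon=0.15, assortment=0.8, consanguinity=0.3, seed=11,
    )
    return simulate_cohort(params, families=50, seed=11)
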