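import pytest
from hypothesis import HealthCheck, settings

from abrahamfit import SoluteDescriptors, datasets

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Published descriptor values for the monomer, used as evaluation inputs.
MONOMER_DESCRIPTORS = SoluteDescriptors(
    E=1.14, S=1.12, A=0.61, B=0.50, V=1.1705, L=5.79, log_kw=6.14, log_cw=-2.40,
    fixed=frozenset({"E", "V"}),
)

DIMER_DESCRIPTORS = SoluteDescriptors(
    E=1.68, S=1.07, A=0.24, B=0.94, V=2.2098, L=10.30, log_kw=6.29,
    fixed=frozenset({"E", "V"}),
)


@pytest.fixture(scope="session")
def coeff_table():
    return datasets.load_coefficient_table()


@pytest.fixture(scope="session")
def solubilities():
    return datasets.load_solubilities()


@pytest.fixture(scope="session")
def direct_logp():
    return datasets.load_direct_logp()


@pytest.fixture(scope="session")
def solvent_metadata():
    return datasets.load_solvent_metadata()


@pytest.fixture(scope="session")
def monomer_reference():
    return datasets.load_monomer_reference()


@pytest.fixture(scope="session")
def dimer_reference():
    return datasets.load_dimer_reference()


@pytest.fixture
def monomer_descriptors():
    return MONOMER_DESCRIPTORS


@pytest.fixture
def dimer_descriptors():
    return DIMER_DESCRIPTORS
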