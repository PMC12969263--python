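import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from hdxmix import SolventCondition, default_factor_table, default_reference_set


@pytest.fixture(scope="session")
def pdla():
    return default_reference_set("PDLA")


@pytest.fixture(scope="session")
def factor_table():
    return default_factor_table()


@pytest.fixture
def neutral_d2o():
    """Pure D2O, glass-electrode reading 7, 25 degC."""
    return SolventCondition.from_ph_read(7.0, 1.0, 298.15)


@pytest.fixture
def neutral_h2o():
    """Pure H2O, pH 7, 25 degC."""
    return SolventCondition.from_ph_read(7.0, 0.0, 298.15)
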