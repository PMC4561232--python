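import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from soilecotox import load_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def enzyme_table() -> pd.DataFrame:
    return load_fixture("enzyme_activity").table


@pytest.fixture(scope="session")
def counts_table() -> pd.DataFrame:
    return load_fixture("microbial_counts").table


@pytest.fixture(scope="session")
def pec_table() -> pd.DataFrame:
    return load_fixture("pec").table


@pytest.fixture(scope="session")
def resistance_table_fx() -> pd.DataFrame:
    return load_fixture("resistance").table


@pytest.fixture(scope="session")
def resilience_table_fx() -> pd.DataFrame:
    return load_fixture("resilience").table
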