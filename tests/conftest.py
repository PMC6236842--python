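import numpy as np
import pandas as pd
import pytest

from cbctqa import SimulationConfig, build_digital_phantom, load_reference_protocols
from cbctqa.protocols import fixture_path


@pytest.fixture(scope="session")
def reference_protocols():
    """The 26-protocol cohort from the packaged protocol table."""
    return load_reference_protocols()


@pytest.fixture(scope="session")
def table1():
    return pd.read_csv(fixture_path("table1.csv"))


@pytest.fixture(scope="session")
def table2():
    """Published Catphan study results (wCBDI, noise, ... per protocol)."""
    return pd.read_csv(fixture_path("table2_catphan.csv"))


@pytest.fixture(scope="session")
def table3():
    return pd.read_csv(fixture_path("table3_patient.csv"))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def clean_phantom(default_config):
    """Noise-free digital Catphan on the test-scale grid (shared, read-only)."""
    return build_digital_phantom(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
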