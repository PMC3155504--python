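import numpy as np
import pytest

import tregloop as tl


@pytest.fixture(scope="session")
def default_params():
    return tl.ModelParameters()


@pytest.fixture(scope="session")
def default_inflow():
    return tl.expected_inflow()


@pytest.fixture(scope="session")
def short_autoimmune():
    """A short autoimmune-regime trajectory shared across read-only tests."""
    return tl.simulate(tl.autoimmune_config(master_seed=1, duration=365.0))


@pytest.fixture(scope="session")
def autoimmune_run():
    """Full-length (5-year) autoimmune trajectory, seed 1."""
    return tl.simulate(tl.autoimmune_config(master_seed=1))


@pytest.fixture(scope="session")
def healthy_run():
    """Full-length (5-year) healthy trajectory, seed 1."""
    return tl.simulate(tl.healthy_config(master_seed=1))
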