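import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from hcdkit import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic landscape (seed 42, 300 genes, 15 planted
    domains, 10 planted SE clusters)."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()
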