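import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from overdent.scenarios import base_tables

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base():
    """The base-case model configuration (10-year horizon)."""
    return base_tables()


@pytest.fixture(scope="session")
def base_params(base):
    """Base case resolved at the modes, average complexity factor 2.3."""
    return base.at_modes(2.3)
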