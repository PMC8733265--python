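import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def head_tail():
    """The labeled-S1 × S2Δ head–tail preset (Kd 0.6 μmol/l, n = 8)."""
    from mstbind import head_tail_scenario

    return head_tail_scenario()
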