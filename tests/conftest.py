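import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eiscap import CircuitParams, FrequencyGrid

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: The five simulation cases: shared Ts=0.1, Ps=0.3, Rd=10 kOhm, Td=1e-6,
#: varying (Ce, Pd); printed Cef in uF to one decimal.
SIMULATION_CASES = {
    "a": (CircuitParams(ts=0.1, ps=0.3, ce=1e-6, rd=1e4, td=1e-6, pd=0.7), 1.1),
    "b": (CircuitParams(ts=0.1, ps=0.3, ce=1e-6, rd=1e4, td=1e-6, pd=0.8), 1.3),
    "c": (CircuitParams(ts=0.1, ps=0.3, ce=1e-6, rd=1e4, td=1e-6, pd=0.9), 1.6),
    "d": (CircuitParams(ts=0.1, ps=0.3, ce=2e-6, rd=1e4, td=1e-6, pd=0.9), 2.6),
    "e": (CircuitParams(ts=0.1, ps=0.3, ce=4e-6, rd=1e4, td=1e-6, pd=0.9), 4.6),
}


@pytest.fixture
def grid() -> FrequencyGrid:
    return FrequencyGrid.log_spaced()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
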