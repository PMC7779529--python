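import numpy as np
import pytest
from hypothesis import settings

import ctwc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ctwc.CTWCParameters()


@pytest.fixture(scope="session")
def small_connectome():
    """8-node synthetic connectome, fully deterministic."""
    return ctwc.generate_connectome(ctwc.SyntheticConnectomeSpec(n_nodes=8, seed=7))


@pytest.fixture(scope="session")
def idling_run(params):
    """Single idling node, 20 s, nominal parameters."""
    return ctwc.simulate_single_node(params, i_o=0.0, duration_ms=20000.0, seed=1)


@pytest.fixture(scope="session")
def active_run(params):
    """Single node driven into the active state (I_o = 1.5), 20 s."""
    return ctwc.simulate_single_node(params, i_o=1.5, duration_ms=20000.0, seed=1)
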