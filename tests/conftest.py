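import numpy as np
import pytest
from hypothesis import settings

from hcmcell import default_params, extract_biomarkers, run_to_steady_state

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params():
    return default_params()


@pytest.fixture(scope="session")
def control_steady(base_params):
    """Control model paced to steady state (shared across tests)."""
    res = run_to_steady_state(base_params, tol=1e-6)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def control_biomarkers(control_steady):
    return extract_biomarkers(control_steady.trace)


@pytest.fixture(scope="session")
def control_state(control_steady):
    return np.array(control_steady.state)
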