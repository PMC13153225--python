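import numpy as np
import pytest

from oecmsim.circuit import SolverOptions
from oecmsim.presets import paper2026


@pytest.fixture(scope="session")
def params():
    """Standard testing condition (E_K = -0.10 V)."""
    return paper2026(e_k=-0.10)


@pytest.fixture(scope="session")
def fast_options():
    """Looser solver settings for unit tests that only need qualitative APs."""
    return SolverOptions(rtol=1e-5, atol=1e-8)


@pytest.fixture(scope="session")
def standard_ap(params):
    """One cached standard AP (trace, features) shared across tests."""
    from oecmsim.protocols import run_single_ap

    return run_single_ap(params)
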