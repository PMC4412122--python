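import numpy as np
import pytest

from cnpsim.signal_gen import SignalSpec, generate_cnp, make_forcing


@pytest.fixture(scope="session")
def default_spec() -> SignalSpec:
    return SignalSpec()


@pytest.fixture(scope="session")
def default_pattern(default_spec):
    return generate_cnp(default_spec)


@pytest.fixture(scope="session")
def forcing_10s(default_spec):
    """Derivative forcing at 1 mV over 10 s, shared across tests."""
    return make_forcing(default_spec, 1.0, 10_000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
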