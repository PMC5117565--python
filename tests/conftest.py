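import pytest

from mitotoxsim import DoxToxicityModel


@pytest.fixture(scope="session")
def model():
    """Shipped calibrated model with the steady-state cache pre-built."""
    m = DoxToxicityModel()
    m.qss_map()
    return m


@pytest.fixture(scope="session")
def core(model):
    return model.core


@pytest.fixture(scope="session")
def baseline(core):
    return core.baseline
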