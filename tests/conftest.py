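import numpy as np
import pytest

from caburst import ModelParams, derive_constants, paced_params


@pytest.fixture(scope="session")
def defaults():
    """Canonical model parameters."""
    return ModelParams()


@pytest.fixture(scope="session")
def paced():
    """Paced comparison configuration (EC drive calibrated for
    one-IC-spike-per-cycle competition)."""
    return paced_params()


@pytest.fixture(scope="session")
def dc_paced(paced):
    return derive_constants(paced)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
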