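import numpy as np
import pytest

from rgfmine import search as se


@pytest.fixture(scope="session")
def pam30():
    return se.load_matrix("PAM30")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
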