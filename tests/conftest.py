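import numpy as np
import pytest

from mammoshield import materials


@pytest.fixture(scope="session")
def library():
    return materials.default_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
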