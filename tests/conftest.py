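import numpy as np
import pytest

from vesselseg import synthetic
from vesselseg.paths import TINY_WIDTHS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_widths():
    return TINY_WIDTHS


@pytest.fixture(scope="session")
def synth_records():
    """Two deterministic 128x128 synthetic fundus scenes."""
    return synthetic.generate_dataset(2, synthetic.SceneParams(), seed=0)
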