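import numpy as np
import pytest

from vwflow.synthetic import preset_150mM


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def config():
    """Default 150 mM study-condition configuration."""
    return preset_150mM(seed=20260919)
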