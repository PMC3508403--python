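import numpy as np
import pytest

from benthicnloss.config import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def times():
    """Default slurry sampling grid (hours)."""
    return np.array([0.0, 5.0, 10.0, 16.0, 21.0, 27.0])
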