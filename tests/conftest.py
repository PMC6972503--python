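import numpy as np
import pytest

from inhibnet.measures import MeasureWindow


@pytest.fixture(scope="session")
def window500() -> MeasureWindow:
    """A generic 500 ms analysis window."""
    return MeasureWindow(500.0, 1000.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
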