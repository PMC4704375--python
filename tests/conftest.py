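import numpy as np
import pytest

from lipmask import Region


@pytest.fixture
def region() -> Region:
    """A mid-latitude rectangle, roughly country-sized."""
    return Region.from_bbox(47.0, 53.0, 6.0, 14.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_930)
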