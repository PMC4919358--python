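import numpy as np
import pytest

from randpam import SamplingGeometry


@pytest.fixture
def drosophila() -> SamplingGeometry:
    """R1-R6 photoreceptor geometry: 30,000 microvilli, 1 ms bins."""
    return SamplingGeometry(n_microvilli=30_000)


@pytest.fixture
def small_geometry() -> SamplingGeometry:
    """A few hundred sampling units — stick-insect-like regime."""
    return SamplingGeometry(n_microvilli=300)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20161)
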