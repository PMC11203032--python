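import numpy as np
import pytest

from getnet.bratsio import MultiModalVolume, SegmentationMask
from getnet.synthdata import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default 32³ phantom: (volume, labels)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_case(phantom):
    vol, lab = phantom
    return MultiModalVolume(vol), SegmentationMask(lab)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
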