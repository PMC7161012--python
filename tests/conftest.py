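import numpy as np
import pytest

from boxseg3d import PhantomSpec, generate_phantom, clip_and_normalize


@pytest.fixture(scope="session")
def phantom():
    """One default phantom, generated once per session."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def norm_phantom(phantom):
    """The same phantom with its image clipped/normalized to [0, 1]."""
    return clip_and_normalize(phantom.image), phantom.gt_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
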