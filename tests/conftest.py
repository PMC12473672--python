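import numpy as np
import pytest

from frondscape.params import CloneLightParams, default_clone_set


@pytest.fixture
def demo_params() -> CloneLightParams:
    """A high-light clone with the default (small) noise level."""
    return default_clone_set()[5]  # MJ201 under high light


@pytest.fixture
def quiet_params(demo_params) -> CloneLightParams:
    """The same clone with all generator noise switched off."""
    return demo_params.replace(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
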