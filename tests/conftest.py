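import numpy as np
import pytest

from raydisp.synthetic import SyntheticRaySpec


@pytest.fixture
def default_spec():
    """Study-condition spec: boundaries {100,300,500}, boundary SNR 3."""
    return SyntheticRaySpec()


@pytest.fixture
def noise_free_spec():
    return SyntheticRaySpec(noise_sd=0.0, gfp_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
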