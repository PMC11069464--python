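import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic conditions: 3 classes x 20, m=60, warp 3, noise 0.1."""
    from somtimes.synthetic import SynthSpec, generate_dataset

    return generate_dataset(SynthSpec(seed=7))
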