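import numpy as np
import pytest
from hypothesis import settings

from hippoparc import GeneratorSpec, make_subject

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_parcel_subject():
    """Parcel-mode subject with zero noise: the exactly recoverable limit."""
    spec = GeneratorSpec(mode="parcel", noise_sd=0.0, cortex_noise_sd=0.0,
                         n_timepoints=200, seed=7)
    return make_subject(spec)


@pytest.fixture(scope="session")
def noisy_mixed_subject():
    """Mixed parcel+gradient subject at the default noise level (small T)."""
    spec = GeneratorSpec(mode="mixed", noise_sd=2.0, n_timepoints=500, seed=3)
    return make_subject(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
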