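import numpy as np
import pytest

from limbseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(n_classes=3, grid_shape=(32, 24, 24), seed=9)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_phantom(small_spec, subject_seed=1)
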