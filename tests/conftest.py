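import numpy as np
import pytest

from fourchamber import PhantomSpec, default_scheme, generate_phantom


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def phantom_512():
    """Default-scale phantom: true CAx 30 deg, true CTR 0.30, no jitter."""
    return generate_phantom(PhantomSpec.from_targets(30.0, 0.30, seed=11))


@pytest.fixture(scope="session")
def phantom_256():
    """Quarter-resolution phantom for cheaper tests."""
    return generate_phantom(
        PhantomSpec.from_targets(30.0, 0.30, image_size=(256, 256), seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
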