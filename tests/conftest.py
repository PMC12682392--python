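import numpy as np
import pytest

from aptwi import cest, phantom


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Stock noise-free phantom acquisition, rendered once per session."""
    scene = phantom.default_scene(seed=7)
    return scene, phantom.simulate_phantom_volumes(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def tumor_pools():
    return (phantom.WATER_POOL, phantom.AMIDE_POOL)
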