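import numpy as np
import pytest

from canopytraits.synthdata import SceneSpec, default_cultivars, render_plant


@pytest.fixture(scope="session")
def cultivars():
    return default_cultivars()


@pytest.fixture(scope="session")
def flat_cultivar(cultivars):
    return cultivars[0]


@pytest.fixture(scope="session")
def curled_cultivar(cultivars):
    return cultivars[2]


@pytest.fixture(scope="session")
def scene():
    return SceneSpec(rng_seed=11)


@pytest.fixture(scope="session")
def small_scene():
    """Coarser scene for bulk statistics tests."""
    return SceneSpec(image_size=96, px_per_cm=4.0, rng_seed=11)


@pytest.fixture(scope="session")
def sample(flat_cultivar, scene):
    """One mid-season flat-cultivar scene."""
    return render_plant(flat_cultivar, 4, scene)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
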