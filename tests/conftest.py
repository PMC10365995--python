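import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from glossim.design import StimulusParams
from glossim.synthetic import synth_scene

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def glossy_scene():
    """A moderately rough glossy scene with visible highlights."""
    return synth_scene(
        StimulusParams(shape="dragon", light_field="kitchen",
                       specular_level=1.0, roughness=0.1),
        size=(128, 128), seed=7)


@pytest.fixture(scope="session")
def sphere_scene():
    """A plain sphere: strictly curved normals everywhere on the mask."""
    return synth_scene(
        StimulusParams(shape="sphere", light_field="kitchen",
                       specular_level=1.0, roughness=0.1),
        size=(96, 96), seed=0)


@pytest.fixture(scope="session")
def matte_scene():
    """A zero-specular control scene."""
    return synth_scene(
        StimulusParams(specular_level=0.0), size=(96, 96), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
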