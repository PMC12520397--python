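import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pigmentsep.scene import make_scene, render_skin_image

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scene():
    """Default-texture scene, small enough for fast unit tests."""
    return make_scene(64, 64, n_spots=40, seed=11)


@pytest.fixture(scope="session")
def small_image(small_scene):
    return render_skin_image(small_scene)


@pytest.fixture(scope="session")
def strong_scene():
    """Strong-feature scene: well-identified ICA regime, no shading."""
    return make_scene(
        128, 128, n_spots=40, spot_scale=6.0, amp_scale=3.0, shading_amplitude=0.0, seed=1
    )


@pytest.fixture(scope="session")
def strong_image(strong_scene):
    return render_skin_image(strong_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
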