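import numpy as np
import pytest

from rownav.geometry import CameraIntrinsics
from rownav.synthetic import SceneConfig, render_scene


@pytest.fixture
def k():
    """The worked-example intrinsics used across the geometry tests."""
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=180.0, width=640, height=360)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene, shared read-only across tests."""
    return render_scene(SceneConfig())
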