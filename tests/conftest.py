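import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import retiflow as rf
from retiflow.containers import Calibration
from retiflow.segmentation import segment

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom():
    """Noiseless four-branch desk-scale scene with its moment video."""
    scene = rf.default_scene(seed=1)
    video, truth = rf.render_moment_video(scene)
    return scene, video, truth


@pytest.fixture(scope="session")
def phantom_map(phantom):
    scene, video, _ = phantom
    return segment(video, disc_center=scene.disc_center,
                   disc_diameter_px=scene.disc_diameter_px)


@pytest.fixture(scope="session")
def phantom_calib(phantom):
    scene, _, _ = phantom
    return Calibration(pixel_size_um=scene.pixel_size_um)
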