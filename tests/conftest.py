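import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pomograde import GradingConfig, SceneSpec, generate_scene

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20140119)


@pytest.fixture
def cfg():
    return GradingConfig()


@pytest.fixture
def scene_factory():
    """Build a labeled scene with sensible defaults, overridable per test."""

    def make(variety="Jonagold", red=0.7, diameter_mm=64.0, seed=11,
             cfg=GradingConfig(), center=None, margin=12):
        ax = diameter_mm / cfg.pixel_length_mm / 2.0
        size = int(np.ceil(2 * ax)) + 2 * margin
        if center is None:
            center = (size / 2.0, size / 2.0)
        spec = SceneSpec(
            image_size=(size, size), apple_center=center,
            apple_axes=(ax, ax), variety=variety,
            red_patch_fraction=red, yellow_patch_fraction=1.0 - red,
            seed=seed, pixel_length_mm=cfg.pixel_length_mm)
        return generate_scene(spec, cfg)

    return make
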