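import numpy as np
import pytest

from pigdepth.synthetic_scene import SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """Fast 64x64 noise-free scene configuration."""
    return SceneConfig(image_height_px=64, image_width_px=64, depth_noise_std_mm=0.0)


@pytest.fixture(scope="session")
def noisy_small_config() -> SceneConfig:
    return SceneConfig(image_height_px=64, image_width_px=64, depth_noise_std_mm=2.0)


@pytest.fixture(scope="session")
def tiny_dataset(noisy_small_config):
    """A small reusable synthetic dataset (images + label matrix)."""
    data = generate_dataset(40, noisy_small_config, seed=11)
    images = np.stack([img.data for img, _ in data])
    labels = np.stack([lab for _, lab in data])
    return images, labels
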