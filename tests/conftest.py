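import numpy as np
import pytest

from photosense.bounds import default_bounds
from photosense.synthetic import SyntheticDatasetSpec, generate_synthetic_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Eight 64px synthetic lesion images with metadata (fast fixture)."""
    return generate_synthetic_dataset(
        SyntheticDatasetSpec(n_images=8, image_side=64, melanoma_fraction=0.25, seed=11)
    )


@pytest.fixture(scope="session")
def study_dataset():
    """The default study configuration: 8 images at 128px, seed 2021."""
    return generate_synthetic_dataset(SyntheticDatasetSpec(n_images=8, seed=2021))


@pytest.fixture
def bounds():
    return default_bounds()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gradient_image():
    """A horizontal luminance gradient (order-sensitivity fixture)."""
    row = np.linspace(0, 255, 64).astype(np.uint8)
    return np.tile(row[None, :, None], (64, 1, 3))
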