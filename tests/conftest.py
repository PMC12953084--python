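import numpy as np
import pytest

from glymquant.images import MultiChannelImage
from glymquant.phantoms import ImagePhantomConfig, generate_astrocyte_image
from glymquant.segmentation import segment_astrocytes


@pytest.fixture(scope="session")
def noise_free_phantom():
    """One noise-free astrocyte phantom with its ground truth."""
    cfg = ImagePhantomConfig(true_polarization=64.74, noise_sd=0.0, seed=7)
    return generate_astrocyte_image(cfg)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-noise astrocyte phantom with its ground truth."""
    cfg = ImagePhantomConfig(true_polarization=72.41, seed=11)
    return generate_astrocyte_image(cfg)


def make_image(channels: dict, pixel_size_um: float = 1.0) -> MultiChannelImage:
    return MultiChannelImage(
        channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
        pixel_size_um=pixel_size_um,
    )


@pytest.fixture
def three_cell_image():
    """Noise-free field with three well-separated astrocytes."""
    cfg = ImagePhantomConfig(
        image_size=(300, 300), n_astrocytes=3, n_processes=0,
        true_polarization=50.0, noise_sd=0.0, seed=5,
    )
    return generate_astrocyte_image(cfg)
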