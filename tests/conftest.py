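import numpy as np
import pytest

from ctiq.phantoms import PhantomTruth, simulate_noise_volume, simulate_wire_image
from ctiq.volume import ImageVolume


@pytest.fixture
def flat_volume():
    """A constant 7-HU volume, 64x64 px at 0.5 mm pitch."""
    return ImageVolume(np.full((3, 64, 64), 7.0), 0.5, 0.5, 1.0)


@pytest.fixture(scope="session")
def wire_default():
    """Noiseless wire image at the default PSF (sigma 0.1874 mm)."""
    truth = PhantomTruth(psf_sigma=0.1874)
    vol, t = simulate_wire_image(truth, grid_size=128, pixel_pitch=0.1)
    return vol, t


@pytest.fixture(scope="session")
def white_noise_volume():
    """Uniform volume of white noise, SD 10 HU, 8 i.i.d. slices, 0.5 mm pitch."""
    truth = PhantomTruth(noise_sigma_white=10.0, rng_seed=42)
    vol, t = simulate_noise_volume(truth, grid_size=256, pixel_pitch=0.5,
                                   n_slices=8)
    return vol, t
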