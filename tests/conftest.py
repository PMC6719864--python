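import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tellimc import dexenon_stack, standard_phantom


@pytest.fixture(scope="session")
def phantom():
    """The fixed reference phantom (stack, truth), generated once."""
    return standard_phantom()


@pytest.fixture(scope="session")
def corrected_stack(phantom):
    """The standard phantom after clipped xenon removal."""
    stack, _ = phantom
    return dexenon_stack(stack, clip=True)


@pytest.fixture(scope="session")
def snr_masks(phantom):
    """Well-separated signal/noise regions: tissue eroded 4 px vs the
    complement of tissue dilated 8 px, so a sigma = 1 blur cannot smear
    tissue counts into the noise region."""
    _, truth = phantom
    signal = ndimage.binary_erosion(truth.tissue_mask, iterations=4)
    noise = ~ndimage.binary_dilation(truth.tissue_mask, iterations=8)
    return signal, noise


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
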