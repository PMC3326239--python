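import numpy as np
import pytest

from petseg.benchmark import case_context
from petseg.phantom import LesionComponent, PhantomSpec, make_phantom
from petseg.preprocess import preprocess
from petseg.volume import BinaryMask, ImageVolume


@pytest.fixture(scope="session")
def sphere_spec():
    """Noiseless 3-cm sphere at 8:1 contrast, blurred at 6 mm FWHM."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        background_uptake=1.0,
        components=[LesionComponent("sphere", (48.0, 48.0, 48.0), (15.0,) * 3, 8.0)],
        blur_fwhm_mm=6.0,
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def sphere_case(sphere_spec):
    """(raw image, truth mask) for the blurred sphere."""
    return make_phantom(sphere_spec)


@pytest.fixture(scope="session")
def sphere_preprocessed(sphere_case):
    """Preprocessed sphere image plus the derived seed/search/background ROIs."""
    raw, truth = sphere_case
    img = preprocess(raw)
    seed, region, bkg = case_context(truth)
    return img, truth, seed, region, bkg


@pytest.fixture()
def two_level_image():
    """Noiseless two-level image: a 5-voxel-radius cube of SUV 8 in SUV-1
    background (no blur), for closed-form fixed-point checks."""
    vals = np.ones((24, 24, 24))
    vals[8:16, 8:16, 8:16] = 8.0
    return ImageVolume(vals, (2.0, 2.0, 2.0))


def make_mask(shape, spacing=(1.0, 1.0, 1.0), where=()):
    m = np.zeros(shape, dtype=bool)
    for idx in where:
        m[idx] = True
    return BinaryMask(m, spacing)
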