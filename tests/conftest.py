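import numpy as np
import pytest

from iriseg.levelset import chan_vese_segment
from iriseg.phantom import PhantomSpec, generate_phantom
from iriseg.volumes import BinaryMask, ImageVolume, normalize_minmax

SPACING = (8.0, 1.5, 1.5)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced phantom for fast unit tests (full default is exercised in
    the acceptance tests)."""
    return PhantomSpec(
        shape=(16, 48, 48),
        liver_semiaxes=(7.0, 20.0, 20.0),
        n_cysts=5,
        cyst_radius=(2.0, 5.0),
        n_vessels=1,
    )


@pytest.fixture(scope="session")
def default_case():
    """One default phantom case with its normalized volume and level-set mask."""
    volume, cyst_gt, vessels, roi = generate_phantom(seed=7)
    normed = normalize_minmax(volume)
    ls = chan_vese_segment(normed, roi)
    return {
        "volume": volume,
        "normed": normed,
        "cyst_gt": cyst_gt,
        "vessels": vessels,
        "roi": roi,
        "ls": ls,
    }


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(np.asarray(data, dtype=bool), spacing)


def slice_volume(img2d, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Wrap a 2D image as a single-slice 3D volume."""
    return ImageVolume(np.asarray(img2d, dtype=float)[None], spacing)


def full_roi(volume: ImageVolume) -> BinaryMask:
    return BinaryMask(np.ones(volume.shape, dtype=bool), volume.spacing)
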