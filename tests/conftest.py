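import numpy as np
import pytest

from gisthabitat.synthetic_cohort import PhantomSpec, generate_phantom
from gisthabitat.preprocess import rescale_unit, znormalize
from gisthabitat.volume import ImageVolume, TumorMask


@pytest.fixture(scope="session")
def phantom_high():
    """One high-mitotic-class phantom with a pronounced skewed core."""
    spec = PhantomSpec(
        diameter_mm=30.0, class_label="high", core_fraction=0.3,
        skewness_target=-2.0, flatness_target=0.8, seed=7,
    )
    unenh, venous, mask, truth = generate_phantom(spec)
    return dict(spec=spec, unenhanced=unenh, venous=venous, mask=mask, truth=truth)


@pytest.fixture(scope="session")
def preprocessed_high(phantom_high):
    """The same phantom, z-normalized and unit-rescaled for clustering."""
    img = znormalize(phantom_high["unenhanced"])
    rescaled = rescale_unit(img, phantom_high["mask"])
    return dict(image=img, rescaled=rescaled, mask=phantom_high["mask"],
                truth=phantom_high["truth"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(values, dtype=float), spacing)


def make_mask(shape_or_array, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(shape_or_array)
    if arr.ndim == 1:  # a shape tuple
        arr = np.ones(tuple(arr), dtype=np.uint8)
    return TumorMask(arr.astype(np.uint8), spacing)
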