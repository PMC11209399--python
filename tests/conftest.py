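import numpy as np
import pytest

from nucmorph import ImageSpec, generate_nucleus_image


@pytest.fixture(scope="session")
def small_roi():
    """One seeded 400×300 ROI with 50 disjoint nuclei and its ground truth."""
    spec = ImageSpec(width_px=400, height_px=300, n_nuclei=50,
                     overlap_fraction=0.0, seed=7)
    image, labels, polygons = generate_nucleus_image(spec)
    return spec, image, labels, polygons


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
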