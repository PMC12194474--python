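import numpy as np
import pytest

from cxraug.formats import normalize_intensity
from cxraug.synthetic import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom(rng):
    """One unit-scale phantom guaranteed to carry lesions."""
    cfg = PhantomConfig(lesions_per_image=(2, 3), seed=7)
    item = generate_phantom(cfg, rng)
    item.image = normalize_intensity(item.image)
    return item
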