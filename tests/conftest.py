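import numpy as np
import pytest

from cvigrade.image import LegImage
from cvigrade.synthetic import SynthSpec, generate_leg_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def canonical_image(rng):
    """A canonical-size image with a centered rectangular foreground."""
    pixels = rng.uniform(40, 220, size=(700, 250, 3))
    mask = np.zeros((700, 250), dtype=bool)
    mask[30:670, 40:210] = True
    return LegImage(pixels=pixels, mask=mask, id="fixture")


@pytest.fixture(scope="session")
def synth_image():
    """One deterministic severe synthetic leg with ground truth."""
    rng = np.random.default_rng(7)
    return generate_leg_image("severe", SynthSpec(n_per_class=1, seed=7), rng)
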