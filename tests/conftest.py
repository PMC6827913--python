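import numpy as np
import pytest

from shadowedge import GeneratorParams, generate_dataset

#: measured CRT phosphor chromaticities (x, y, Y) used throughout the tests
CRT_PRIMARIES = [
    (0.6207, 0.3380, 15.0485),
    (0.2822, 0.6068, 57.0515),
    (0.1495, 0.0683, 6.9209),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190)


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(sizes=(72,))


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """8 patches/class, 72 px only: quick but large enough for LDA fits."""
    return generate_dataset(8, small_params, seed=11)


def make_step_patch(height=72, width=72, top=1.0, bottom=0.0, lm=0.0, sop=0.0):
    """Ideal oriented luminance step in opponent space (transition on the midline)."""
    img = np.zeros((height, width, 3))
    img[: height // 2, :, 0] = top
    img[height // 2 :, :, 0] = bottom
    img[..., 1] = lm
    img[..., 2] = sop
    return img
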