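import numpy as np
import pytest

from radrobust.volumes import ROIMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_roi(rng):
    """A random 8x8x6 HU volume with an irregular ~70% foreground mask."""
    values = rng.normal(60.0, 12.0, size=(8, 8, 6))
    mask = rng.random((8, 8, 6)) < 0.7
    mask[3, 3, 2] = True  # never empty
    image = VolumeImage(values, (0.8, 0.8, 2.0))
    return image, ROIMask(mask, (0.8, 0.8, 2.0))


def random_gl_volume(rng, max_side=6, n_levels=8, fill=0.8):
    """Random discretised grey-level volume (0 outside the ROI)."""
    shape = tuple(int(v) for v in rng.integers(3, max_side + 1, 3))
    gl = rng.integers(1, n_levels + 1, size=shape)
    inside = rng.random(shape) < fill
    gl = np.where(inside, gl, 0)
    if (gl > 0).sum() < 4:
        gl[1, 1, 1] = 1
        gl[1, 1, 2] = 2
        gl[1, 2, 1] = 1
        gl[2, 1, 1] = 3
    return gl
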