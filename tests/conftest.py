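import numpy as np
import pytest

from fracseg.io_core import LabelMap, Volume
from fracseg.phantom import PhantomSpec, make_bone_shape, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def split_fragment_map():
    """4x4x4 grid at 1 mm: label 1 at x in {0,1}, label 2 at x in {2,3}."""
    d = np.zeros((4, 4, 4), dtype=np.int32)
    d[:2] = 1
    d[2:] = 2
    return LabelMap(d, spacing=(1.0, 1.0, 1.0), scheme="fragment")


def random_fragment_map(rng, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    """A random blobby two-fragment map for oracle comparisons."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    fg = field > np.quantile(field, 0.5)
    cut = ndimage.gaussian_filter(rng.normal(size=shape), sigma=3.0)
    data = np.zeros(shape, dtype=np.int32)
    data[fg & (cut <= np.median(cut[fg]) if fg.any() else cut <= 0)] = 1
    data[fg & (data == 0)] = 2
    if not (data == 1).any() or not (data == 2).any():
        # force both labels present
        data[0, 0, 0] = 1
        data[-1, -1, -1] = 2
    return LabelMap(data, spacing=spacing, scheme="fragment")


@pytest.fixture
def single_bone_spec():
    return PhantomSpec(grid_shape=(48, 48, 48), n_bones=1, scenario="stable_gap", seed=13)


@pytest.fixture
def small_scene():
    spec = PhantomSpec(grid_shape=(64, 64, 64), n_bones=2, scenario="compression", seed=21)
    return make_scene(spec)
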