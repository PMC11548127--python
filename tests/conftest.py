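import dataclasses

import numpy as np
import pytest

from ftirmap.core import PixelMask, SpectralCube, WavenumberAxis
from ftirmap.simulate import default_sc_config, simulate_map


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_axis():
    """Axis 1000..1016 step 8, five channels."""
    return WavenumberAxis(np.arange(1000.0, 1033.0, 8.0))


def make_cube(data, axis=None, pitch=2.7):
    data = np.asarray(data, dtype=float)
    if axis is None:
        axis = WavenumberAxis(1000.0 + 8.0 * np.arange(data.shape[2]))
    return SpectralCube(data=data, axis=axis, pixel_pitch=pitch)


@pytest.fixture
def random_cube(rng):
    """8x8x5 cube of positive random absorbance."""
    return make_cube(rng.uniform(0.1, 1.0, size=(8, 8, 5)))


def small_sc_config(seed=0, rows=32, cols=32, **overrides):
    cfg = default_sc_config(seed=seed)
    return dataclasses.replace(cfg, rows=rows, cols=cols, **overrides)


def quiet_sc_config(seed=0, rows=16, cols=16, **overrides):
    """No heterogeneity, no artifacts: every pixel identical."""
    defaults = dict(
        thickness_cv=0.0,
        lipid_weight_cv=0.0,
        baseline_scale=0.0,
        noise_sd=0.0,
        hot_frac=0.0,
        dead_frac=0.0,
        contam_frac=0.0,
    )
    defaults.update(overrides)
    return small_sc_config(seed=seed, rows=rows, cols=cols, **defaults)


@pytest.fixture
def sc_map_with_artifacts():
    cube, truth = simulate_map(small_sc_config(seed=7, rows=48, cols=48))
    return cube, truth


def full_mask(cube):
    return PixelMask.full((cube.rows, cube.cols))
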