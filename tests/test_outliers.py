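import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftirmap.core import (
    DegenerateDistributionError,
    InsufficientDataError,
    PixelMask,
)
from ftirmap.outliers import (
    FenceParams,
    PcaParams,
    band_histogram,
    fd_bin_width,
    fd_bin_width_from_iqr,
    histogram_outliers,
    pca_outliers,
    tukey_fences,
)
from ftirmap.preprocess import BaselineParams, PreprocessPlan, apply_plan
from ftirmap.qc import confusion_rates
from ftirmap.simulate import simulate_map

from .conftest import make_cube, quiet_sc_config, small_sc_config


class TestTukeyFences:
    def test_equal_values(self):
        lo, hi = tukey_fences(np.full(10, 4.2), k=1.5)
        assert lo == hi == pytest.approx(4.2)

    def test_k_zero_gives_quartiles(self, rng):
        values = rng.normal(size=100)
        lo, hi = tukey_fences(values, k=0.0)
        assert lo == pytest.approx(np.percentile(values, 25))
        assert hi == pytest.approx(np.percentile(values, 75))

    def test_hand_computed_example(self):
        # Q1 = 2.25, Q3 = 4.75 by linear interpolation
        lo, hi = tukey_fences([1, 2, 3, 4, 5, 100], k=1.5)
        assert lo == pytest.approx(-1.5)
        assert hi == pytest.approx(8.5)
        assert 100 > hi  # the outlier is outside the fence

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            tukey_fences([1.0, 2.0, 3.0], k=1.5)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60),
        st.floats(min_value=0.0, max_value=2.0),
        st.floats(min_value=0.0, max_value=2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_fence_nesting(self, values, k1, dk):
        lo1, hi1 = tukey_fences(values, k1)
        lo2, hi2 = tukey_fences(values, k1 + dk)
        assert lo2 <= lo1 and hi1 <= hi2


class TestFdBinWidth:
    def test_closed_forms(self):
        assert fd_bin_width_from_iqr(1.0, 8) == pytest.approx(1.0)
        assert fd_bin_width_from_iqr(2.0, 1) == pytest.approx(4.0)
        assert fd_bin_width_from_iqr(0.5, 1000) == pytest.approx(0.1)

    def test_from_values(self):
        # quartiles of 0..7 are 1.75 and 5.25: IQR = 3.5, n = 8
        values = np.arange(8.0)
        assert fd_bin_width(values) == pytest.approx(2 * 3.5 / 2.0)

    def test_zero_iqr_signals_single_bin(self):
        with pytest.raises(DegenerateDistributionError):
            fd_bin_width(np.full(10, 1.0))

    def test_band_histogram_falls_back_to_single_bin(self):
        counts, edges = band_histogram(np.full(10, 1.0))
        assert counts.tolist() == [10]


def _flat_cube(value=0.5, shape=(12, 12), channels=24):
    data = np.full(shape + (channels,), value)
    # give channels distinct but pixel-constant values so PCA sees variance 0
    data += np.linspace(0, 0.1, channels)
    return make_cube(data)


class TestHistogramOutliers:
    def test_homogeneous_map_no_outliers(self):
        cube = _flat_cube()
        band = _any_band(cube)
        with pytest.warns(RuntimeWarning):
            mask = histogram_outliers(cube, FenceParams(k=1.5, bands=(band,)))
        assert mask.grid.all()

    def test_hot_pixels_exactly_flagged(self, rng):
        cube = _flat_cube()
        flat_idx = rng.choice(cube.n_pixels, size=10, replace=False)
        rows, cols = np.divmod(flat_idx, cube.cols)
        data = cube.data.copy()
        data[rows, cols] += 10.0
        # bounded jitter breaks degeneracy without creating fence-crossing tails
        data += rng.uniform(-1e-3, 1e-3, data.shape)
        cube = cube.with_data(data)
        mask = histogram_outliers(cube, FenceParams(k=1.5, bands=(_any_band(cube),)))
        expected = np.ones((cube.rows, cube.cols), dtype=bool)
        expected[rows, cols] = False
        np.testing.assert_array_equal(mask.grid, expected)

    def test_retention_monotone_in_k(self, rng):
        cube = make_cube(rng.lognormal(0, 0.4, size=(16, 16, 8)))
        band = _any_band(cube)
        retentions = [
            histogram_outliers(cube, FenceParams(k=k, bands=(band,))).retention
            for k in (0.5, 1.0, 1.5, 3.0)
        ]
        assert retentions == sorted(retentions)

    def test_union_flags_superset_of_intersection(self, rng):
        cube = make_cube(rng.lognormal(0, 0.5, size=(16, 16, 8)))
        bands = (_any_band(cube, 0), _any_band(cube, 4))
        union = histogram_outliers(cube, FenceParams(k=1.0, bands=bands, combine="union"))
        inter = histogram_outliers(cube, FenceParams(k=1.0, bands=bands, combine="intersection"))
        assert ((~union.grid) >= (~inter.grid)).all()

    def test_dead_pixels_auto_outliers(self, rng):
        cube = make_cube(rng.uniform(0.2, 0.6, size=(10, 10, 8)))
        data = cube.data.copy()
        data[2, 3] = np.nan
        cube = cube.with_data(data)
        mask = histogram_outliers(cube, FenceParams(k=3.0, bands=(_any_band(cube),)))
        assert not mask.grid[2, 3]

    def test_provenance_records_parameters(self, rng):
        cube = make_cube(rng.uniform(0, 1, size=(8, 8, 8)))
        mask = histogram_outliers(cube, FenceParams(k=1.0, bands=(_any_band(cube),)))
        assert "k=1.0" in mask.provenance


def _any_band(cube, channel=None):
    from ftirmap.core import BandDef

    center = cube.axis.values[channel if channel is not None else len(cube.axis) // 2]
    return BandDef(f"ch{center:.0f}", center, 0.0, (center - 4.0, center + 4.0))


class TestPcaOutliers:
    def test_identical_spectra_no_outliers(self):
        cube = _flat_cube()
        mask, table = pca_outliers(cube, PcaParams())
        assert mask.grid.all()
        assert (table["distance"] == 0).all()

    def test_single_spike_flagged(self, rng):
        cube = _flat_cube()
        data = cube.data.copy()
        data[4, 7] += 5.0
        cube = cube.with_data(data)
        mask, table = pca_outliers(cube, PcaParams())
        expected = np.ones((cube.rows, cube.cols), dtype=bool)
        expected[4, 7] = False
        np.testing.assert_array_equal(mask.grid, expected)

    def test_threshold_nesting(self, rng):
        cube = make_cube(rng.lognormal(0, 0.4, size=(16, 16, 12)))
        loose, _ = pca_outliers(cube, PcaParams(threshold_c=4.0))
        tight, _ = pca_outliers(cube, PcaParams(threshold_c=2.0))
        assert (loose.grid >= tight.grid).all()

    def test_dead_pixels_auto_outliers(self, rng):
        cube = make_cube(rng.uniform(0.2, 0.6, size=(10, 10, 8)))
        data = cube.data.copy()
        data[5, 5] = np.nan
        cube = cube.with_data(data)
        mask, _ = pca_outliers(cube, PcaParams())
        assert not mask.grid[5, 5]

    def test_channel_reorder_invariance(self, rng):
        cube = make_cube(rng.lognormal(0, 0.4, size=(12, 12, 10)))
        mask1, _ = pca_outliers(cube, PcaParams())
        perm = rng.permutation(10)
        # same axis labels, genuinely permuted channel data: the detector
        # must not care which wavenumber sits in which column
        reordered = cube.with_data(cube.data[..., perm])
        mask2, _ = pca_outliers(reordered, PcaParams())
        np.testing.assert_array_equal(mask1.grid, mask2.grid)

    def test_channel_affine_rescale_invariance_when_scaled(self, rng):
        cube = make_cube(rng.lognormal(0, 0.4, size=(12, 12, 10)))
        gains = rng.uniform(0.5, 2.0, 10)
        offsets = rng.uniform(-1.0, 1.0, 10)
        rescaled = cube.with_data(cube.data * gains + offsets)
        mask1, _ = pca_outliers(cube, PcaParams(scale_channels=True))
        mask2, _ = pca_outliers(rescaled, PcaParams(scale_channels=True))
        np.testing.assert_array_equal(mask1.grid, mask2.grid)

    def test_score_table_shape(self, rng):
        cube = make_cube(rng.uniform(0, 1, size=(6, 6, 8)))
        mask, table = pca_outliers(cube, PcaParams(n_components=3))
        assert {"row", "col", "pc1", "pc2", "pc3", "distance", "outlier"} <= set(table.columns)
        assert len(table) == 36

    def test_insufficient_pixels(self):
        cube = make_cube(np.random.default_rng(0).uniform(0, 1, size=(1, 2, 5)))
        with pytest.raises(InsufficientDataError):
            pca_outliers(cube, PcaParams(n_components=2))


@pytest.fixture(scope="module")
def prepared():
    cube, truth = simulate_map(small_sc_config(seed=31, rows=48, cols=48))
    pp, valid = apply_plan(cube, PreprocessPlan(BaselineParams(), "area"))
    return pp, truth


class TestRecoveryOnSimulatedMaps:
    """Both protocols recover injected defects on a preprocessed default map."""

    def test_histogram_recovery(self, prepared):
        pp, truth = prepared
        mask = histogram_outliers(pp, FenceParams(k=1.5))
        sens, spec = confusion_rates(mask, truth.outlier_mask)
        assert sens >= 0.95
        assert spec >= 0.95

    def test_pca_recovery(self, prepared):
        pp, truth = prepared
        mask, _ = pca_outliers(pp, PcaParams(n_components=2, threshold_c=3.0))
        sens, spec = confusion_rates(mask, truth.outlier_mask)
        assert sens >= 0.95
        assert spec >= 0.95
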