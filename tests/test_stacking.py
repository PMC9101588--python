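import json

import numpy as np
import pytest
import shapely

from esdm.grids import GridSpec
from esdm.stacking import BinaryMap, binarize, mask_stream_buffer, stack_richness
from esdm.terrain import meters_per_degree


@pytest.fixture(scope="module")
def grid():
    return GridSpec(40, 40, -100.0, 23.0, 1 / 120)


class TestBinarize:
    def test_threshold_zero_all_ones_on_positive_map(self, grid):
        pred = np.full(grid.shape, 0.3)
        assert binarize(pred, 0.0, grid).values.sum() == grid.n_rows * grid.n_cols

    def test_exactly_at_threshold_is_absence(self, grid):
        pred = np.full(grid.shape, 0.42)
        assert binarize(pred, 0.42, grid).values.sum() == 0

    def test_threshold_one_all_zero_and_nan_preserved(self, grid):
        pred = np.random.default_rng(0).random(grid.shape)
        pred[0, 0] = np.nan
        bm = binarize(pred, 1.0, grid)
        assert np.nansum(bm.values) == 0
        assert np.isnan(bm.values[0, 0])

    def test_monotone_in_threshold(self, grid):
        pred = np.random.default_rng(1).random(grid.shape)
        counts = [binarize(pred, t, grid).count_presences()
                  for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_threshold(self, grid):
        with pytest.raises(ValueError):
            binarize(np.zeros(grid.shape), 1.5, grid)


class TestStackRichness:
    def _bm(self, grid, values, name=""):
        return BinaryMap(grid=grid, values=np.asarray(values, dtype=float),
                         species=name)

    def test_disjoint_maps_conserve_total(self, grid):
        a = np.zeros(grid.shape); a[:5] = 1
        b = np.zeros(grid.shape); b[10:15] = 1
        rich = stack_richness([self._bm(grid, a, "a"), self._bm(grid, b, "b")])
        assert set(np.unique(rich.values)) <= {0.0, 1.0}
        assert rich.total() == a.sum() + b.sum()

    def test_identical_all_one_maps(self, grid):
        maps = [self._bm(grid, np.ones(grid.shape), f"s{i}") for i in range(4)]
        rich = stack_richness(maps)
        assert (rich.values == 4).all()

    def test_manual_sum_on_5x5_fixture(self):
        grid5 = GridSpec(5, 5, 0.0, 1.0, 0.1)
        rng = np.random.default_rng(2)
        mats = [(rng.random(grid5.shape) > 0.5).astype(float) for _ in range(3)]
        rich = stack_richness([self._bm(grid5, m) for m in mats])
        for r in range(5):
            for c in range(5):
                assert rich.values[r, c] == mats[0][r, c] + mats[1][r, c] + mats[2][r, c]

    def test_nodata_semantics_and_contributing_counts(self, grid):
        a = np.ones(grid.shape); a[0, 0] = np.nan
        b = np.ones(grid.shape); b[0, 0] = np.nan; b[0, 1] = np.nan
        rich = stack_richness([self._bm(grid, a), self._bm(grid, b)])
        assert np.isnan(rich.values[0, 0])          # nodata in all inputs
        assert rich.values[0, 1] == 1               # sums over the one with data
        assert rich.n_contributing[0, 1] == 1
        assert rich.values[1, 1] == 2

    def test_grid_mismatch_rejected(self, grid):
        other = GridSpec(40, 40, -99.0, 23.0, 1 / 120)
        with pytest.raises(ValueError, match="different grids"):
            stack_richness([self._bm(grid, np.zeros(grid.shape)),
                            self._bm(other, np.zeros(other.shape))])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            stack_richness([])


class TestStreamBuffer:
    def _vertical_stream(self, grid):
        west, south, east, north = grid.bounds
        mid_lon = (west + east) / 2
        return shapely.LineString([(mid_lon, south - 0.1), (mid_lon, north + 0.1)])

    def test_huge_buffer_leaves_map_unchanged(self, grid):
        rich = stack_richness([BinaryMap(grid, np.ones(grid.shape), "s")])
        out = mask_stream_buffer(rich, self._vertical_stream(grid), buffer_km=10_000)
        np.testing.assert_array_equal(out.values, rich.values)

    def test_far_streams_mask_everything(self, grid):
        rich = stack_richness([BinaryMap(grid, np.ones(grid.shape), "s")])
        far = shapely.LineString([(0.0, 0.0), (1.0, 1.0)])
        out = mask_stream_buffer(rich, far, buffer_km=2.0)
        assert np.isnan(out.values).all()

    def test_straight_stream_masked_width_about_two_buffers(self, grid):
        bm = BinaryMap(grid, np.ones(grid.shape), "s")
        out = mask_stream_buffer(bm, self._vertical_stream(grid), buffer_km=2.0)
        kept_per_row = np.isfinite(out.values).sum(axis=1)
        lat_mid = grid.y_origin - grid.n_rows * grid.cell_size / 2
        m_lon, _ = meters_per_degree(lat_mid)
        cell_km = grid.cell_size * m_lon / 1000
        expected = 2 * 2.0 / cell_km
        assert (np.abs(kept_per_row - expected) <= 1.5).all()

    def test_geojson_input_and_empty_geometry_error(self, grid, tmp_path):
        bm = BinaryMap(grid, np.ones(grid.shape), "s")
        stream = self._vertical_stream(grid)
        path = tmp_path / "streams.geojson"
        path.write_text(json.dumps(shapely.geometry.mapping(stream)))
        out = mask_stream_buffer(bm, path, buffer_km=2.0)
        assert np.isfinite(out.values).any()
        with pytest.raises(ValueError, match="empty"):
            mask_stream_buffer(bm, shapely.LineString(), buffer_km=2.0)
        with pytest.raises(ValueError, match="buffer_km"):
            mask_stream_buffer(bm, stream, buffer_km=0.0)
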