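"""Raster container, I/O, resampling, aggregation and occurrence filtering."""

import numpy as np
import pytest

from enmflow.grid import (
    BiasGrid,
    GridTransform,
    RasterGrid,
    RasterStack,
    aggregate_landcover_fractions,
    balance_by_region,
    build_bias_grid,
    correlation_prune,
    filter_temporal,
    read_raster,
    resample_bilinear,
    thin_one_per_cell,
    write_raster,
)


class TestRasterIO:
    def test_round_trip_bit_exact(self, toy_grid, tmp_path):
        p = tmp_path / "g.tif"
        write_raster(toy_grid, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.values, toy_grid.values)
        assert back.transform == toy_grid.transform
        assert back.nodata == toy_grid.nodata
        assert back.crs == toy_grid.crs

    def test_stack_rejects_mismatched_shapes(self, toy_grid):
        other = RasterGrid(np.zeros((3, 3)), toy_grid.transform)
        with pytest.raises(ValueError, match="bad"):
            RasterStack({"a": toy_grid, "bad": other})

    def test_nodata_excluded_from_summaries(self, toy_grid):
        s = toy_grid.summary()
        assert s["n_valid"] == 15
        assert s["max"] == 14.0  # the nodata cell held the largest raw value


class TestBilinear:
    def test_constant_preserved(self):
        g = RasterGrid(np.full((6, 6), 7.0), GridTransform(0, 6, 1, 1))
        target = GridTransform(1, 5, 0.5, 0.5)
        out = resample_bilinear(g, target, (8, 8))
        assert np.allclose(out.values[out.valid_mask], 7.0)

    def test_midpoint_of_2x2(self):
        g = RasterGrid(np.array([[0.0, 0.0], [10.0, 10.0]]), GridTransform(0, 2, 1, 1))
        # target cell center at the exact midpoint of the four source centers
        target = GridTransform(0.5, 1.5, 1.0, 1.0)
        out = resample_bilinear(g, target, (1, 1))
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_linear_ramp_preserved(self):
        x = np.arange(10, dtype=float)
        g = RasterGrid(np.tile(x, (10, 1)), GridTransform(0, 10, 1, 1))
        target = GridTransform(2, 8, 0.5, 0.5)
        out = resample_bilinear(g, target, (10, 10))
        valid = out.valid_mask
        # ramp along x: value equals fractional column position in source units
        cols = np.arange(10)
        expect = 2 + (cols + 0.5) * 0.5 - 0.5
        np.testing.assert_allclose(out.values[5, :][valid[5, :]], expect[valid[5, :]])

    def test_nodata_corner_propagates(self):
        vals = np.array([[0.0, 0.0], [10.0, -9999.0]])
        g = RasterGrid(vals, GridTransform(0, 2, 1, 1))
        out = resample_bilinear(g, GridTransform(0.5, 1.5, 1, 1), (1, 1))
        assert out.values[0, 0] == g.nodata


class TestLandcoverAggregation:
    def test_pure_block(self):
        g = RasterGrid(np.ones((10, 10)), GridTransform(0, 10, 1, 1))
        st = aggregate_landcover_fractions(g, {1: 1}, 10)
        assert st.first.values.shape == (1, 1)
        assert st.first.values[0, 0] == 1.0

    def test_half_and_half_and_merge(self):
        vals = np.zeros((4, 4))
        vals[:, 2:] = 1.0
        g = RasterGrid(vals, GridTransform(0, 4, 1, 1))
        st = aggregate_landcover_fractions(g, {0: 0, 1: 1}, 4)
        assert st.layers["lc_0"].values[0, 0] == pytest.approx(0.5)
        assert st.layers["lc_1"].values[0, 0] == pytest.approx(0.5)
        merged = aggregate_landcover_fractions(g, {0: 0, 1: 0}, 4)
        assert merged.layers["lc_0"].values[0, 0] == pytest.approx(1.0)

    def test_dropped_class_counts_in_denominator(self):
        vals = np.zeros((4, 4))
        vals[:2] = 1.0
        g = RasterGrid(vals, GridTransform(0, 4, 1, 1))
        st = aggregate_landcover_fractions(g, {0: 0, 1: "drop"}, 4)
        assert list(st.layers) == ["lc_0"]
        assert st.layers["lc_0"].values[0, 0] == pytest.approx(0.5)

    def test_non_integer_factor_rejected(self):
        g = RasterGrid(np.zeros((5, 5)), GridTransform(0, 5, 1, 1))
        with pytest.raises(ValueError):
            aggregate_landcover_fractions(g, {0: 0}, 2)


class TestTemporalFilter:
    def test_after_cutoff_is_strict(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.5, 1.5, 2.5], [0.5, 1.5, 2.5],
                                  years=[1985, 1990, 1991])
        out = filter_temporal(occ, 1990)
        assert list(out.records["year"]) == [1991]

    def test_all_recent_unchanged_and_empty_ok(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.5, 1.5], [0.5, 1.5], years=[2000, 2010])
        assert len(filter_temporal(occ, 1990)) == 2
        empty = occ.with_records(occ.records.iloc[:0])
        assert len(filter_temporal(empty, 1990)) == 0

    def test_missing_year_dropped(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.5, 1.5], [0.5, 1.5],
                                  years=[np.nan, 2000])
        assert len(filter_temporal(occ, 1990)) == 1


class TestThinning:
    def test_one_record_per_cell(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.2, 0.4, 0.6, 0.8, 0.5], [0.5] * 5)
        out = thin_one_per_cell(occ, seed=1)
        assert len(out) == 1

    def test_distinct_cells_kept(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.5, 1.5, 2.5], [0.5, 1.5, 2.5])
        assert len(thin_one_per_cell(occ, seed=1)) == 3

    def test_deterministic_and_idempotent(self, toy_grid, make_occurrence_set):
        occ = make_occurrence_set(toy_grid, [0.2, 0.4, 1.5, 1.6], [0.5, 0.5, 1.5, 1.5])
        a = thin_one_per_cell(occ, seed=7)
        b = thin_one_per_cell(occ, seed=7)
        assert list(a.records["source_id"]) == list(b.records["source_id"])
        twice = thin_one_per_cell(a, seed=3)
        assert list(twice.records["source_id"]) == list(a.records["source_id"])


class TestBalance:
    def _region_map(self):
        vals = np.zeros((10, 20))
        vals[:, 10:] = 1.0  # two regions of 100 cells each
        return RasterGrid(vals, GridTransform(0, 10, 1, 1))

    def test_downsamples_to_min_density(self, make_occurrence_set):
        rm = self._region_map()
        lons = [0.5 + i for i in range(10)] + [10.5, 12.5]
        lats = [0.5 + (i % 5) for i in range(10)] + [0.5, 2.5]
        occ = make_occurrence_set(rm, lons, lats, regions=[0] * 10 + [1] * 2)
        out = balance_by_region(occ, rm, seed=1)
        reg = rm.values[out.records["row"], out.records["col"]]
        assert (reg == 0).sum() == 2 and (reg == 1).sum() == 2

    def test_balanced_input_identity(self, make_occurrence_set):
        rm = self._region_map()
        occ = make_occurrence_set(rm, [0.5, 2.5, 10.5, 12.5], [0.5, 2.5, 0.5, 2.5])
        out = balance_by_region(occ, rm, seed=1)
        assert len(out) == 4

    def test_single_region_identity(self, toy_grid, make_occurrence_set):
        rm = RasterGrid(np.zeros((4, 4)), toy_grid.transform)
        occ = make_occurrence_set(toy_grid, [0.5, 1.5, 2.5], [0.5, 1.5, 2.5])
        assert len(balance_by_region(occ, rm, seed=1)) == 3


class TestBiasGrid:
    def test_bm01_values(self, make_occurrence_set):
        g = RasterGrid(np.zeros((3, 3)), GridTransform(0, 3, 1, 1))
        occ = make_occurrence_set(g, [1.5], [1.5])
        bias = build_bias_grid([occ], "BM01")
        assert bias.grid.values[1, 1] == 1.0
        off = np.delete(bias.grid.values.ravel(), 4)
        assert np.all(off == 0.1)

    def test_bm001_differs_only_in_background(self, make_occurrence_set):
        g = RasterGrid(np.zeros((3, 3)), GridTransform(0, 3, 1, 1))
        occ = make_occurrence_set(g, [1.5], [1.5])
        b1 = build_bias_grid([occ], "BM01")
        b2 = build_bias_grid([occ], "BM001")
        assert set(np.unique(b2.grid.values)) == {0.01, 1.0}
        assert np.array_equal(b1.grid.values == 1.0, b2.grid.values == 1.0)

    def test_all_sampled_and_unknown_variant(self, make_occurrence_set):
        g = RasterGrid(np.zeros((2, 2)), GridTransform(0, 2, 1, 1))
        occ = make_occurrence_set(g, [0.5, 1.5, 0.5, 1.5], [0.5, 0.5, 1.5, 1.5])
        assert np.all(build_bias_grid([occ], "BM01").grid.values == 1.0)
        with pytest.raises(ValueError):
            build_bias_grid([occ], "BM05")


class TestCorrelationPrune:
    def _stack(self, cols: dict, descriptor="climate"):
        t = GridTransform(0, 1, 1, 1)
        layers = {k: RasterGrid(np.asarray(v, float).reshape(1, -1), t) for k, v in cols.items()}
        return RasterStack(layers, {k: descriptor for k in cols})

    def test_duplicate_layer_removed(self):
        x = np.random.default_rng(0).normal(size=50)
        st = self._stack({"a": x, "b": x})
        cells = np.column_stack([np.zeros(50, int), np.arange(50)])
        assert correlation_prune(st, cells) == ["a"]

    def test_independent_kept(self):
        rng = np.random.default_rng(1)
        st = self._stack({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        cells = np.column_stack([np.zeros(500, int), np.arange(500)])
        assert correlation_prune(st, cells) == ["a", "b"]

    def test_chain_keeps_a_and_c(self):
        # a~b and b~c above the cap, a~c below it: a and c share only the
        # common factor (r = 0.5), b IS the common factor (r ~ 0.71 to both)
        rng = np.random.default_rng(2)
        n = 4000
        common = rng.normal(size=n)
        a = common + rng.normal(size=n)
        c = common + rng.normal(size=n)
        b = common
        st = self._stack({"a": a, "b": b, "c": c})
        cells = np.column_stack([np.zeros(n, int), np.arange(n)])
        kept = correlation_prune(st, cells, threshold=0.65, priority=["a", "b", "c"])
        assert kept == ["a", "c"]

    def test_constant_layer_treated_as_uncorrelated(self):
        rng = np.random.default_rng(3)
        st = self._stack({"a": rng.normal(size=100), "b": np.full(100, 2.0)})
        cells = np.column_stack([np.zeros(100, int), np.arange(100)])
        assert correlation_prune(st, cells) == ["a", "b"]

    def test_order_stable(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        st = self._stack({"a": x, "b": x + 0.05 * rng.normal(size=300),
                          "c": rng.normal(size=300)})
        cells = np.column_stack([np.zeros(300, int), np.arange(300)])
        k1 = correlation_prune(st, cells, priority=["a", "b", "c"])
        k2 = correlation_prune(st, cells, priority=["a", "b", "c"])
        assert k1 == k2 == ["a", "c"]
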