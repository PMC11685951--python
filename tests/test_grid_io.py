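"""Raster round-trips, sample-table validation, predictor extraction."""

import numpy as np
import pandas as pd
import pytest

from srscape.grid import (
    AlignmentError,
    ConfigurationError,
    GridSpec,
    PredictorStack,
    Raster,
    SampleTable,
    dataset_summary,
    extract_predictors,
    read_raster,
    read_samples,
    write_raster,
)


class TestRasterIO:
    @pytest.mark.parametrize("dtype", [np.float32, np.float64])
    def test_round_trip_bit_exact(self, tmp_path, dtype):
        spec = GridSpec(n_rows=10, n_cols=10, x_min=0, y_max=10, cell_size=1.0)
        values = np.random.default_rng(0).normal(size=(10, 10)).astype(dtype)
        write_raster(Raster(values, spec), tmp_path / "r.tif")
        back = read_raster(tmp_path / "r.tif")
        assert back.values.dtype == dtype
        np.testing.assert_array_equal(back.values, values)
        assert back.spec.matches(spec)

    def test_nodata_round_trips_as_missing(self, tmp_path):
        spec = GridSpec(n_rows=3, n_cols=3, x_min=0, y_max=3, cell_size=1.0)
        values = np.ones((3, 3))
        values[1, 1] = np.nan
        write_raster(Raster(values, spec), tmp_path / "r.tif")
        back = read_raster(tmp_path / "r.tif")
        assert np.isnan(back.values[1, 1])
        assert back.valid.sum() == 8

    def test_mismatched_cell_sizes_raise_on_stacking(self):
        a = GridSpec(n_rows=4, n_cols=4, x_min=0, y_max=4, cell_size=1.0)
        b = GridSpec(n_rows=4, n_cols=4, x_min=0, y_max=4, cell_size=0.5)
        with pytest.raises(AlignmentError):
            PredictorStack.from_rasters(
                {"p": Raster(np.zeros((4, 4)), a), "q": Raster(np.zeros((4, 4)), b)},
                {"p": "continuous", "q": "continuous"},
            )


class TestCellIndexing:
    def test_west_north_edges_inclusive(self, flat_spec):
        # the shared edge between cells belongs to the east/south neighbour's
        # west/north edge, i.e. to the cell it opens into
        row, col = flat_spec.index_of(2.0, 4.0)  # on west edge of col 2, north edge of row 2
        assert (row, col) == (2, 2)
        row, col = flat_spec.index_of(0.0, 6.0)  # grid's own NW corner
        assert (row, col) == (0, 0)

    def test_outer_east_south_edges_are_outside(self, flat_spec):
        row, col = flat_spec.index_of(6.0, 3.0)
        assert col == -1
        row, col = flat_spec.index_of(3.0, 0.0)
        assert row == -1

    def test_cell_center_round_trip(self, flat_spec):
        rows = np.arange(flat_spec.n_rows)
        cols = np.arange(flat_spec.n_cols)
        x, y = flat_spec.cell_center(rows, cols)
        r2, c2 = flat_spec.index_of(x, y)
        np.testing.assert_array_equal(r2, rows)
        np.testing.assert_array_equal(c2, cols)


class TestReadSamples:
    def make_csv(self, tmp_path, rows):
        path = tmp_path / "samples.csv"
        header = "sample_id,longitude_dd,latitude_dd,sr87_sr86,sample_type,source,reference"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_valid_rows_parse(self, tmp_path):
        path = self.make_csv(
            tmp_path,
            [
                "a,10.5,-3.2,0.7123,plant,new,x",
                "b,11.0,-3.0,0.7456,soil,published,y",
                "c,12.0,2.0,0.7089,fauna,new,z",
            ],
        )
        table = read_samples(path)
        assert len(table) == 3
        assert table.rejected.empty
        assert table.frame["sr_ratio"].tolist() == [0.7123, 0.7456, 0.7089]

    def test_bad_rows_reported_not_dropped_silently(self, tmp_path):
        path = self.make_csv(
            tmp_path,
            [
                "ok,10.0,0.0,0.715,plant,new,",
                "bad_lat,10.0,95.0,0.715,plant,new,",
                "bad_sr,10.0,0.0,not_a_number,plant,new,",
            ],
        )
        table = read_samples(path)
        assert len(table) == 1
        assert len(table.rejected) == 2
        reasons = " ".join(table.rejected["reason"])
        assert "latitude out of range" in reasons
        assert "unparseable sr_ratio" in reasons

    def test_implausible_ratio_warns_but_keeps(self, tmp_path):
        path = self.make_csv(tmp_path, ["w,10.0,0.0,0.95,plant,new,"])
        with pytest.warns(UserWarning, match="87Sr/86Sr"):
            table = read_samples(path)
        assert len(table) == 1

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,longitude_dd\nx,1\n")
        with pytest.raises(ConfigurationError, match="mandatory"):
            read_samples(path)

    def test_empty_table(self, tmp_path):
        path = self.make_csv(tmp_path, [])
        with pytest.raises(ValueError, match="empty"):
            read_samples(path)

    def test_schema_remapping(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text("id,lon,lat,sr\nq,10,0,0.71\n")
        table = read_samples(
            path,
            schema={"sample_id": "id", "longitude": "lon", "latitude": "lat", "sr_ratio": "sr"},
        )
        assert len(table) == 1


def _table_at(points):
    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(points))],
            "longitude": [p[0] for p in points],
            "latitude": [p[1] for p in points],
            "sr_ratio": 0.71,
            "sample_type": "plant",
            "source": "new",
            "reference": "",
        }
    )
    return SampleTable(frame)


class TestExtraction:
    def test_fully_valued_cell_gives_raw_values(self, flat_spec):
        layer = np.arange(36, dtype=float).reshape(6, 6)
        stack = PredictorStack({"p": layer}, {"p": "continuous"}, flat_spec)
        design = extract_predictors(_table_at([(2.5, 3.5)]), stack)  # cell (2, 2)
        assert design.frame["p"].iloc[0] == layer[2, 2]
        assert design.infill_log == []

    def test_continuous_infill_is_mean_of_five_nearest(self, flat_spec):
        # sample cell (2, 2) missing; only five donor cells are valid:
        # the four rook neighbours (distance 1) and (1, 1) (distance sqrt 2,
        # first in row-major order among the diagonal ties)
        layer = np.full((6, 6), np.nan)
        layer[1, 2], layer[3, 2], layer[2, 1], layer[2, 3] = 0.710, 0.712, 0.714, 0.716
        layer[1, 1] = 0.718
        layer[5, 5] = 99.0  # farther; must not participate
        stack = PredictorStack({"p": layer}, {"p": "continuous"}, flat_spec)
        design = extract_predictors(_table_at([(2.5, 3.5)]), stack)
        assert design.frame["p"].iloc[0] == pytest.approx(0.714)
        assert design.infill_log == [(0, "p", "mean_5_nearest")]

    def test_diagonal_ties_break_row_major(self, flat_spec):
        # all four diagonal neighbours valid and equidistant; the row-major
        # first (smallest flat index) must be the one chosen for categorical
        layer = np.full((6, 6), np.nan)
        layer[1, 1], layer[1, 3], layer[3, 1], layer[3, 3] = 7.0, 8.0, 9.0, 10.0
        stack = PredictorStack({"lith": layer}, {"lith": "categorical"}, flat_spec)
        design = extract_predictors(_table_at([(2.5, 3.5)]), stack)
        assert design.frame["lith"].iloc[0] == 7.0
        assert design.infill_log == [(0, "lith", "nearest_cell")]

    def test_categorical_infill_takes_nearest_cell(self, flat_spec):
        layer = np.full((6, 6), np.nan)
        layer[2, 3] = 7.0
        stack = PredictorStack({"lith": layer}, {"lith": "categorical"}, flat_spec)
        design = extract_predictors(_table_at([(2.5, 3.5)]), stack)
        assert design.frame["lith"].iloc[0] == 7.0

    def test_infilled_value_within_donor_range(self, flat_spec):
        rng = np.random.default_rng(11)
        for _ in range(20):
            layer = rng.normal(size=(6, 6))
            hide = rng.random((6, 6)) < 0.5
            layer[hide] = np.nan
            layer[2, 2] = np.nan
            if np.isnan(layer).sum() > 31:  # need >= 5 donors
                continue
            stack = PredictorStack({"p": layer.copy()}, {"p": "continuous"}, flat_spec)
            design = extract_predictors(_table_at([(2.5, 3.5)]), stack)
            v = design.frame["p"].iloc[0]
            valid = layer[~np.isnan(layer)]
            assert valid.min() <= v <= valid.max()

    def test_point_outside_extent_raises(self, flat_spec):
        layer = np.zeros((6, 6))
        stack = PredictorStack({"p": layer}, {"p": "continuous"}, flat_spec)
        with pytest.raises(ValueError, match="outside grid extent"):
            extract_predictors(_table_at([(12.0, 3.0)]), stack)

    def test_extraction_deterministic(self, samples, landscape):
        stack, _ = landscape
        a = extract_predictors(samples, stack)
        b = extract_predictors(samples, stack)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.infill_log == b.infill_log


def test_dataset_summary_matches_hand_stats():
    sr = np.array([0.705, 0.710, 0.715, 0.720, 0.725])
    table = SampleTable(pd.DataFrame({"sr_ratio": sr}))
    stats = dataset_summary(table)
    assert stats["n"] == 5
    assert stats["min"] == 0.705 and stats["max"] == 0.725
    assert stats["mean"] == pytest.approx(0.715)
    assert stats["q1"] == pytest.approx(0.710)
    assert stats["q3"] == pytest.approx(0.720)
    assert stats["sd"] == pytest.approx(np.std(sr, ddof=1))
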