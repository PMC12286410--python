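import numpy as np
import pytest
import tifffile

from conftest import make_raster
from reefscale.dem_io import (
    AGRRA_GROUPS,
    CoralPolygonLayer,
    ElevationRaster,
    GroupCodebook,
    RasterFormatError,
    RowSegment,
    count_short_run_cells,
    default_codebook,
    extract_row_segments,
    read_dem,
    read_polygons,
    write_polygons,
    write_raster,
)
from shapely.geometry import Polygon


class TestReadWriteRaster:
    def test_identity_read_back(self, tmp_path):
        r = make_raster([[1.0, 2.0], [3.0, 4.0]])
        path = tmp_path / "tiny.tif"
        write_raster(r, path)
        back = read_dem(path)
        np.testing.assert_array_equal(back.values, r.values)
        assert not back.nodata_mask.any()
        assert back.pixel_size == pytest.approx(0.008)

    def test_round_trip_preserves_georeferencing(self, tmp_path):
        r = make_raster(np.arange(12.0).reshape(3, 4), pixel_size=0.5,
                        origin=(1234.5, 6789.0), crs_id="EPSG:32616")
        path = tmp_path / "geo.tif"
        write_raster(r, path)
        back = read_dem(path)
        assert back.origin == pytest.approx(r.origin)
        assert back.pixel_size == pytest.approx(0.5)
        assert back.crs_id == "EPSG:32616"

    def test_all_nodata(self, tmp_path):
        r = make_raster(np.full((3, 3), np.nan))
        path = tmp_path / "void.tif"
        write_raster(r, path)
        back = read_dem(path)
        assert back.nodata_mask.all()

    def test_single_sentinel_cell(self, tmp_path):
        # write-then-read round trip: sentinel -9999 in exactly one cell
        values = np.ones((4, 4))
        values[2, 1] = -9999.0
        path = tmp_path / "sentinel.tif"
        tifffile.imwrite(
            path, values,
            extratags=[
                (33550, "d", 3, (0.008, 0.008, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
                (42113, "s", 6, "-9999"),
            ],
        )
        back = read_dem(path)
        expected = np.zeros((4, 4), dtype=bool)
        expected[2, 1] = True
        np.testing.assert_array_equal(back.nodata_mask, expected)

    def test_mask_restored_as_sentinel(self, tmp_path):
        mask = np.zeros((2, 3), dtype=bool)
        mask[0, 2] = True
        r = make_raster(np.ones((2, 3)), mask=mask)
        path = tmp_path / "masked.tif"
        write_raster(r, path)
        raw = tifffile.imread(path)
        assert raw[0, 2] == -9999.0
        back = read_dem(path)
        np.testing.assert_array_equal(back.nodata_mask, mask)

    def test_sentinel_collision_rejected(self, tmp_path):
        r = make_raster([[1.0, -9999.0]])
        with pytest.raises(ValueError, match="sentinel"):
            write_raster(r, tmp_path / "clash.tif")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dem(tmp_path / "nope.tif")

    def test_unreadable_format(self, tmp_path):
        bad = tmp_path / "bad.tif"
        bad.write_bytes(b"this is not a tiff at all")
        with pytest.raises((RasterFormatError, Exception)):
            read_dem(bad)

    def test_geographic_crs_rejected(self, tmp_path):
        path = tmp_path / "degrees.tif"
        geodir = (1, 1, 0, 2, 1024, 0, 1, 2, 2048, 0, 1, 4326)
        tifffile.imwrite(
            path, np.ones((2, 2)),
            extratags=[
                (33550, "d", 3, (0.0001, 0.0001, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, -87.0, 20.0, 0.0)),
                (34735, "H", len(geodir), geodir),
            ],
        )
        with pytest.raises(RasterFormatError, match="linear|projected"):
            read_dem(path)

    def test_non_square_pixels_rejected(self, tmp_path):
        path = tmp_path / "rect.tif"
        tifffile.imwrite(
            path, np.ones((2, 2)),
            extratags=[
                (33550, "d", 3, (0.008, 0.010, 0.0)),
                (33922, "d", 6, (0.0,) * 6),
            ],
        )
        with pytest.raises(RasterFormatError, match="non-square"):
            read_dem(path)

    def test_near_square_within_tolerance_ok(self, tmp_path):
        path = tmp_path / "near.tif"
        tifffile.imwrite(
            path, np.ones((2, 2)),
            extratags=[
                (33550, "d", 3, (0.008, 0.008004, 0.0)),
                (33922, "d", 6, (0.0,) * 6),
            ],
        )
        assert read_dem(path).pixel_size == pytest.approx(0.008002)

    def test_complexity_raster_round_trip_geometry(self, tmp_path, small_dem):
        from reefscale import WaveletSpec, decompose_dem, ra_raster

        comps = decompose_dem(small_dem, WaveletSpec(order=1, levels=2))
        ra = ra_raster(comps.local, "DLC")
        path = tmp_path / "dlc.tif"
        write_raster(ra, path)
        back = read_dem(path)
        assert back.grid.same_geometry(small_dem.grid)


class TestElevationRaster:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ElevationRaster(values=np.ones((2, 2)),
                            nodata_mask=np.zeros((3, 2), bool),
                            pixel_size=1.0)

    def test_bad_pixel_size(self):
        with pytest.raises(ValueError, match="pixel_size"):
            ElevationRaster(values=np.ones((2, 2)),
                            nodata_mask=np.zeros((2, 2), bool),
                            pixel_size=0.0)

    def test_non_finite_cells_masked(self):
        r = make_raster([[1.0, np.inf], [np.nan, 4.0]])
        assert r.nodata_mask[0, 1] and r.nodata_mask[1, 0]
        np.testing.assert_array_equal(r.valid_values, [1.0, 4.0])


class TestRowSegments:
    def test_fully_valid_row(self):
        r = make_raster(np.ones((1, 100)))
        segs = extract_row_segments(r, min_length=16)
        assert len(segs) == 1
        assert segs[0].start_col == 0 and len(segs[0]) == 100

    def test_short_run_skipped(self):
        mask = np.ones((1, 100), dtype=bool)
        mask[0, 0:10] = False   # 10-cell run, below min_length
        mask[0, 20:100] = False  # 80-cell run
        r = make_raster(np.ones((1, 100)), mask=mask)
        segs = extract_row_segments(r, min_length=16)
        assert len(segs) == 1
        assert segs[0].start_col == 20 and len(segs[0]) == 80

    def test_all_masked_empty(self):
        r = make_raster(np.ones((3, 8)), mask=np.ones((3, 8), bool))
        assert extract_row_segments(r, min_length=2) == []

    def test_min_length_validation(self, flat_raster):
        with pytest.raises(ValueError, match="min_length"):
            extract_row_segments(flat_raster, min_length=1)

    def test_segments_ordered_and_disjoint(self, rng):
        mask = rng.random((6, 50)) < 0.3
        r = make_raster(rng.normal(size=(6, 50)), mask=mask)
        segs = extract_row_segments(r, min_length=2)
        by_row = {}
        for s in segs:
            by_row.setdefault(s.row_index, []).append(s)
        for row_segs in by_row.values():
            starts = [s.start_col for s in row_segs]
            assert starts == sorted(starts)
            for a, b in zip(row_segs, row_segs[1:]):
                assert a.start_col + len(a) < b.start_col + 1

    def test_row_reconstruction_property(self, rng):
        """Segments plus masked gaps tile each row exactly."""
        mask = rng.random((4, 40)) < 0.4
        values = rng.normal(size=(4, 40))
        r = make_raster(values, mask=mask)
        segs = extract_row_segments(r, min_length=2)
        rebuilt = np.full((4, 40), np.nan)
        for s in segs:
            rebuilt[s.row_index, s.cols] = s.values
        covered = np.isfinite(rebuilt)
        # every covered cell matches, every valid cell in a run >= 2 is covered
        np.testing.assert_array_equal(rebuilt[covered], r.values[covered])
        assert not (covered & r.nodata_mask).any()
        n_short = count_short_run_cells(r, 2)
        assert covered.sum() + n_short == (~r.nodata_mask).sum()

    def test_segment_rejects_nan(self):
        with pytest.raises(ValueError, match="finite"):
            RowSegment(row_index=0, start_col=0, values=[1.0, np.nan])


class TestCodebook:
    def test_default_covers_all_groups(self):
        cb = default_codebook()
        assert cb.groups() == set(AGRRA_GROUPS)

    def test_csv_round_trip(self, tmp_path):
        cb = default_codebook()
        path = tmp_path / "codebook.csv"
        cb.to_csv(path)
        assert path.read_text().splitlines()[0] == \
            "species_code,group_name,raster_code"
        back = GroupCodebook.from_csv(path)
        assert back.mapping == cb.mapping

    def test_duplicate_raster_codes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GroupCodebook(mapping={"A": ("Branching", 1),
                                   "B": ("Meandroid", 1)})

    def test_zero_code_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            GroupCodebook(mapping={"A": ("Branching", 0)})

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            GroupCodebook(mapping={"A": ("Coralline", 1)})


class TestPolygonLayer:
    def test_geojson_round_trip(self, tmp_path):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        layer = CoralPolygonLayer(records=[(square, "AAGA")],
                                  crs_id="EPSG:32616")
        path = tmp_path / "corals.geojson"
        write_polygons(layer, path)
        back = read_polygons(path)
        assert len(back) == 1
        geom, code = back.records[0]
        assert code == "AAGA"
        assert geom.equals(square)
        assert back.crs_id == "EPSG:32616"

    def test_invalid_polygon_repaired(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        layer = CoralPolygonLayer(records=[(bowtie, "PPOR")])
        assert layer.records[0][0].is_valid

    def test_empty_species_code_rejected(self):
        square = Polygon([(0, 0), (1, 0), (1, 1)])
        with pytest.raises(ValueError, match="species_code"):
            CoralPolygonLayer(records=[(square, "")])

    def test_missing_property_raises(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature", '
            '"geometry": {"type": "Point", "coordinates": [0, 0]}, '
            '"properties": {}}]}'
        )
        with pytest.raises(ValueError, match="species_code"):
            read_polygons(path)
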