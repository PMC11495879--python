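"""Raster container, GeoTIFF round-trips and site clipping."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import tifffile

from scrubshift import GridRaster, GridTransform, SitePolygons, clip_to_site
from scrubshift.raster import (
    CRSMismatchError,
    RasterIOError,
    load_site_polygons,
    read_raster,
    write_raster,
)

from conftest import make_height_raster, make_mask


class TestGridRaster:
    def test_cell_area_is_width_times_height(self):
        t = GridTransform(0, 10, 0.05, 0.04)
        assert t.cell_area == 0.05 * 0.04

    @pytest.mark.parametrize("w,h", [(0, 1), (-1, 1), (1, float("inf")), (1, float("nan"))])
    def test_bad_cell_sizes_rejected(self, w, h):
        with pytest.raises(ValueError):
            GridTransform(0, 0, w, h)

    def test_non_finite_non_nodata_cells_rejected(self, unit_transform):
        vals = np.zeros((3, 3))
        vals[1, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            GridRaster(vals, unit_transform)

    def test_nodata_cells_are_counted(self, unit_transform):
        vals = np.zeros((3, 3))
        vals[0, :2] = -9999.0
        r = GridRaster(vals, unit_transform, nodata=-9999.0)
        assert r.n_data == 7

    def test_index_of_inverts_cell_center(self, fine_transform):
        for row, col in [(0, 0), (3, 7), (99, 42)]:
            x, y = fine_transform.cell_center(row, col)
            assert fine_transform.index_of(x, y) == (row, col)


class TestGeoTiffIO:
    def test_height_round_trip_identity(self, tmp_path, fine_transform):
        rng = np.random.default_rng(7)
        r = GridRaster(rng.uniform(0, 6, (10, 10)), fine_transform,
                       crs_tag="EPSG:27700")
        path = tmp_path / "h.tif"
        write_raster(r, path)
        r2 = read_raster(path)
        np.testing.assert_array_equal(r.values, r2.values)
        assert r2.transform == r.transform
        assert r2.crs_tag == "EPSG:27700"

    def test_nodata_tag_propagates(self, tmp_path, unit_transform):
        vals = np.zeros((4, 4))
        vals[[0, 1, 2], [0, 1, 2]] = -9999.0
        r = GridRaster(vals, unit_transform, nodata=-9999.0)
        path = tmp_path / "nd.tif"
        write_raster(r, path)
        r2 = read_raster(path)
        assert r2.nodata == -9999.0
        assert (~r2.data_mask).sum() == 3

    def test_class_codes_stay_integer(self, tmp_path, unit_transform):
        r = GridRaster(np.array([[10, 50], [100, 255]], dtype=np.uint8),
                       unit_transform, nodata=255)
        path = tmp_path / "cls.tif"
        write_raster(r, path)
        r2 = read_raster(path)
        assert np.issubdtype(r2.values.dtype, np.integer)
        assert r2.nodata == 255
        np.testing.assert_array_equal(r.values, r2.values)

    def test_multiband_file_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8),
                         photometric="rgb")
        with pytest.raises(RasterIOError, match="expected single band.*3"):
            read_raster(path)

    def test_missing_file_and_missing_georef(self, tmp_path):
        with pytest.raises(RasterIOError, match="not found"):
            read_raster(tmp_path / "nope.tif")
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((4, 4)))
        with pytest.raises(RasterIOError, match="georeferenced"):
            read_raster(path)


def brute_force_clip_count(raster, site):
    """Oracle: per-cell-centre point-in-polygon test with scalar shapely calls."""
    n = 0
    rows, cols = raster.shape
    for r in range(rows):
        for c in range(cols):
            if not raster.data_mask[r, c]:
                continue
            p = Point(*raster.transform.cell_center(r, c))
            if not site.boundary.covers(p):
                continue
            if any(ex.covers(p) for ex in site.exclusions):
                continue
            n += 1
    return n


class TestClipToSite:
    def test_full_boundary_is_identity(self, unit_transform):
        r = make_height_raster(np.arange(100.0).reshape(10, 10), unit_transform)
        site = SitePolygons(boundary=box(-1, -1, 11, 11))
        clipped = clip_to_site(r, site)
        np.testing.assert_array_equal(clipped.values, r.values)

    def test_left_half_boundary_keeps_50_cells(self, unit_transform):
        r = make_height_raster(np.ones((10, 10)), unit_transform)
        site = SitePolygons(boundary=box(0, 0, 5, 10))  # centres of 5 columns inside
        clipped = clip_to_site(r, site)
        assert clipped.n_data == 50
        assert clipped.n_data == brute_force_clip_count(r, site)

    def test_exclusion_removes_exactly_its_cells(self, unit_transform):
        r = make_height_raster(np.ones((10, 10)), unit_transform)
        site = SitePolygons(boundary=box(0, 0, 10, 10),
                            exclusions=[box(3, 3, 5, 5)])  # 2×2 cells
        clipped = clip_to_site(r, site)
        assert clipped.n_data == 100 - 4
        assert clipped.n_data == brute_force_clip_count(r, site)

    def test_retained_values_unchanged_and_idempotent(self, unit_transform):
        rng = np.random.default_rng(3)
        r = make_height_raster(rng.uniform(0, 8, (10, 10)), unit_transform)
        site = SitePolygons(boundary=Polygon([(0, 0), (10, 0), (10, 10)]),
                            exclusions=[box(6, 1, 8, 3)])
        once = clip_to_site(r, site)
        kept = once.data_mask
        np.testing.assert_array_equal(once.values[kept], r.values[kept])
        twice = clip_to_site(once, site)
        np.testing.assert_array_equal(once.values, twice.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_triangle_matches_brute_force(self, unit_transform, seed):
        rng = np.random.default_rng(seed)
        r = make_height_raster(np.ones((10, 10)), unit_transform)
        pts = rng.uniform(-2, 12, (3, 2))
        tri = Polygon(pts)
        if not tri.is_valid or tri.area == 0:
            pytest.skip("degenerate triangle")
        if not tri.intersects(box(0, 0, 10, 10)):
            pytest.skip("disjoint triangle")
        site = SitePolygons(boundary=tri)
        assert clip_to_site(r, site).n_data == brute_force_clip_count(r, site)

    def test_disjoint_boundary_is_an_error(self, unit_transform):
        r = make_height_raster(np.ones((4, 4)), unit_transform)
        with pytest.raises(ValueError, match="disjoint"):
            clip_to_site(r, SitePolygons(boundary=box(100, 100, 110, 110)))

    def test_crs_mismatch_is_an_error(self, unit_transform):
        r = make_height_raster(np.ones((4, 4)), unit_transform, crs="EPSG:27700")
        site = SitePolygons(boundary=box(0, 0, 4, 4), crs_tag="EPSG:4326")
        with pytest.raises(CRSMismatchError):
            clip_to_site(r, site)

    def test_boundary_touching_centre_counts_as_inside(self):
        # centre of the single cell sits exactly on the polygon edge
        r = make_mask([[1]], GridTransform(0, 1, 1, 1))
        site = SitePolygons(boundary=box(0.5, 0.0, 2.0, 1.0))
        assert clip_to_site(r, site).n_data == 1


class TestSitePolygons:
    def test_invalid_boundary_rejected(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="invalid"):
            SitePolygons(boundary=bowtie)

    def test_disjoint_exclusion_warns(self):
        with pytest.warns(UserWarning, match="does not intersect"):
            SitePolygons(boundary=box(0, 0, 10, 10),
                         exclusions=[box(50, 50, 60, 60)])

    def test_denominator_override_takes_precedence(self):
        site = SitePolygons(boundary=box(0, 0, 10, 10),
                            denominator_area_m2=169270.0)
        assert site.site_area_m2 == 169270.0

    def test_geojson_load(self, tmp_path):
        geojson = """{"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {},
             "geometry": {"type": "Polygon",
                          "coordinates": [[[0,0],[10,0],[10,10],[0,10],[0,0]]]}}]}"""
        p = tmp_path / "boundary.geojson"
        p.write_text(geojson)
        site = load_site_polygons(p)
        assert site.boundary.area == 100.0
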