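"""IDW interpolation, surfaces and ASCII-grid round trips."""

import math

import numpy as np
import pytest

from grainrisk.errors import EmptyGroupError, ParameterError
from grainrisk.spatial_idw import (
    GridSpec,
    IDWInterpolator,
    Surface,
    exceedance_surface,
    idw_predict,
    interpolate_surface,
    read_ascii_grid,
    write_ascii_grid,
)

from conftest import make_record


def haversine_oracle(lon1, lat1, lon2, lat2, radius=6_371_008.8):
    """Independent great-circle distance (law-of-cosines free form)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def records_at(points, values, crop="rice"):
    return [make_record(sample_id=str(i), crop=crop, lon=lo, lat=la, f_mgkg=v)
            for i, ((lo, la), v) in enumerate(zip(points, values))]


class TestIdwPredict:
    def test_single_sample_constant_everywhere(self):
        recs = records_at([(106.0, 26.0)], [3.7])
        for pt in [(104.0, 25.0), (109.0, 29.0), (106.0, 26.0)]:
            assert idw_predict(pt, recs, "F") == pytest.approx(3.7)

    def test_exact_at_sample_location(self):
        recs = records_at([(104.0, 25.0), (108.0, 28.0), (106.0, 26.5)],
                          [1.0, 5.0, 2.5])
        assert idw_predict((108.0, 28.0), recs, "F") == pytest.approx(5.0)

    def test_three_point_brute_force_oracle(self):
        pts = [(104.2, 25.3), (107.8, 28.1), (106.1, 26.4)]
        vals = [1.3, 4.1, 2.2]
        recs = records_at(pts, vals)
        q = (105.5, 27.0)
        w = [haversine_oracle(*q, lon, lat) ** -2.0 for lon, lat in pts]
        expected = sum(wi * vi for wi, vi in zip(w, vals)) / sum(w)
        got = idw_predict(q, recs, "F", power=2.0, k=3)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coincident_ties_average(self):
        recs = records_at([(106.0, 26.0), (106.0, 26.0), (108.0, 28.0)],
                          [1.0, 3.0, 9.0])
        assert idw_predict((106.0, 26.0), recs, "F") == pytest.approx(2.0)

    def test_high_power_converges_to_nearest_neighbour(self):
        pts = [(104.0, 25.0), (107.0, 27.0), (109.0, 29.0)]
        recs = records_at(pts, [1.0, 5.0, 9.0])
        # query much closer to the middle sample
        assert idw_predict((107.1, 27.05), recs, "F", power=20.0) == pytest.approx(
            5.0, abs=1e-6)

    def test_sample_permutation_invariance(self, rng):
        pts = [(float(lo), float(la)) for lo, la in
               zip(rng.uniform(104, 109, 8), rng.uniform(25, 29, 8))]
        vals = list(rng.uniform(0, 5, 8))
        recs = records_at(pts, vals)
        q = (106.3, 26.7)
        base = idw_predict(q, recs, "F", k=5)
        perm = [recs[i] for i in rng.permutation(8)]
        assert idw_predict(q, perm, "F", k=5) == pytest.approx(base, rel=1e-12)

    def test_empty_sample_list_raises(self):
        with pytest.raises(EmptyGroupError):
            idw_predict((106.0, 26.0), [], "F")

    def test_invalid_power_rejected(self):
        recs = records_at([(106.0, 26.0)], [1.0])
        with pytest.raises(ParameterError):
            IDWInterpolator(power=0.0).fit(
                np.array([[106.0, 26.0]]), np.array([1.0]))


class TestSurfaces:
    def spec(self, n_cols=5, n_rows=4):
        return GridSpec.square(104.0, 109.0, 25.0, n_cols=n_cols, n_rows=n_rows)

    def test_constant_field(self):
        recs = records_at([(105.0, 25.5), (108.0, 27.5)], [2.0, 2.0])
        surf = interpolate_surface(recs, "F", self.spec())
        assert np.allclose(surf.values, 2.0)

    def test_convexity_bounds(self, rng):
        pts = list(zip(rng.uniform(104, 109, 10), rng.uniform(25, 28, 10)))
        vals = rng.uniform(1, 7, 10)
        recs = records_at(pts, list(vals))
        surf = interpolate_surface(recs, "F", self.spec(12, 10))
        assert surf.values.min() >= vals.min() - 1e-12
        assert surf.values.max() <= vals.max() + 1e-12

    def test_surface_equals_independent_point_calls(self):
        spec = GridSpec.square(104.0, 108.0, 25.0, n_cols=2, n_rows=2)
        pts = [(104.5, 25.2), (107.5, 27.8), (105.0, 26.9), (106.2, 25.4)]
        recs = records_at(pts, [1.0, 2.0, 3.0, 4.0])
        surf = interpolate_surface(recs, "F", spec, k=4)
        for i, lat in enumerate(spec.lats()):
            for j, lon in enumerate(spec.lons()):
                assert surf.values[i, j] == pytest.approx(
                    idw_predict((lon, lat), recs, "F", k=4), rel=1e-12)

    def test_exceedance_indicator(self):
        spec = self.spec(3, 3)
        vals = np.array([[0.1, 0.5, np.nan], [0.2, 0.05, 0.3], [0.01, 0.21, 0.2]])
        surf = Surface(spec=spec, values=vals)
        ind = exceedance_surface(surf, 0.2)
        expected = np.array([[0, 1, np.nan], [0, 0, 1], [0, 1, 0]], dtype=float)
        assert np.array_equal(ind.values, expected, equal_nan=True)

    def test_exceedance_all_below(self):
        surf = Surface(spec=self.spec(3, 3), values=np.full((3, 3), 0.05))
        assert not exceedance_surface(surf, 0.2).values.any()

    def test_negative_limit_marks_everything(self):
        surf = Surface(spec=self.spec(3, 3), values=np.full((3, 3), 0.05))
        assert exceedance_surface(surf, -1.0).values.all()


class TestAsciiGrid:
    def test_round_trip_3x3(self, tmp_path):
        spec = GridSpec.square(104.0, 106.0, 25.0, n_cols=3, n_rows=3)
        vals = np.array([[1.234567, 2.0, 3.5], [4.25, 5.0, 6.125],
                         [7.0, 8.875, 9.0]])
        surf = Surface(spec=spec, values=vals, element="Cd")
        path = tmp_path / "g.asc"
        write_ascii_grid(surf, path)
        back = read_ascii_grid(path)
        assert np.allclose(back.values, vals, rtol=5e-6)  # 6 significant digits
        assert back.spec.n_cols == 3 and back.spec.n_rows == 3
        assert back.spec.lon_min == pytest.approx(104.0)
        assert back.spec.lat_max == pytest.approx(27.0)

    def test_header_field_order(self, tmp_path):
        spec = GridSpec.square(104.0, 106.0, 25.0, n_cols=3, n_rows=3)
        surf = Surface(spec=spec, values=np.zeros((3, 3)))
        path = tmp_path / "g.asc"
        write_ascii_grid(surf, path)
        keys = [line.split()[0] for line in path.read_text().splitlines()[:6]]
        assert keys == ["ncols", "nrows", "xllcorner", "yllcorner",
                        "cellsize", "NODATA_value"]

    def test_cellsize_consistent_with_bounds(self, tmp_path):
        spec = GridSpec.square(104.0, 109.0, 25.0, n_cols=11, n_rows=6)
        surf = Surface(spec=spec, values=np.zeros((6, 11)))
        path = tmp_path / "g.asc"
        write_ascii_grid(surf, path)
        header = dict(line.split() for line in path.read_text().splitlines()[:6])
        cellsize = float(header["cellsize"])
        assert cellsize == pytest.approx((109.0 - 104.0) / 10)
        back = read_ascii_grid(path)
        assert back.spec.dlon == pytest.approx(back.spec.dlat)

    def test_nodata_round_trip(self, tmp_path):
        spec = GridSpec.square(104.0, 106.0, 25.0, n_cols=3, n_rows=2)
        vals = np.array([[1.0, np.nan, 3.0], [4.0, 5.0, np.nan]])
        surf = Surface(spec=spec, values=vals)
        path = tmp_path / "g.asc"
        write_ascii_grid(surf, path)
        back = read_ascii_grid(path)
        assert np.array_equal(back.values, vals, equal_nan=True)

    def test_non_square_cells_rejected(self, tmp_path):
        spec = GridSpec(lon_min=104, lon_max=109, lat_min=25, lat_max=26,
                        n_cols=6, n_rows=6)
        surf = Surface(spec=spec, values=np.zeros((6, 6)))
        with pytest.raises(ParameterError):
            write_ascii_grid(surf, tmp_path / "g.asc")


class TestGridSpec:
    def test_square_adjusts_lat_extent(self):
        spec = GridSpec.square(103.5, 109.5, 24.5, n_cols=200, n_rows=150)
        assert spec.dlon == pytest.approx(spec.dlat)
        assert spec.lat_max == pytest.approx(24.5 + spec.dlon * 149)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ParameterError):
            GridSpec(lon_min=104, lon_max=104, lat_min=25, lat_max=26,
                     n_cols=3, n_rows=3)
        with pytest.raises(ParameterError):
            GridSpec(lon_min=104, lon_max=105, lat_min=25, lat_max=26,
                     n_cols=1, n_rows=3)
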