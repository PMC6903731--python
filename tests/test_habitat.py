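"""Covariate extraction, isocline polygons, habitat-area index tests."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.integrate import quad

from pengwinter.habitat import (AlongTrackMatch, along_track_match,
                                cell_mean_covariate, extract_isocline_polygons,
                                geo_area_km2, habitat_area,
                                habitat_area_raster, ice_residence_fraction)
from pengwinter.hud import HUD, HexGrid
from pengwinter.projection import R_EARTH, laea_forward
from pengwinter.synthetic import (SimulationConfig, generate_env_grids,
                                  ice_edge_lat, sic_isocline_lat)


def grid_da(values, lats, lons):
    return xr.DataArray(values, dims=("lat", "lon"),
                        coords={"lat": lats, "lon": lons})


def hud_with_cells(grid, cells, month="2017-07"):
    rows = [{"month": pd.Period(month, "M"), "q": q, "r": r,
             "deployment_id": "a", "colony": "C", "stage": "adult",
             "n_positions": 1} for q, r in cells]
    return HUD(grid=grid, table=pd.DataFrame(rows))


class TestCellMeanCovariate:
    def test_constant_field(self):
        lats = np.arange(-74.75, -50.0, 0.5)
        lons = np.arange(-179.75, 0.0, 0.5)
        da = grid_da(np.full((lats.size, lons.size), 3.14), lats, lons)
        grid = HexGrid(25.0)
        # occupied cells near the colonies
        x, y = laea_forward(np.array([-60.0, -61.0]), np.array([-62.0, -63.0]))
        cells = list(zip(*grid.point_to_cell(x, y)))
        hud = hud_with_cells(grid, cells)
        out = cell_mean_covariate(hud, pd.Period("2017-07", "M"), da)
        # constant field: exact whether a cell averages interior grid
        # centers or falls back to the nearest center
        assert np.allclose(out["value"], 3.14)
        assert (out["flag"] != "all missing").all()

    def test_linear_field_close_to_centroid_value(self, config, env):
        sst = env.monthly["sst"].sel(month=7)
        grid = HexGrid(25.0)
        x, y = laea_forward(np.array([-100.0]), np.array([-60.0]))
        q, r = grid.point_to_cell(x, y)
        hud = hud_with_cells(grid, [(int(q[0]), int(r[0]))])
        out = cell_mean_covariate(hud, pd.Period("2017-07", "M"), sst)
        from pengwinter.projection import laea_inverse
        cx, cy = grid.centroid(int(q[0]), int(r[0]))
        clon, clat = laea_inverse(cx, cy)
        expected = float(sst.sel(lon=clon, lat=clat, method="nearest"))
        # within one grid-cell gradient step of the centroid value
        step = config.sst_slope * config.grid_res * 2
        assert abs(out["value"].iloc[0] - expected) <= step

    def test_tiny_hexagon_triggers_nearest_fallback(self):
        lats = np.arange(-74.5, -50.0, 1.0)     # ~111 km spacing
        lons = np.arange(-179.5, 0.0, 1.0)
        da = grid_da(np.broadcast_to(lats[:, None] * 1.0,
                                     (lats.size, lons.size)).copy(),
                     lats, lons)
        grid = HexGrid(5.0)                      # hexes ~ 21 km^2 << cell
        # choose a hex cell well away from any grid center
        x, y = laea_forward(np.array([-100.35]), np.array([-60.37]))
        q, r = grid.point_to_cell(x, y)
        hud = hud_with_cells(grid, [(int(q[0]), int(r[0]))])
        out = cell_mean_covariate(hud, pd.Period("2017-07", "M"), da)
        row = out.iloc[0]
        if row["flag"]:                          # fallback expected path
            assert row["flag"] == "nearest-center fallback"
        assert np.isfinite(row["value"])


class TestAlongTrackMatch:
    def test_fix_at_grid_center_exact(self, env):
        t = env.sic_daily["time"].values[100]
        lat = float(env.sic_daily["lat"].values[10])
        lon = float(env.sic_daily["lon"].values[20])
        fixes = pd.DataFrame({"timestamp": [pd.Timestamp(t) + pd.Timedelta(hours=13)],
                              "lon": [lon], "lat": [lat]})
        m = along_track_match(fixes, env.sic_daily)
        assert m.table["sic"].iloc[0] == pytest.approx(
            float(env.sic_daily.sel(time=t, lat=lat, lon=lon)))
        assert m.table["flag"].iloc[0] == ""

    def test_poleward_of_half_cover_isocline_matches_high_sic(self, config,
                                                              env):
        """Fixes 2 degrees poleward of the 50% isocline must match SIC
        above 50% even with the daily AR(1) perturbation."""
        day = pd.Timestamp("2017-07-15T13:00")
        lons = np.array([-150.0, -100.0, -50.0])
        lats = ice_edge_lat(lons, 7, config) - 2.0
        fixes = pd.DataFrame({"timestamp": [day] * 3, "lon": lons,
                              "lat": lats})
        m = along_track_match(fixes, env.sic_daily)
        assert (m.table["sic"] > 50.0).all()

    def test_missing_day_flagged(self, env):
        fixes = pd.DataFrame({"timestamp": [pd.Timestamp("2018-01-01T13:00")],
                              "lon": [-60.0], "lat": [-62.0]})
        m = along_track_match(fixes, env.sic_daily)
        assert m.table["flag"].iloc[0] == "missing day"
        assert np.isnan(m.table["sic"].iloc[0])


class TestIceResidence:
    def _match(self, sics):
        times = pd.date_range("2017-07-01", periods=len(sics), freq="2h")
        return AlongTrackMatch(table=pd.DataFrame(
            {"time": times, "lon": -100.0, "lat": -60.0, "sst": 0.0,
             "sic": sics, "flag": ""}))

    def test_no_ice(self):
        frac, mean_sic = ice_residence_fraction(self._match([0.0] * 50))
        assert frac == 0.0 and np.isnan(mean_sic)

    def test_all_ice(self):
        frac, mean_sic = ice_residence_fraction(self._match([40.0] * 50))
        assert frac == 1.0 and mean_sic == pytest.approx(40.0)

    def test_one_of_hundred_intervals(self):
        sics = [0.0] * 101
        sics[10] = 37.2
        frac, mean_sic = ice_residence_fraction(self._match(sics))
        assert frac == pytest.approx(0.01)
        assert mean_sic == pytest.approx(37.2)


class TestIsoclinePolygons:
    def test_latitude_field_contour(self):
        lats = np.arange(-74.75, -50.0, 0.5)
        lons = np.arange(-179.75, 0.0, 0.5)
        da = grid_da(np.broadcast_to(lats[:, None],
                                     (lats.size, lons.size)).copy(),
                     lats, lons)
        region = extract_isocline_polygons(da, -60.0, side="<=")
        # boundary along -60: region spans lat_min..-60 over all lon
        assert region.bounds[3] == pytest.approx(-60.0, abs=0.5)
        expected = (R_EARTH ** 2 * np.radians(180.0)
                    * (np.sin(np.radians(-60.0)) - np.sin(np.radians(-75.0))))
        assert geo_area_km2(region) == pytest.approx(expected, rel=0.02)

    def test_constant_field_full_or_empty(self):
        lats = np.arange(-74.5, -50.0, 1.0)
        lons = np.arange(-179.5, 0.0, 1.0)
        da = grid_da(np.full((lats.size, lons.size), 10.0), lats, lons)
        full = extract_isocline_polygons(da, 5.0, side=">=")
        empty = extract_isocline_polygons(da, 5.0, side="<=")
        assert empty.is_empty
        domain_area = geo_area_km2(full)
        expected = (R_EARTH ** 2 * np.radians(180.0)
                    * (np.sin(np.radians(-50.0)) - np.sin(np.radians(-75.0))))
        assert domain_area == pytest.approx(expected, rel=1e-3)

    def test_level_outside_range_empty(self):
        lats = np.arange(-74.5, -50.0, 1.0)
        lons = np.arange(-179.5, 0.0, 1.0)
        da = grid_da(np.full((lats.size, lons.size), 10.0), lats, lons)
        assert extract_isocline_polygons(da, 200.0, side=">=").is_empty

    def test_ice_band_area_matches_analytic_integral(self, config, env):
        """Area of {SIC >= 50%} vs the closed-form integral of the
        logistic band south of the rippled edge, within 2%."""
        region = extract_isocline_polygons(env.monthly["sic"].sel(month=7),
                                           50.0, side=">=")
        lat_min = config.grid_lat[0]

        def band_height(lon):
            edge = float(ice_edge_lat(lon, 7, config))
            return np.sin(np.radians(edge)) - np.sin(np.radians(lat_min))

        integral, _ = quad(band_height, config.grid_lon[0],
                           config.grid_lon[1], limit=200)
        expected = R_EARTH ** 2 * np.radians(1.0) * integral
        assert geo_area_km2(region) == pytest.approx(expected, rel=0.02)


class TestHabitatArea:
    def test_ice_free_warm_free_ocean(self):
        lats = np.arange(-74.75, -50.0, 0.5)
        lons = np.arange(-179.75, 0.0, 0.5)
        shape = (lats.size, lons.size)
        sst = grid_da(np.zeros(shape), lats, lons)
        sic = grid_da(np.zeros(shape), lats, lons)
        idx = habitat_area(sst, sic, None, month=7)
        expected = (R_EARTH ** 2 * np.radians(180.0)
                    * (np.sin(np.radians(-50.0)) - np.sin(np.radians(-75.0))))
        assert idx.open_water_km2 == pytest.approx(expected, rel=1e-3)
        assert idx.miz_km2 == 0.0

    def test_all_land_zero(self, env):
        from shapely.geometry import box
        everything = box(-181.0, -76.0, 1.0, -49.0)
        idx = habitat_area(env.monthly["sst"].sel(month=7),
                           env.monthly["sic"].sel(month=7), everything, 7)
        assert idx.open_water_km2 == 0.0 and idx.miz_km2 == 0.0

    def test_polygon_vs_raster_oracle_and_disjointness(self, config, env):
        """July polygon areas agree with the rasterized cell-count within
        2%, and the open-water / MIZ regions never intersect."""
        sst = env.monthly["sst"].sel(month=7)
        sic = env.monthly["sic"].sel(month=7)
        poly = habitat_area(sst, sic, env.land_mask, 7)
        rast = habitat_area_raster(sst, sic, env.land_mask, 7)
        assert poly.open_water_km2 == pytest.approx(rast.open_water_km2,
                                                    rel=0.02)
        assert poly.miz_km2 == pytest.approx(rast.miz_km2, rel=0.02)
        # disjoint by construction: SIC < 5 vs SIC >= 5
        ow = extract_isocline_polygons(sic, config.sic_daily_sd * 0 + 5.0,
                                       side="<=")
        miz = extract_isocline_polygons(sic, 5.0, side=">=")
        inter = ow.intersection(miz)
        assert geo_area_km2(inter) < 1e-6 * poly.open_water_km2

    def test_open_water_monotone_in_isotherm_position(self, env):
        """Warming the SST field pulls the 2 degC isotherm poleward and can
        only shrink the open-water belt; cooling can only grow it."""
        sst = env.monthly["sst"].sel(month=7)
        sic = env.monthly["sic"].sel(month=7)
        base = habitat_area(sst, sic, env.land_mask, 7)
        warmer = habitat_area(sst + 1.0, sic, env.land_mask, 7)
        colder = habitat_area(sst - 1.0, sic, env.land_mask, 7)
        assert warmer.open_water_km2 <= base.open_water_km2 * (1 + 1e-9)
        assert colder.open_water_km2 >= base.open_water_km2 * (1 - 1e-9)

    def test_agreement_tightens_with_resolution(self):
        """Polygon/raster mismatch at 1 degree resolution shrinks when the
        grid is refined to 0.5 degrees."""
        errs = {}
        for res in (1.0, 0.5):
            cfg = SimulationConfig(seed=7)
            cfg.grid_res = res
            env = generate_env_grids(cfg)
            sst = env.monthly["sst"].sel(month=7)
            sic = env.monthly["sic"].sel(month=7)
            poly = habitat_area(sst, sic, env.land_mask, 7)
            rast = habitat_area_raster(sst, sic, env.land_mask, 7)
            errs[res] = (abs(poly.open_water_km2 / rast.open_water_km2 - 1)
                         + abs(poly.miz_km2 / rast.miz_km2 - 1))
        assert errs[0.5] < errs[1.0] + 0.01
        assert errs[0.5] < 0.04
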