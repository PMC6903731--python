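"""Environmental covariate extraction and the 2-part habitat-area index.

Covariates (SST, SIC, depth, zonal current) are summarized two ways:

* per HUD hexagon — the mean of the gridded values whose cell centers
  fall inside the hexagon (nearest-center fallback when a hexagon is
  smaller than the grid resolution);
* along-track — each raw fix matched to the nearest grid cell of the
  same UTC day, from which the ice-residence fraction (time associated
  with fixes whose matched SIC exceeds a threshold, default 5%) is
  computed.

Habitat availability per month, 180°W-0°W, is a 2-part index: open-water
area between the 5% SIC isocline and the 2°C isotherm (SST <= 2°C and
SIC < 5%), and the marginal ice zone (5% <= SIC <= 50%), both clipped by
the land mask.  Isoclines come from marching squares and are converted
to polygons; areas are evaluated in the equal-area working plane.  A
rasterized cell-count computation of the same areas is provided as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import GeometryCollection, MultiPolygon, Polygon, box
from shapely.ops import transform, unary_union
from skimage import measure

from .hud import HUD, HexGrid
from .projection import R_EARTH, laea_forward

_SIDES = {">=", "<=", ">", "<"}


@dataclass
class HabitatAreaIndex:
    month: int
    open_water_km2: float
    miz_km2: float


@dataclass
class AlongTrackMatch:
    """Per-fix daily environmental matches; ``flag`` marks missing days."""

    table: pd.DataFrame            # time, lon, lat, sst, sic, flag


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------

def cell_mean_covariate(hud: HUD, month, grid: xr.DataArray) -> pd.DataFrame:
    """Mean gridded value per occupied hexagon for one month.

    Grid-cell centers are assigned to hexagons by the same
    nearest-centroid rule the HUD uses; hexagons containing no grid
    center fall back to the value at the nearest center and are flagged.
    NaN grid values are excluded from means.
    """
    cells = hud.cells_for_month(month)[["q", "r"]].drop_duplicates()
    lats = grid["lat"].values
    lons = grid["lon"].values
    lon2, lat2 = np.meshgrid(lons, lats)
    gx, gy = laea_forward(lon2.ravel(), lat2.ravel())
    gq, gr = hud.grid.point_to_cell(gx, gy)
    vals = grid.values.ravel()

    frame = pd.DataFrame({"q": gq, "r": gr, "value": vals})
    means = frame.groupby(["q", "r"], observed=True)["value"].mean()

    rows = []
    for q, r in cells.itertuples(index=False):
        key = (q, r)
        if key in means.index and np.isfinite(means.loc[key]):
            rows.append({"q": q, "r": r, "value": float(means.loc[key]),
                         "flag": ""})
        else:
            cx, cy = hud.grid.centroid(q, r)
            d2 = (gx - cx) ** 2 + (gy - cy) ** 2
            order = np.argsort(d2)
            val = np.nan
            for j in order:
                if np.isfinite(vals[j]):
                    val = float(vals[j])
                    break
            flag = "nearest-center fallback" if np.isfinite(val) else "all missing"
            rows.append({"q": q, "r": r, "value": val, "flag": flag})
    return pd.DataFrame(rows)


def along_track_match(fixes: pd.DataFrame, sic_daily: xr.DataArray,
                      sst: Optional[xr.DataArray] = None) -> AlongTrackMatch:
    """Match raw fixes to same-UTC-day nearest-grid-cell SIC (and SST).

    ``sst`` may be daily (``time`` dim) or monthly (``month`` dim, the
    month's composite standing in for each day); a missing grid day is
    flagged, never interpolated.
    """
    times = pd.DatetimeIndex(fixes["timestamp"])
    days = times.normalize()
    rows = []
    avail_days = pd.DatetimeIndex(sic_daily["time"].values).normalize()
    for i in range(len(fixes)):
        lon = float(fixes["lon"].iloc[i])
        lat = float(fixes["lat"].iloc[i])
        flag = ""
        if days[i] in avail_days:
            sic_val = float(sic_daily.sel(time=days[i])
                            .sel(lon=lon, lat=lat, method="nearest"))
        else:
            sic_val, flag = np.nan, "missing day"
        sst_val = np.nan
        if sst is not None:
            if "time" in sst.dims:
                sst_days = pd.DatetimeIndex(sst["time"].values).normalize()
                if days[i] in sst_days:
                    sst_val = float(sst.sel(time=days[i])
                                    .sel(lon=lon, lat=lat, method="nearest"))
                else:
                    flag = (flag + ";" if flag else "") + "missing sst day"
            elif "month" in sst.dims and times[i].month in sst["month"].values:
                sst_val = float(sst.sel(month=times[i].month)
                                .sel(lon=lon, lat=lat, method="nearest"))
        rows.append({"time": times[i], "lon": lon, "lat": lat,
                     "sst": sst_val, "sic": sic_val, "flag": flag})
    return AlongTrackMatch(table=pd.DataFrame(rows))


def ice_residence_fraction(match: AlongTrackMatch,
                           ice_threshold: float = 5.0
                           ) -> Tuple[float, float]:
    """Fraction of tracked time in ice (matched SIC >= threshold).

    Each fix owns the interval to the next fix; returns (fraction,
    mean matched SIC over the in-ice fixes).
    """
    tab = match.table
    if len(tab) == 0:
        raise ValueError("no matched fixes")
    if len(tab) == 1:
        in_ice = tab["sic"].iloc[0] >= ice_threshold
        return (1.0 if in_ice else 0.0,
                float(tab["sic"].iloc[0]) if in_ice else float("nan"))
    t = pd.DatetimeIndex(tab["time"]).asi8 / 1e9
    dt = np.diff(t)
    sic = tab["sic"].to_numpy(dtype=float)[:-1]
    valid = np.isfinite(sic)
    total = dt[valid].sum()
    if total == 0:
        return 0.0, float("nan")
    in_ice = valid & (sic >= ice_threshold)
    frac = dt[in_ice].sum() / total
    all_sic = tab["sic"].to_numpy(dtype=float)
    ice_vals = all_sic[np.isfinite(all_sic) & (all_sic >= ice_threshold)]
    mean_ice = float(ice_vals.mean()) if ice_vals.size else float("nan")
    return float(frac), mean_ice


# ---------------------------------------------------------------------------
# Isocline polygons and habitat area
# ---------------------------------------------------------------------------

def _outer_box(da: xr.DataArray) -> Tuple[float, float, float, float]:
    lons = da["lon"].values
    lats = da["lat"].values
    dlon = lons[1] - lons[0]
    dlat = lats[1] - lats[0]
    return (lons[0] - dlon / 2.0, lats[0] - dlat / 2.0,
            lons[-1] + dlon / 2.0, lats[-1] + dlat / 2.0)


def extract_isocline_polygons(da: xr.DataArray, level: float,
                              side: str = ">="):
    """Region polygon(s) of {field `side` level} via marching squares.

    The 2-D field (dims lat, lon) is padded with an outside value at the
    domain's outer edges so every contour closes; each closed contour is
    classified by sampling the field at an interior point, and the region
    is the union of positive loops minus the union of negative loops
    (two-level nesting).  Returns a shapely geometry in lon/lat.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    if da.dims != ("lat", "lon"):
        da = da.transpose("lat", "lon")
    vals = da.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("grid must be at least 2x2")
    lats = da["lat"].values
    lons = da["lon"].values
    lo_lon, lo_lat, hi_lon, hi_lat = _outer_box(da)
    domain = box(lo_lon, lo_lat, hi_lon, hi_lat)

    wants_high = side in (">=", ">")
    # pad just past the level so contours of regions touching the domain
    # boundary close (numerically) on the outer edge itself
    eps = 1e-9 * (abs(level) + np.nanmax(np.abs(vals)) + 1.0)
    pad_val = level - eps if wants_high else level + eps
    padded = np.pad(vals, 1, constant_values=pad_val)
    lat_ext = np.concatenate([[lo_lat], lats, [hi_lat]])
    lon_ext = np.concatenate([[lo_lon], lons, [hi_lon]])

    contours = measure.find_contours(padded, level)
    if not contours:
        # constant field relative to the level: all or nothing
        center = vals[vals.shape[0] // 2, vals.shape[1] // 2]
        inside = center >= level if wants_high else center <= level
        return domain if inside else Polygon()

    interp = RegularGridInterpolator((lats, lons), vals, bounds_error=False,
                                     fill_value=None)
    positive, negative = [], []
    for c in contours:
        lat_c = np.interp(c[:, 0], np.arange(lat_ext.size), lat_ext)
        lon_c = np.interp(c[:, 1], np.arange(lon_ext.size), lon_ext)
        if len(lat_c) < 4:
            continue
        poly = Polygon(np.column_stack([lon_c, lat_c]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area == 0:
            continue
        rp = poly.representative_point()
        v = float(interp((rp.y, rp.x)))
        inside = v >= level if wants_high else v <= level
        (positive if inside else negative).append(poly)

    region = unary_union(positive) if positive else Polygon()
    if negative:
        region = region.difference(unary_union(negative))
    return region.intersection(domain)


def geo_area_km2(geom, max_segment_deg: float = 0.25) -> float:
    """Area (km^2) of a lon/lat geometry, evaluated in the equal-area
    plane after densifying edges so projected edges track great-ellipse
    curvature."""
    if geom.is_empty:
        return 0.0
    geom = shapely.segmentize(geom, max_segment_deg)

    def _proj(lon, lat):
        return laea_forward(np.asarray(lon), np.asarray(lat))

    return float(transform(_proj, geom).area)


def habitat_area(sst: xr.DataArray, sic: xr.DataArray,
                 land_mask, month: int,
                 lon_window: Tuple[float, float] = (-180.0, 0.0),
                 sst_max: float = 2.0, sic_open: float = 5.0,
                 sic_miz_hi: float = 50.0) -> HabitatAreaIndex:
    """Polygon-differenced 2-part habitat index for one month.

    open water = {SST <= sst_max} ∩ {SIC < sic_open} ∩ window − land;
    MIZ = {sic_open <= SIC <= sic_miz_hi} ∩ window − land.  The SST
    bound is inclusive and the open-water SIC bound exclusive so the two
    parts partition cleanly at the 5% isocline.
    """
    cold = extract_isocline_polygons(sst, sst_max, side="<=")
    ice_free = extract_isocline_polygons(sic, sic_open, side="<=")
    icy = extract_isocline_polygons(sic, sic_open, side=">=")
    not_packed = extract_isocline_polygons(sic, sic_miz_hi, side="<=")

    lo_lon, lo_lat, hi_lon, hi_lat = _outer_box(sic)
    window = box(max(lon_window[0], lo_lon), lo_lat,
                 min(lon_window[1], hi_lon), hi_lat)

    open_water = cold.intersection(ice_free).intersection(window)
    miz = icy.intersection(not_packed).intersection(window)
    if land_mask is not None and not land_mask.is_empty:
        open_water = open_water.difference(land_mask)
        miz = miz.difference(land_mask)
    return HabitatAreaIndex(month=month,
                            open_water_km2=geo_area_km2(open_water),
                            miz_km2=geo_area_km2(miz))


def habitat_area_raster(sst: xr.DataArray, sic: xr.DataArray,
                        land_mask, month: int,
                        lon_window: Tuple[float, float] = (-180.0, 0.0),
                        sst_max: float = 2.0, sic_open: float = 5.0,
                        sic_miz_hi: float = 50.0) -> HabitatAreaIndex:
    """Cell-count version of :func:`habitat_area` (independent check).

    Sums exact spherical cell areas over grid cells whose centers
    satisfy the same inequalities, are inside the longitude window, and
    are not on land.
    """
    lats = sic["lat"].values
    lons = sic["lon"].values
    dlat = lats[1] - lats[0]
    dlon = lons[1] - lons[0]
    band = (R_EARTH ** 2 * np.radians(dlon)
            * (np.sin(np.radians(lats + dlat / 2.0))
               - np.sin(np.radians(lats - dlat / 2.0))))
    area2d = np.broadcast_to(band[:, None], (lats.size, lons.size))

    lon2, lat2 = np.meshgrid(lons, lats)
    in_window = (lon2 >= lon_window[0]) & (lon2 <= lon_window[1])
    if land_mask is not None and not land_mask.is_empty:
        on_land = shapely.contains_xy(land_mask, lon2.ravel(), lat2.ravel())
        on_land = on_land.reshape(lon2.shape)
    else:
        on_land = np.zeros_like(in_window, dtype=bool)

    sst_v = sst.transpose("lat", "lon").values
    sic_v = sic.transpose("lat", "lon").values
    ow = (sst_v <= sst_max) & (sic_v < sic_open) & in_window & ~on_land
    miz = (sic_v >= sic_open) & (sic_v <= sic_miz_hi) & in_window & ~on_land
    return HabitatAreaIndex(month=month,
                            open_water_km2=float(area2d[ow].sum()),
                            miz_km2=float(area2d[miz].sum()))


def monthly_habitat_table(env, lon_window: Tuple[float, float] = (-180.0, 0.0),
                          sst_max: float = 2.0, sic_open: float = 5.0,
                          sic_miz_hi: float = 50.0) -> pd.DataFrame:
    """Open-water and MIZ areas for every month of an EnvGridSet."""
    rows = []
    for m in env.monthly["month"].values:
        idx = habitat_area(env.monthly["sst"].sel(month=m),
                           env.monthly["sic"].sel(month=m),
                           env.land_mask, int(m), lon_window=lon_window,
                           sst_max=sst_max, sic_open=sic_open,
                           sic_miz_hi=sic_miz_hi)
        rows.append({"month": int(m), "open_water_km2": idx.open_water_km2,
                     "miz_km2": idx.miz_km2})
    return pd.DataFrame(rows)
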