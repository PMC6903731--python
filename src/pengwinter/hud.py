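"""Hexagonal habitat-utilization distributions (HUDs) and overlap indices.

Imputed 2-h positions, pooled across all draws of every deployment, are
binned into a flat-top hexagonal tessellation of the equal-area working
plane with centroids spaced 25 km apart (cell area = sqrt(3)/2 * 25^2
= 541.266 km^2).  A month's HUD is, per cell, the set of distinct
individuals with at least one imputed position in the cell during that
calendar month (UTC); multiple draws of the same bird never count as
co-occurrence.

Overlap follows the occupancy definition: the area where at least two
individuals (inter-colony: individuals from at least two distinct
colonies) co-occur, relative to the total occupied area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .ctcrw import ImputedTrackSet

SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class HexGrid:
    """Flat-top axial hex tessellation anchored at the projection origin.

    ``spacing`` is the distance between adjacent cell centroids (km);
    the hexagon circumradius is spacing / sqrt(3).
    """

    spacing: float = 25.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def circumradius(self) -> float:
        return self.spacing / SQRT3

    @property
    def cell_area(self) -> float:
        """Planar cell area, km^2: (sqrt(3)/2) * spacing^2."""
        return (SQRT3 / 2.0) * self.spacing ** 2

    def centroid(self, q, r) -> Tuple[np.ndarray, np.ndarray]:
        """Centroid (x, y) km of axial cell(s) (q, r)."""
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        rh = self.circumradius
        return 1.5 * rh * q, SQRT3 * rh * (r + q / 2.0)

    def point_to_cell(self, x, y) -> Tuple[np.ndarray, np.ndarray]:
        """Nearest-centroid cell assignment via axial cube rounding.

        Deterministic on boundaries (cube rounding breaks ties by the
        largest rounding residual, a fixed lexicographic-like rule).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rh = self.circumradius
        qf = (2.0 / 3.0) * x / rh
        rf = (-x / 3.0 + SQRT3 / 3.0 * y) / rh
        sf = -qf - rf
        q = np.round(qf)
        r = np.round(rf)
        s = np.round(sf)
        dq = np.abs(q - qf)
        dr = np.abs(r - rf)
        ds = np.abs(s - sf)
        fix_q = (dq > dr) & (dq > ds)
        fix_r = (~fix_q) & (dr > ds)
        q = np.where(fix_q, -r - s, q)
        r = np.where(fix_r, -q - s, r)
        return q.astype(np.int64), r.astype(np.int64)

    def cell_polygon(self, q: int, r: int) -> Polygon:
        """Hexagon polygon of one cell in the working plane (km)."""
        cx, cy = self.centroid(q, r)
        ang = np.radians(np.arange(0, 360, 60))
        rh = self.circumradius
        return Polygon(np.column_stack([cx + rh * np.cos(ang),
                                        cy + rh * np.sin(ang)]))


@dataclass
class HUD:
    """Monthly cell occupancy: one row per (month, cell, individual).

    ``table`` columns: month (pandas Period[M]), q, r, deployment_id,
    colony, stage, n_positions (visit weight over all pooled draws).
    """

    grid: HexGrid
    table: pd.DataFrame

    def months(self) -> List[pd.Period]:
        return sorted(self.table["month"].unique())

    def cells_for_month(self, month) -> pd.DataFrame:
        return self.table[self.table["month"] == month]


@dataclass
class OverlapIndex:
    month: object
    scope: str                     # "inter" | "intra:<colony>"
    overlap_area_km2: float
    total_area_km2: float
    n_overlap_cells: int = 0
    n_total_cells: int = 0
    flag: str = ""

    @property
    def ratio(self) -> float:
        """Overlap as a fraction of the total occupied area; computed on
        cell counts (exact) since every cell has the same area."""
        if self.n_total_cells == 0:
            return 0.0
        return self.n_overlap_cells / self.n_total_cells

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def build_hexgrid(spacing: float = 25.0) -> HexGrid:
    return HexGrid(spacing=spacing)


def assign_cells(imputed: Sequence[ImputedTrackSet], grid: HexGrid,
                 deployment_meta: Dict[str, Dict[str, str]]) -> HUD:
    """Pool imputed draws into monthly per-individual cell occupancy.

    ``deployment_meta`` maps deployment_id -> {"colony": ..., "stage": ...}.
    Each 2-h draw position lands in exactly one (month, cell); presence
    sets deduplicate draws while ``n_positions`` keeps the visit weight.
    """
    frames = []
    for trk in imputed:
        n_draws, n_t = trk.x.shape
        months = pd.DatetimeIndex(trk.times).to_period("M")
        q, r = grid.point_to_cell(trk.x.ravel(), trk.y.ravel())
        df = pd.DataFrame({
            "month": np.tile(months, n_draws),
            "q": q, "r": r,
        })
        agg = df.groupby(["month", "q", "r"], observed=True).size()
        agg = agg.rename("n_positions").reset_index()
        meta = deployment_meta.get(trk.deployment_id, {})
        agg["deployment_id"] = trk.deployment_id
        agg["colony"] = meta.get("colony", "")
        agg["stage"] = meta.get("stage", "")
        frames.append(agg)
    if not frames:
        table = pd.DataFrame(columns=["month", "q", "r", "deployment_id",
                                      "colony", "stage", "n_positions"])
    else:
        table = pd.concat(frames, ignore_index=True)
    return HUD(grid=grid, table=table)


def intercolony_overlap(hud: HUD, month) -> OverlapIndex:
    """Cells holding individuals from >= 2 distinct colonies, as an area
    fraction of all occupied cells that month (all colonies pooled)."""
    sub = hud.cells_for_month(month)
    if sub.empty:
        return OverlapIndex(month, "inter", 0.0, 0.0, flag="month absent")
    per_cell = sub.groupby(["q", "r"], observed=True)["colony"].nunique()
    area = hud.grid.cell_area
    n_total = len(per_cell)
    n_overlap = int((per_cell >= 2).sum())
    flag = "" if sub["colony"].nunique() >= 2 else "single colony"
    return OverlapIndex(month, "inter", n_overlap * area, n_total * area,
                        n_overlap_cells=n_overlap, n_total_cells=n_total,
                        flag=flag)


def intracolony_overlap(hud: HUD, colony: str, month) -> OverlapIndex:
    """Cells with >= 2 distinct individuals of one colony, relative to
    that colony's occupied area for the month."""
    sub = hud.cells_for_month(month)
    sub = sub[sub["colony"] == colony]
    scope = f"intra:{colony}"
    if sub.empty:
        return OverlapIndex(month, scope, 0.0, 0.0, flag="colony absent")
    per_cell = sub.groupby(["q", "r"], observed=True)["deployment_id"].nunique()
    area = hud.grid.cell_area
    n_total = len(per_cell)
    n_overlap = int((per_cell >= 2).sum())
    flag = "" if sub["deployment_id"].nunique() >= 2 else "single individual"
    return OverlapIndex(month, scope, n_overlap * area, n_total * area,
                        n_overlap_cells=n_overlap, n_total_cells=n_total,
                        flag=flag)


def overlap_table(hud: HUD) -> pd.DataFrame:
    """Monthly inter- and intra-colony overlap percentages (long form)."""
    rows = []
    for month in hud.months():
        inter = intercolony_overlap(hud, month)
        rows.append({"month": str(month), "scope": inter.scope,
                     "overlap_km2": inter.overlap_area_km2,
                     "total_km2": inter.total_area_km2,
                     "percent": inter.percent, "flag": inter.flag})
        for colony in sorted(hud.cells_for_month(month)["colony"].unique()):
            intra = intracolony_overlap(hud, colony, month)
            rows.append({"month": str(month), "scope": intra.scope,
                         "overlap_km2": intra.overlap_area_km2,
                         "total_km2": intra.total_area_km2,
                         "percent": intra.percent, "flag": intra.flag})
    return pd.DataFrame(rows)


def hud_to_csv(hud: HUD, path) -> None:
    out = hud.table.copy()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)


def hud_to_geojson(hud: HUD, path) -> None:
    """Write occupied cells as GeoJSON polygons (lon/lat) with month,
    per-cell individual/colony counts and visit weights."""
    import json

    from .projection import laea_inverse

    features = []
    for month in hud.months():
        cells = hud_cell_polygons(hud, month)
        for row in cells.itertuples(index=False):
            xs, ys = row.polygon.exterior.xy
            lon, lat = laea_inverse(np.asarray(xs), np.asarray(ys))
            features.append({
                "type": "Feature",
                "properties": {"month": str(month), "q": int(row.q),
                               "r": int(row.r),
                               "n_individuals": int(row.n_individuals),
                               "n_colonies": int(row.n_colonies),
                               "visits": int(row.visits)},
                "geometry": {"type": "Polygon",
                             "coordinates": [np.column_stack([lon, lat]).tolist()]},
            })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def hud_cell_polygons(hud: HUD, month) -> pd.DataFrame:
    """Cell polygons (working plane) with per-cell occupancy counts."""
    sub = hud.cells_for_month(month)
    rows = []
    for (q, r), grp in sub.groupby(["q", "r"], observed=True):
        rows.append({"q": q, "r": r,
                     "polygon": hud.grid.cell_polygon(int(q), int(r)),
                     "n_individuals": grp["deployment_id"].nunique(),
                     "n_colonies": grp["colony"].nunique(),
                     "visits": grp["n_positions"].sum()})
    return pd.DataFrame(rows)
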