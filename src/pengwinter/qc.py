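"""Quality control of raw Argos fixes.

Three filters, applied per deployment in order:

1. quality screening — drop every class-Z fix and every fix whose error
   ellipse is unspecified (missing or zero semi-major axis);
2. a speed filter — walking forward from the release location (which is
   always trusted), drop any fix whose implied great-circle speed from
   the last retained fix exceeds a conservative sustained swim speed
   (default 2.5 m/s, inclusive threshold);
3. minimum-duration retention — keep only deployments whose filtered
   fixes span at least 7 days (first fix to last fix).

A :class:`QcReport` records per-deployment removal counts by filter so
retention accounting is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .projection import haversine_km, normalize_lon
from .synthetic import Deployment, FIX_COLUMNS

VALID_CLASSES = {"3", "2", "1", "0", "A", "B", "Z"}

REQUIRED_COLUMNS = ["deployment_id", "timestamp", "lon", "lat", "lc_class"]


@dataclass
class QcReport:
    """Per-deployment bookkeeping of the QC cascade."""

    per_deployment: pd.DataFrame = field(default_factory=pd.DataFrame)
    rejected_rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def retained_ids(self) -> List[str]:
        if self.per_deployment.empty:
            return []
        kept = self.per_deployment[self.per_deployment["retained"]]
        return list(kept["deployment_id"])

    def removal_fraction(self, deployments: Sequence[Deployment],
                         stage: str) -> float:
        """Fraction of a stage's deployments removed by the duration filter."""
        ids = {d.deployment_id for d in deployments if d.stage == stage}
        sub = self.per_deployment[self.per_deployment["deployment_id"].isin(ids)]
        if sub.empty:
            return float("nan")
        return 1.0 - sub["retained"].mean()

    def to_csv(self, path) -> None:
        self.per_deployment.to_csv(path, index=False)


def read_argos_csv(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a raw fix table; returns (fixes, rejected_rows).

    Rows with unparseable timestamps or coordinates are reported in the
    second frame rather than silently dropped.  Longitudes are wrapped
    into (-180, 180]; output is time-sorted within each deployment.
    """
    raw = pd.read_csv(path, dtype={"deployment_id": str, "lc_class": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"fix table missing required columns: {missing}")
    for col in ("ellipse_semi_major_m", "ellipse_semi_minor_m",
                "ellipse_orientation_deg"):
        if col not in raw.columns:
            raw[col] = np.nan

    times = pd.to_datetime(raw["timestamp"], errors="coerce", utc=False,
                           format="ISO8601")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    bad = times.isna() | lon.isna() | lat.isna() | (lat.abs() > 90.0)
    rejected = raw[bad].copy()
    if len(rejected):
        rejected["reject_reason"] = "unparseable time/coordinates"

    fixes = raw[~bad].copy()
    fixes["timestamp"] = times[~bad]
    fixes["lon"] = normalize_lon(lon[~bad].to_numpy())
    fixes["lat"] = lat[~bad].to_numpy()
    fixes = fixes.sort_values(["deployment_id", "timestamp"],
                              kind="stable").reset_index(drop=True)
    return fixes[FIX_COLUMNS], rejected


def ellipse_unspecified(fixes: pd.DataFrame) -> pd.Series:
    """Predicate for the 'unspecified ellipse error' screen.

    A fix fails if its semi-major axis is missing or non-positive.
    """
    sm = pd.to_numeric(fixes["ellipse_semi_major_m"], errors="coerce")
    return sm.isna() | (sm <= 0.0)


def filter_quality(fixes: pd.DataFrame) -> pd.DataFrame:
    """Remove class-Z fixes and fixes with unspecified error ellipses."""
    keep = (fixes["lc_class"] != "Z") & ~ellipse_unspecified(fixes)
    return fixes[keep.to_numpy()].reset_index(drop=True)


def speed_filter(fixes: pd.DataFrame, vmax_ms: float = 2.5,
                 anchor: Optional[Tuple[float, float, pd.Timestamp]] = None
                 ) -> pd.DataFrame:
    """Recursive forward speed filter (inclusive threshold).

    ``anchor`` is (lon, lat, time) of the trusted release; walking
    forward in time, a fix is dropped when the great-circle speed from
    the last retained fix (starting at the anchor) exceeds ``vmax_ms``.
    Duplicate timestamps with distinct positions keep only the first.
    Assumes a single deployment's fixes, already time-sorted.
    """
    if fixes.empty:
        return fixes.reset_index(drop=True)
    times = pd.DatetimeIndex(fixes["timestamp"]).asi8 / 1e9
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    vmax_kmps = vmax_ms / 1000.0

    if anchor is not None:
        last_lon, last_lat = float(anchor[0]), float(anchor[1])
        last_t = pd.Timestamp(anchor[2]).value / 1e9
    else:
        last_lon, last_lat, last_t = lon[0], lat[0], times[0]

    keep = np.zeros(len(fixes), dtype=bool)
    start = 0
    if anchor is None:
        keep[0] = True
        start = 1
    for i in range(start, len(fixes)):
        dt = times[i] - last_t
        if dt < 0:
            continue
        if dt == 0:
            # duplicate timestamp: the first occurrence was retained, the
            # rest are dropped whether or not their positions agree
            continue
        dist = float(haversine_km(last_lon, last_lat, lon[i], lat[i]))
        if dist / dt <= vmax_kmps:        # inclusive boundary
            keep[i] = True
            last_lon, last_lat, last_t = lon[i], lat[i], times[i]
    return fixes[keep].reset_index(drop=True)


def retain_min_duration(fixes_by_dep: Dict[str, pd.DataFrame],
                        deployments: Sequence[Deployment],
                        min_days: float = 7.0) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Keep deployments whose filtered fixes span >= ``min_days`` days.

    Returns (retained fixes by deployment, per-deployment summary frame
    with duration and retention flag plus stage/colony for reporting).
    """
    meta = {d.deployment_id: d for d in deployments}
    rows = []
    retained: Dict[str, pd.DataFrame] = {}
    for dep_id, fx in fixes_by_dep.items():
        if len(fx) >= 2:
            span = (fx["timestamp"].iloc[-1] - fx["timestamp"].iloc[0]
                    ).total_seconds() / 86400.0
        else:
            span = 0.0
        keep = span >= min_days
        d = meta.get(dep_id)
        rows.append({"deployment_id": dep_id,
                     "colony": d.colony if d else "",
                     "stage": d.stage if d else "",
                     "duration_days": span,
                     "retained": keep})
        if keep:
            retained[dep_id] = fx
    return retained, pd.DataFrame(rows)


def run_qc(fixes: pd.DataFrame, deployments: Sequence[Deployment],
           vmax_ms: float = 2.5, min_days: float = 7.0
           ) -> Tuple[Dict[str, pd.DataFrame], QcReport]:
    """Full QC cascade for a multi-deployment fix table.

    Returns retained fixes grouped by deployment plus a report whose
    per-filter removal counts sum to (raw - retained) for every
    deployment.
    """
    meta = {d.deployment_id: d for d in deployments}
    by_dep: Dict[str, pd.DataFrame] = {}
    counts = []
    for dep_id, group in fixes.groupby("deployment_id", sort=True):
        group = group.sort_values("timestamp", kind="stable").reset_index(drop=True)
        n_raw = len(group)
        q = filter_quality(group)
        n_quality = n_raw - len(q)
        d = meta.get(dep_id)
        anchor = ((d.colony_lon, d.colony_lat, d.release_time)
                  if d is not None else None)
        s = speed_filter(q, vmax_ms=vmax_ms, anchor=anchor)
        n_speed = len(q) - len(s)
        by_dep[dep_id] = s
        counts.append({"deployment_id": dep_id, "n_raw": n_raw,
                       "removed_quality": n_quality, "removed_speed": n_speed,
                       "n_filtered": len(s)})
    # deployments with zero fixes still appear in the accounting
    for dep_id in meta:
        if dep_id not in by_dep:
            by_dep[dep_id] = fixes.iloc[0:0]
            counts.append({"deployment_id": dep_id, "n_raw": 0,
                           "removed_quality": 0, "removed_speed": 0,
                           "n_filtered": 0})

    retained, durations = retain_min_duration(by_dep, deployments,
                                              min_days=min_days)
    per_dep = pd.DataFrame(counts).merge(durations, on="deployment_id")
    report = QcReport(per_deployment=per_dep.sort_values("deployment_id")
                      .reset_index(drop=True))
    return retained, report
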