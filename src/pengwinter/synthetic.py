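"""Synthetic deployments, tracks, Argos fixes, and environmental grids.

Everything downstream of this module (quality control, state-space
smoothing, utilization distributions, habitat metrics) is exercised on
data produced here, so the generator encodes the study conditions
explicitly:

* three Antarctic Peninsula colonies with tag releases in late
  February / early March;
* duty-cycled Argos transmission (six hours daily, 12:00-18:00 UTC) with
  a mean of ~6 location estimates per window for adults and ~3.4 for
  juveniles, each fix carrying a location class with class-dependent
  isotropic Gaussian error;
* three movement behaviors — ``local`` (mean-reverting around the
  colony), ``east`` and ``west`` (zonal drift tracking a synthetic
  circumpolar front) — all driven by a continuous-time correlated
  random walk (CTCRW) velocity process;
* analytic environmental fields (SST, sea-ice concentration, bathymetry,
  zonal current) whose closed forms are recorded so tests can invert
  isoclines exactly.

Every output is a deterministic function of the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr
from scipy.linalg import expm
from shapely.geometry import MultiPolygon, Polygon, mapping

from .projection import (
    aeqd_forward,
    aeqd_inverse,
    laea_forward,
    normalize_lon,
)

KM_PER_DEG = np.pi * 6371.0 / 180.0  # spherical km per degree of arc

#: Tagging colonies (name -> (lon, lat), degrees east/north).
DEFAULT_COLONIES: Dict[str, Tuple[float, float]] = {
    "Admiralty Bay": (-58.469, -62.236),
    "Cape Shirreff": (-60.789, -62.46),
    "Cierva Cove": (-60.984, -64.143),
}

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

FIX_COLUMNS = [
    "deployment_id",
    "timestamp",
    "lon",
    "lat",
    "lc_class",
    "ellipse_semi_major_m",
    "ellipse_semi_minor_m",
    "ellipse_orientation_deg",
]


def child_seed(seed: int, key: str) -> int:
    """Stable per-deployment seed below 2**31, order-independent."""
    return (int(seed) * 1000003 ^ zlib.crc32(key.encode())) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Movement parameters are in km and days: ``beta`` is the velocity
    autocorrelation rate (1/day), ``sigma`` the velocity volatility
    (km/day^1.5), ``attraction`` the restoring rate of local birds toward
    their colony (1/day), and ``drift_speed`` the zonal migration speed
    (km/day) of east/west migrants along the synthetic front.
    """

    colony_locations: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COLONIES))
    stage_mix: Dict[str, float] = field(
        default_factory=lambda: {"adult": 0.8, "juvenile": 0.2})
    behavior_mix: Dict[str, float] = field(
        default_factory=lambda: {"local": 0.6, "east": 0.1, "west": 0.3})
    release_window: Tuple[str, str] = ("2017-02-18", "2017-03-09")
    # lognormal (mean of log-days, sd of log-days) per stage
    track_length_days: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"adult": (4.2, 0.7), "juvenile": (2.6, 0.5)})
    ctcrw_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"local": (1.0, 30.0),
                                 "east": (1.0, 30.0),
                                 "west": (1.0, 30.0)})
    attraction: float = 0.05              # 1/day, local behavior only
    drift_speed: float = 40.0             # km/day along the front
    front_latitudes: Dict[str, float] = field(
        default_factory=lambda: {"PF": -58.0, "SACCF": -62.0})
    front_attraction: float = 0.02        # 1/day pull of migrants toward SACCF
    argos_class_probs: Dict[str, float] = field(
        default_factory=lambda: {"3": 0.08, "2": 0.12, "1": 0.18,
                                 "0": 0.17, "A": 0.15, "B": 0.25, "Z": 0.05})
    argos_class_sd: Dict[str, float] = field(
        default_factory=lambda: {"3": 0.25, "2": 0.5, "1": 1.5,
                                 "0": 5.0, "A": 5.0, "B": 10.0})  # km
    z_corruption_km: float = 1000.0
    missing_ellipse_frac: float = 0.02
    duty_cycle: Tuple[float, float] = (12.0, 18.0)     # UTC hours
    fixes_per_window: Dict[str, float] = field(
        default_factory=lambda: {"adult": 6.0, "juvenile": 3.4})
    step_hours: float = 2.0
    seed: int = 0

    # --- environmental-field parameters (analytic forms; see env docstrings)
    grid_lon: Tuple[float, float] = (-180.0, 0.0)
    grid_lat: Tuple[float, float] = (-75.0, -50.0)
    grid_res: float = 0.5                 # degrees
    months: Tuple[int, ...] = tuple(range(2, 11))      # Feb..Oct 2017
    year: int = 2017
    sst_south: float = -1.8               # °C at the southern grid edge
    sst_slope: float = 0.21               # °C per degree latitude northward
    sst_season_amp: float = 0.8           # °C, warmest in February
    sst_ripple_amp: float = 0.3           # °C, longitudinal frontal meander
    sst_ripple_waves: int = 2
    ice_edge_march: float = -70.0         # 50% SIC isocline latitude, March
    ice_edge_september: float = -60.0     # after its northward advance
    ice_edge_width: float = 1.5           # logistic width, degrees latitude
    ice_ripple_amp: float = 1.0           # degrees, longitudinal ripple
    ice_ripple_waves: int = 3
    sic_daily_sd: float = 3.0             # % field-wide AR(1) perturbation
    sic_daily_rho: float = 0.8
    shelf_lat: float = -62.5
    shelf_width: float = 2.0
    shelf_depth: float = -500.0
    basin_depth: float = -4000.0
    current_background: float = 0.02      # m/s eastward
    current_jet: float = 0.12
    current_jet_lat: float = -58.0
    current_jet_width: float = 3.0

    def validate(self) -> None:
        for name, probs in (("behavior_mix", self.behavior_mix),
                            ("argos_class_probs", self.argos_class_probs),
                            ("stage_mix", self.stage_mix)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probabilities")
        if any(sd < 0 for sd in self.argos_class_sd.values()):
            raise ValueError("argos_class_sd values must be >= 0")
        for beh, (beta, sigma) in self.ctcrw_params.items():
            if beta <= 0 or sigma < 0:
                raise ValueError(f"ctcrw_params[{beh}] must have beta>0, sigma>=0")
        lo, hi = self.duty_cycle
        if not 0 <= lo < hi <= 24:
            raise ValueError("duty_cycle must be an increasing window within a UTC day")
        lon0, lon1 = self.grid_lon
        lat0, lat1 = self.grid_lat
        for _, (clon, clat) in self.colony_locations.items():
            if not (lon0 <= clon <= lon1 and lat0 <= clat <= lat1):
                raise ValueError("environmental grid extent does not cover all colonies")


@dataclass
class Deployment:
    """Tag-release metadata for one bird."""

    deployment_id: str
    colony: str
    colony_lon: float
    colony_lat: float
    stage: str                      # adult | juvenile
    release_time: pd.Timestamp
    tag_model: str = "synthetic-tag"

    def as_row(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        d["release_time"] = pd.Timestamp(self.release_time).isoformat()
        return d


@dataclass
class TrueTrack:
    """Ground-truth trajectory on the 2-h clock (for recovery tests)."""

    deployment_id: str
    times: np.ndarray               # datetime64[ns], strictly increasing
    lon: np.ndarray
    lat: np.ndarray
    vx: np.ndarray                  # km/day, local east component
    vy: np.ndarray                  # km/day, local north component
    behavior: str

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty track")
        dt = np.diff(self.times.astype("datetime64[ns]").astype(np.int64))
        if np.any(dt <= 0):
            raise ValueError("track times must be strictly increasing")
        if not (np.all(np.isfinite(self.lon)) and np.all(np.isfinite(self.lat))):
            raise ValueError("track positions must be finite")

    @property
    def xy(self) -> Tuple[np.ndarray, np.ndarray]:
        """Positions in the equal-area working plane (km)."""
        return laea_forward(self.lon, self.lat)


# ---------------------------------------------------------------------------
# Analytic environmental fields
# ---------------------------------------------------------------------------

def sst_analytic(lat, lon, month, config: SimulationConfig):
    """SST (°C): linear in latitude (warmer north) with a seasonal cosine
    offset (warmest in February) and a small longitudinal frontal meander."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    offset = config.sst_season_amp * np.cos(2 * np.pi * (month - 2) / 12.0)
    meander = config.sst_ripple_amp * np.sin(
        2 * np.pi * config.sst_ripple_waves * (lon + 180.0) / 360.0)
    return (config.sst_south + config.sst_slope * (lat - config.grid_lat[0])
            + offset + meander)


def sst_isotherm_lat(temp_c: float, lon, month: int,
                     config: SimulationConfig):
    """Closed-form latitude of an SST isotherm (field linear in latitude)."""
    lon = np.asarray(lon, dtype=float)
    offset = config.sst_season_amp * np.cos(2 * np.pi * (month - 2) / 12.0)
    meander = config.sst_ripple_amp * np.sin(
        2 * np.pi * config.sst_ripple_waves * (lon + 180.0) / 360.0)
    return (config.grid_lat[0]
            + (temp_c - offset - meander - config.sst_south) / config.sst_slope)


def ice_edge_lat(lon, month, config: SimulationConfig):
    """Latitude of the 50% SIC isocline: advances north March->September,
    with a small longitudinal sinusoidal ripple."""
    lon = np.asarray(lon, dtype=float)
    frac = np.clip((month - 3) / 6.0, 0.0, 1.0)
    base = config.ice_edge_march + frac * (config.ice_edge_september - config.ice_edge_march)
    ripple = config.ice_ripple_amp * np.sin(
        2 * np.pi * config.ice_ripple_waves * (lon + 180.0) / 360.0)
    return base + ripple


def sic_analytic(lat, lon, month, config: SimulationConfig):
    """SIC (%): logistic front in latitude around the moving ice edge."""
    lat = np.asarray(lat, dtype=float)
    edge = ice_edge_lat(lon, month, config)
    return 100.0 / (1.0 + np.exp((lat - edge) / config.ice_edge_width))


def sic_isocline_lat(level: float, lon, month, config: SimulationConfig):
    """Closed-form inverse of the logistic SIC field at a given level (%)."""
    if not 0.0 < level < 100.0:
        raise ValueError("SIC isocline level must be in (0, 100)")
    edge = ice_edge_lat(lon, month, config)
    return edge + config.ice_edge_width * np.log(100.0 / level - 1.0)


def depth_analytic(lat, config: SimulationConfig):
    """Bathymetry (m, negative): Gaussian shelf band over a deep basin."""
    lat = np.asarray(lat, dtype=float)
    bump = np.exp(-(((lat - config.shelf_lat) / config.shelf_width) ** 2))
    return config.basin_depth + (config.shelf_depth - config.basin_depth) * bump


def u_current_analytic(lat, config: SimulationConfig):
    """Zonal surface current (m/s, eastward positive): background + jet."""
    lat = np.asarray(lat, dtype=float)
    jet = np.exp(-(((lat - config.current_jet_lat) / config.current_jet_width) ** 2))
    return config.current_background + config.current_jet * jet


def default_land_mask(config: SimulationConfig) -> MultiPolygon:
    """Synthetic peninsula-shaped land polygon south of the colonies."""
    peninsula = Polygon([(-64.0, -75.0), (-56.0, -75.0),
                         (-58.0, -64.8), (-62.0, -64.8)])
    island = Polygon([(-61.3, -62.7), (-60.3, -62.7),
                      (-60.3, -62.2), (-61.3, -62.2)])
    return MultiPolygon([peninsula, island])


@dataclass
class EnvGridSet:
    """Monthly environmental fields plus daily SIC and a land mask.

    ``monthly`` is an :class:`xarray.Dataset` with dims (month, lat, lon)
    holding sst (°C), sic (%), and static depth (m) / u_current (m/s)
    broadcast per month; ``sic_daily`` has dims (time, lat, lon) on a
    daily clock.  The analytic parameters are serialized into ``attrs``
    so isocline positions can be recomputed exactly.
    """

    monthly: xr.Dataset
    sic_daily: xr.DataArray
    land_mask: MultiPolygon
    config: SimulationConfig

    def land_mask_geojson(self) -> str:
        return json.dumps({
            "type": "FeatureCollection",
            "features": [{"type": "Feature", "properties": {"name": "land"},
                          "geometry": mapping(self.land_mask)}],
        })

    def to_netcdf(self, directory) -> None:
        """Write monthly fields, daily SIC, and the land mask to a
        directory (classic NetCDF via the scipy engine + GeoJSON)."""
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.monthly.to_netcdf(d / "env_monthly.nc", engine="scipy")
        self.sic_daily.to_dataset(name="sic").to_netcdf(
            d / "sic_daily.nc", engine="scipy",
            encoding={"time": {"units": "days since 1970-01-01",
                               "dtype": "float64"}})
        (d / "land_mask.geojson").write_text(self.land_mask_geojson())


def read_env_grids(directory, config: Optional[SimulationConfig] = None
                   ) -> EnvGridSet:
    """Read an :meth:`EnvGridSet.to_netcdf` bundle back from disk."""
    from pathlib import Path

    from shapely.geometry import shape
    d = Path(directory)
    monthly = xr.load_dataset(d / "env_monthly.nc", engine="scipy")
    sic_daily = xr.load_dataset(d / "sic_daily.nc", engine="scipy")["sic"]
    gj = json.loads((d / "land_mask.geojson").read_text())
    geom = shape(gj["features"][0]["geometry"])
    if geom.geom_type == "Polygon":
        geom = MultiPolygon([geom])
    return EnvGridSet(monthly=monthly, sic_daily=sic_daily, land_mask=geom,
                      config=config or SimulationConfig())


def generate_env_grids(config: SimulationConfig) -> EnvGridSet:
    """Build the analytic monthly grids and the daily SIC stack.

    Grid cells are centred half a step inside the configured extent so
    cell edges tile the window exactly.
    """
    config.validate()
    res = config.grid_res
    lon0, lon1 = config.grid_lon
    lat0, lat1 = config.grid_lat
    lons = np.arange(lon0 + res / 2.0, lon1, res)
    lats = np.arange(lat0 + res / 2.0, lat1, res)
    months = np.asarray(config.months)

    lat2d = lats[:, None]
    lon2d = lons[None, :]
    sst = np.stack([sst_analytic(lat2d, lon2d, m, config) for m in months])
    sic = np.stack([sic_analytic(lat2d, lon2d, m, config) for m in months])
    depth = np.broadcast_to(depth_analytic(lat2d, config) + 0.0 * lon2d,
                            (lats.size, lons.size))
    ucur = np.broadcast_to(u_current_analytic(lat2d, config) + 0.0 * lon2d,
                           (lats.size, lons.size))

    monthly = xr.Dataset(
        {
            "sst": (("month", "lat", "lon"), sst, {"units": "degC"}),
            "sic": (("month", "lat", "lon"), sic, {"units": "%"}),
            "depth": (("lat", "lon"), np.asarray(depth), {"units": "m"}),
            "u_current": (("lat", "lon"), np.asarray(ucur), {"units": "m/s"}),
        },
        coords={"month": months, "lat": lats, "lon": lons},
        attrs={"analytic_params": json.dumps({
            "sst_south": config.sst_south, "sst_slope": config.sst_slope,
            "sst_season_amp": config.sst_season_amp,
            "ice_edge_march": config.ice_edge_march,
            "ice_edge_september": config.ice_edge_september,
            "ice_edge_width": config.ice_edge_width,
            "ice_ripple_amp": config.ice_ripple_amp,
            "ice_ripple_waves": config.ice_ripple_waves,
        })},
    )

    # daily SIC: monthly field + field-wide AR(1) offset, clipped to [0, 100]
    rng = np.random.default_rng(child_seed(config.seed, "env-daily-sic"))
    start = pd.Timestamp(f"{config.year}-{months[0]:02d}-01")
    end = (pd.Timestamp(f"{config.year}-{months[-1]:02d}-01")
           + pd.offsets.MonthEnd(0))
    days = pd.date_range(start, end, freq="D")
    rho, sd = config.sic_daily_rho, config.sic_daily_sd
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), size=len(days))
    ar = np.empty(len(days))
    ar[0] = rng.normal(0.0, sd)
    for i in range(1, len(days)):
        ar[i] = rho * ar[i - 1] + eps[i]
    month_index = {m: i for i, m in enumerate(months)}
    daily = np.empty((len(days), lats.size, lons.size))
    for i, day in enumerate(days):
        base = sic[month_index[day.month]]
        daily[i] = np.clip(base + ar[i], 0.0, 100.0)
    sic_daily = xr.DataArray(
        daily, dims=("time", "lat", "lon"),
        coords={"time": days, "lat": lats, "lon": lons},
        name="sic", attrs={"units": "%", "ar1_sd": sd, "ar1_rho": rho})

    return EnvGridSet(monthly=monthly, sic_daily=sic_daily,
                      land_mask=default_land_mask(config), config=config)


# ---------------------------------------------------------------------------
# True-track simulation
# ---------------------------------------------------------------------------

def ctcrw_transition(beta: float, sigma: float, dt):
    """Exact CTCRW discretization over interval(s) ``dt`` (days).

    Per axis, state (position p, velocity v):
    v' = e^(-beta dt) v + N(0, qvv); p' = p + v (1-e^(-beta dt))/beta + noise,
    with qpp, qpv, qvv the stationary-form integrals of the OU velocity.
    Returns (e, phi, qpp, qpv, qvv) broadcast over ``dt``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    dt = np.asarray(dt, dtype=float)
    u = beta * dt
    one_m_e = -np.expm1(-u)              # 1 - e^(-u), cancellation-free
    one_m_e2 = -np.expm1(-2.0 * u)       # 1 - e^(-2u)
    e = 1.0 - one_m_e
    phi = one_m_e / beta
    s2 = float(sigma) ** 2
    qvv = s2 * one_m_e2 / (2.0 * beta)
    qpv = s2 * one_m_e ** 2 / (2.0 * beta ** 2)
    # f(u) = u - 2(1-e^-u) + (1-e^-2u)/2 = u^3/3 - u^4/4 + 7u^5/60 - ...;
    # the direct form cancels catastrophically for small u
    f_direct = u - 2.0 * one_m_e + 0.5 * one_m_e2
    f_series = u ** 3 * (1.0 / 3.0 - u / 4.0 + 7.0 * u ** 2 / 60.0)
    f = np.where(u < 1e-3, f_series, f_direct)
    qpp = (s2 / beta ** 3) * np.maximum(f, 0.0)
    return e, phi, qpp, qpv, qvv


def ou_attracted_discretization(beta: float, sigma: float, gamma: float,
                                dt: float):
    """Exact one-step (M, Q) for the colony-attracted linear SDE.

    d[p, v] = A [p, v] dt + [0, sigma] dW with A = [[-gamma, 1], [0, -beta]].
    Uses the Van Loan matrix-exponential construction; for gamma = 0 this
    reproduces the plain CTCRW transition.
    """
    A = np.array([[-gamma, 1.0], [0.0, -beta]])
    Qc = np.array([[0.0, 0.0], [0.0, sigma ** 2]])
    H = np.zeros((4, 4))
    H[:2, :2] = A
    H[:2, 2:] = Qc
    H[2:, 2:] = -A.T
    G = expm(H * dt)
    M = G[:2, :2]
    Q = G[:2, 2:] @ M.T
    Q = 0.5 * (Q + Q.T)
    return M, Q


def stationary_position_sd(beta: float, sigma: float, gamma: float) -> float:
    """Closed-form stationary sd (km) of position for the attracted SDE."""
    return sigma / np.sqrt(2.0 * beta * gamma * (beta + gamma))


def _sample_mvn2(rng: np.random.Generator, Q: np.ndarray, n: int) -> np.ndarray:
    """n draws from N(0, Q) for a 2x2 PSD Q (Cholesky with zero guard)."""
    w = np.linalg.eigvalsh(Q)
    if w[-1] <= 0:
        return np.zeros((n, 2))
    jitter = max(w[-1] * 1e-12, 1e-300)
    L = np.linalg.cholesky(Q + jitter * np.eye(2))
    return rng.standard_normal((n, 2)) @ L.T


def simulate_true_track(deployment: Deployment, behavior: str,
                        config: SimulationConfig,
                        duration_days: float,
                        seed: Optional[int] = None) -> TrueTrack:
    """Simulate one ground-truth trajectory on the 2-h clock.

    ``local`` birds follow the colony-attracted SDE, simulated exactly in
    the azimuthal-equidistant tangent plane at the colony (so the process
    is the stated linear SDE with no map distortion).  ``east``/``west``
    migrants integrate CTCRW velocities in local east/north steps with a
    constant zonal drift of the configured sign plus a weak meridional
    pull toward the synthetic SACCF front latitude.
    """
    if behavior not in ("local", "east", "west"):
        raise ValueError(f"unknown behavior {behavior!r}")
    beta, sigma = config.ctcrw_params[behavior]
    if beta <= 0 or sigma < 0:
        raise ValueError("beta must be > 0 and sigma >= 0")
    if seed is None:
        seed = child_seed(config.seed, f"track:{deployment.deployment_id}")
    rng = np.random.default_rng(seed)

    dt = config.step_hours / 24.0
    n_steps = max(1, int(round(duration_days / dt)))
    times = (pd.Timestamp(deployment.release_time)
             + pd.to_timedelta(np.arange(n_steps + 1) * config.step_hours,
                               unit="h")).values

    if behavior == "local":
        M, Q = ou_attracted_discretization(beta, sigma, config.attraction, dt)
        noise = _sample_mvn2(rng, Q, 2 * n_steps)
        state = np.zeros((2, 2))            # columns: (p, v) for x and y axes
        xs = np.zeros(n_steps + 1)
        ys = np.zeros(n_steps + 1)
        vxs = np.zeros(n_steps + 1)
        vys = np.zeros(n_steps + 1)
        for k in range(n_steps):
            state[0] = M @ state[0] + noise[2 * k]
            state[1] = M @ state[1] + noise[2 * k + 1]
            xs[k + 1], vxs[k + 1] = state[0]
            ys[k + 1], vys[k + 1] = state[1]
        lon, lat = aeqd_inverse(xs, ys, deployment.colony_lon,
                                deployment.colony_lat)
        return TrueTrack(deployment.deployment_id, times, np.asarray(lon),
                         np.asarray(lat), vxs, vys, behavior)

    # migrants: local east/north stepping with zonal drift along the front
    e, phi, qpp, qpv, qvv = ctcrw_transition(beta, sigma, dt)
    Qstep = np.array([[qpp, qpv], [qpv, qvv]])
    noise = _sample_mvn2(rng, Qstep, 2 * n_steps)
    drift = config.drift_speed * (1.0 if behavior == "east" else -1.0)
    front_lat = config.front_latitudes.get("SACCF", -62.0)
    lon = np.empty(n_steps + 1)
    lat = np.empty(n_steps + 1)
    vxs = np.zeros(n_steps + 1)
    vys = np.zeros(n_steps + 1)
    lon[0], lat[0] = deployment.colony_lon, deployment.colony_lat
    vx = vy = 0.0
    for k in range(n_steps):
        de = phi * vx + noise[2 * k, 0] + drift * dt
        dn = (phi * vy + noise[2 * k + 1, 0]
              - config.front_attraction * (lat[k] - front_lat) * KM_PER_DEG * dt)
        vx = e * vx + noise[2 * k, 1]
        vy = e * vy + noise[2 * k + 1, 1]
        lat[k + 1] = np.clip(lat[k] + dn / KM_PER_DEG, -89.5, 89.5)
        lon[k + 1] = lon[k] + de / (KM_PER_DEG * np.cos(np.radians(lat[k])))
        vxs[k + 1], vys[k + 1] = vx, vy
    return TrueTrack(deployment.deployment_id, times,
                     np.asarray(normalize_lon(lon)), lat, vxs, vys, behavior)


def interpolate_track(track: TrueTrack, at_times: np.ndarray):
    """Linear interpolation of the true path at arbitrary UTC instants.

    Interpolates in the equal-area plane (no dateline seam) and converts
    back to lon/lat.
    """
    t0 = track.times.astype("datetime64[ns]").astype(np.int64)
    tq = pd.DatetimeIndex(at_times).values.astype("datetime64[ns]").astype(np.int64)
    x, y = track.xy
    xi = np.interp(tq, t0, x)
    yi = np.interp(tq, t0, y)
    from .projection import laea_inverse
    return laea_inverse(xi, yi)


# ---------------------------------------------------------------------------
# Argos observation process
# ---------------------------------------------------------------------------

def observe_argos(track: TrueTrack, config: SimulationConfig,
                  stage: str = "adult",
                  seed: Optional[int] = None) -> pd.DataFrame:
    """Generate duty-cycled Argos fixes for one true track.

    Fix instants fall only inside the daily duty window (default
    12:00-18:00 UTC), with a Poisson number of fixes per window.  Each
    fix is the interpolated true position plus isotropic Gaussian error
    with its sampled class sd; class-Z fixes are grossly corrupted, and a
    configured fraction of non-Z fixes carry no error ellipse.
    """
    if seed is None:
        seed = child_seed(config.seed, f"argos:{track.deployment_id}")
    rng = np.random.default_rng(seed)
    stage_rate = config.fixes_per_window.get(
        stage, next(iter(config.fixes_per_window.values())))

    start = pd.Timestamp(track.times[0])
    end = pd.Timestamp(track.times[-1])
    lo, hi = config.duty_cycle
    day = start.normalize()
    fix_times: List[pd.Timestamp] = []
    while day <= end.normalize():
        n = rng.poisson(stage_rate)
        if n:
            hours = lo + (hi - lo) * rng.random(n)
            for h in np.sort(hours):
                t = day + pd.Timedelta(hours=float(h))
                if start <= t <= end:
                    fix_times.append(t)
        day += pd.Timedelta(days=1)
    if not fix_times:
        return pd.DataFrame(columns=FIX_COLUMNS)

    times = pd.DatetimeIndex(fix_times)
    lon_true, lat_true = interpolate_track(track, times.values)
    x, y = laea_forward(lon_true, lat_true)

    classes = np.array(list(config.argos_class_probs))
    probs = np.array([config.argos_class_probs[c] for c in classes])
    lc = rng.choice(classes, size=len(times), p=probs)

    sd = np.array([config.argos_class_sd.get(c, 0.0) for c in lc])
    err = rng.standard_normal((len(times), 2)) * sd[:, None]
    is_z = lc == "Z"
    if is_z.any():
        err[is_z] = rng.uniform(-config.z_corruption_km, config.z_corruption_km,
                                size=(int(is_z.sum()), 2))
    from .projection import laea_inverse
    lon_obs, lat_obs = laea_inverse(x + err[:, 0], y + err[:, 1])

    semi_major = sd * 1000.0
    semi_minor = sd * 1000.0
    orientation = np.zeros(len(times))
    missing = (~is_z) & (rng.random(len(times)) < config.missing_ellipse_frac)
    semi_major[missing | is_z] = np.nan
    semi_minor[missing | is_z] = np.nan
    orientation[missing | is_z] = np.nan

    return pd.DataFrame({
        "deployment_id": track.deployment_id,
        "timestamp": times,
        "lon": np.asarray(lon_obs),
        "lat": np.asarray(lat_obs),
        "lc_class": lc,
        "ellipse_semi_major_m": semi_major,
        "ellipse_semi_minor_m": semi_minor,
        "ellipse_orientation_deg": orientation,
    })[FIX_COLUMNS]


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    """Write a fix table with ISO-8601 UTC timestamps (spec columns)."""
    out = fixes.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def write_deployments_csv(deployments: Sequence[Deployment], path) -> None:
    pd.DataFrame([d.as_row() for d in deployments]).to_csv(path, index=False)


def read_deployments_csv(path) -> List[Deployment]:
    df = pd.read_csv(path)
    return [Deployment(deployment_id=str(r.deployment_id), colony=r.colony,
                       colony_lon=float(r.colony_lon), colony_lat=float(r.colony_lat),
                       stage=r.stage, release_time=pd.Timestamp(r.release_time),
                       tag_model=getattr(r, "tag_model", "synthetic-tag"))
            for r in df.itertuples()]
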