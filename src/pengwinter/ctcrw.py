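"""Continuous-time correlated random walk (CTCRW) state-space smoothing.

The movement model is, per axis, an integrated Ornstein-Uhlenbeck
velocity process: velocity v follows dv = -beta v dt + sigma dW and
position p integrates v.  Over a step of length dt the exact transition
is

    v' = e^(-beta dt) v + N(0, qvv)
    p' = p + v (1 - e^(-beta dt)) / beta + noise,

with Var(p-noise) = (sigma^2/beta^2)(dt - 2(1-e^(-beta dt))/beta
+ (1-e^(-2 beta dt))/(2 beta)) and Cov(p,v) =
(sigma^2/(2 beta^2))(1-e^(-beta dt))^2.  The x and y axes of the
equal-area working plane are independent given (beta, sigma) and share
parameters (isotropic movement).  Argos fixes observe position with a
known class-dependent Gaussian sd (optionally rescaled by a fitted
``error_scale``).

Maximum-likelihood fitting runs the Kalman filter over log-parameters;
smoothing uses the RTS fixed-interval smoother with Joseph-form updates,
and multiple track imputation draws joint paths from the smoothing
distribution by mean-corrected simulation smoothing.

Units: km and days throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import minimize

from .projection import laea_forward, laea_inverse
from .synthetic import child_seed, ctcrw_transition

#: Diffuse prior variance on initial velocity (km^2/day^2).
V0_DIFFUSE = 1.0e6

#: Default per-class measurement sd (km), matching the observation model
#: of the synthetic Argos generator.
DEFAULT_CLASS_SD_KM: Dict[str, float] = {
    "3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 5.0, "B": 10.0,
}


@dataclass
class CtcrwParams:
    """Model parameters; optimization is on the log scale."""

    beta: float = 1.0          # velocity autocorrelation rate, 1/day
    sigma: float = 20.0        # velocity volatility, km/day^1.5
    error_scale: float = 1.0   # multiplier on class measurement sds

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.sigma <= 0 or self.error_scale <= 0:
            raise ValueError("beta, sigma, error_scale must be > 0")

    def to_log(self) -> np.ndarray:
        return np.log([self.beta, self.sigma])

    @classmethod
    def from_log(cls, theta, error_scale: float = 1.0) -> "CtcrwParams":
        return cls(beta=float(np.exp(theta[0])), sigma=float(np.exp(theta[1])),
                   error_scale=error_scale)


@dataclass
class ErrorModel:
    class_sd_km: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SD_KM))

    def sd_for(self, classes: Sequence[str], scale: float = 1.0) -> np.ndarray:
        return np.array([self.class_sd_km[c] for c in classes]) * scale


@dataclass
class CtcrwFit:
    """A fitted deployment: ML parameters plus smoothed states.

    ``times`` is the union of the 2-h clock (release to last fix) and
    the fix instants; ``is_clock`` flags the 2-h output nodes.  Smoothed
    means have shape (n, 2, 2) ordered (node, [p, v], [x-axis, y-axis])
    and covariances (n, 3) as (pp, pv, vv), identical for both axes.
    """

    deployment_id: str
    params: CtcrwParams
    loglik: float
    converged: bool
    message: str
    times: np.ndarray
    t_days: np.ndarray
    is_clock: np.ndarray
    obs_mask: np.ndarray
    obs_xy: np.ndarray            # (n_obs, 2)
    obs_sd: np.ndarray            # (n_obs,), already scaled
    smoothed_mean: np.ndarray     # (n, 2, 2)
    smoothed_cov: np.ndarray      # (n, 3)


@dataclass
class ImputedTrackSet:
    """Joint draws from the smoothing distribution on the 2-h clock."""

    deployment_id: str
    times: np.ndarray             # (n,), datetime64
    x: np.ndarray                 # (n_draws, n) km
    y: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.x.shape[0]

    def lonlat(self) -> Tuple[np.ndarray, np.ndarray]:
        return laea_inverse(self.x, self.y)

    def to_xarray(self) -> xr.Dataset:
        lon, lat = self.lonlat()
        return xr.Dataset(
            {"x": (("draw", "time"), self.x), "y": (("draw", "time"), self.y),
             "lon": (("draw", "time"), lon), "lat": (("draw", "time"), lat)},
            coords={"draw": np.arange(self.n_draws, dtype="int32"),
                    "time": self.times},
            attrs={"deployment_id": self.deployment_id, "seed": self.seed})

    def to_netcdf(self, path) -> None:
        """NetCDF3 (scipy engine) with a float time axis — the classic
        format has no 64-bit integers."""
        self.to_xarray().to_netcdf(
            path, engine="scipy",
            encoding={"time": {"units": "seconds since 1970-01-01",
                               "dtype": "float64"}})


# ---------------------------------------------------------------------------
# Kalman filter: fast scalar likelihood
# ---------------------------------------------------------------------------

def kalman_loglik(params: CtcrwParams, t_days: np.ndarray, x_km: np.ndarray,
                  y_km: np.ndarray, sd_km: np.ndarray) -> float:
    """Exact Gaussian log-likelihood of fix positions under the CTCRW.

    The prior at the first fix is (position = first fix with its
    measurement variance, velocity = 0 with diffuse variance); every fix,
    including the first, is then assimilated.  x and y contributions add
    (axes independent).
    """
    t = np.asarray(t_days, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 fixes")
    if np.any(np.diff(t) <= 0):
        raise ValueError("fix times must be strictly increasing")
    e, phi, qpp, qpv, qvv = ctcrw_transition(params.beta, params.sigma,
                                             np.diff(t))
    rvar = (np.asarray(sd_km, dtype=float) * params.error_scale) ** 2
    return _loglik_scalar(e.tolist(), phi.tolist(), qpp.tolist(), qpv.tolist(),
                          qvv.tolist(), np.asarray(x_km, float).tolist(),
                          np.asarray(y_km, float).tolist(), rvar.tolist())


def _loglik_scalar(e, phi, qpp, qpv, qvv, xs, ys, rvar) -> float:
    """Pure-scalar Kalman recursion for two independent axes (hot path)."""
    LOG2PI = 1.8378770664093453
    r0 = rvar[0]
    mpx, mvx = xs[0], 0.0
    mpy, mvy = ys[0], 0.0
    fpp, fpv, fvv = r0, 0.0, V0_DIFFUSE
    ll = 0.0
    n = len(xs)
    for i in range(n):
        if i > 0:
            ei, pi_ = e[i - 1], phi[i - 1]
            mpx = mpx + pi_ * mvx
            mvx = ei * mvx
            mpy = mpy + pi_ * mvy
            mvy = ei * mvy
            ppp = fpp + 2.0 * pi_ * fpv + pi_ * pi_ * fvv + qpp[i - 1]
            ppv = ei * (fpv + pi_ * fvv) + qpv[i - 1]
            pvv = ei * ei * fvv + qvv[i - 1]
        else:
            ppp, ppv, pvv = fpp, fpv, fvv
        r = rvar[i]
        S = ppp + r
        if S <= 0.0:                      # roundoff guard at extreme params
            S = 1e-12
        kp = ppp / S
        kv = ppv / S
        ix = xs[i] - mpx
        iy = ys[i] - mpy
        ll -= 0.5 * (2.0 * (LOG2PI + math.log(S)) + (ix * ix + iy * iy) / S)
        mpx += kp * ix
        mvx += kv * ix
        mpy += kp * iy
        mvy += kv * iy
        omk = 1.0 - kp
        fpp = omk * omk * ppp + kp * kp * r
        fpv = omk * (ppv - kv * ppp) + kp * kv * r
        fvv = pvv - 2.0 * kv * ppv + kv * kv * ppp + kv * kv * r
    return ll


# ---------------------------------------------------------------------------
# Batched filter + RTS smoother (covariances shared across the batch)
# ---------------------------------------------------------------------------

def _filter_smooth(beta: float, sigma: float, t: np.ndarray,
                   obs_mask: np.ndarray, yobs: np.ndarray,
                   rvar_obs: np.ndarray, m0: np.ndarray,
                   p0: Tuple[float, float, float]):
    """Kalman filter + RTS smoother over a node grid with missing obs.

    Parameters
    ----------
    t : (n,) strictly increasing times in days.
    obs_mask : (n,) bool; True where a position observation exists.
    yobs : (n_obs, batch) observed positions (any number of batch columns
        sharing the same observation pattern and variances).
    rvar_obs : (n_obs,) measurement variances.
    m0 : (2, batch) prior mean at node 0; p0 prior covariance (pp, pv, vv).

    Returns a dict with smoothed/filtered means (n, 2, batch), smoothed
    covariances (n, 3) (batch-independent), and per-column log-likelihood.
    """
    n = t.size
    batch = yobs.shape[1] if yobs.size else m0.shape[1]
    e, phi, qpp, qpv, qvv = ctcrw_transition(beta, sigma, np.diff(t))
    obs_at = np.flatnonzero(obs_mask)
    obs_ptr = 0

    fp = np.array(m0[0], dtype=float)
    fv = np.array(m0[1], dtype=float)
    fpp, fpv, fvv = p0
    ll = np.zeros(batch)

    f_mean = np.empty((n, 2, batch))
    f_cov = np.empty((n, 3))
    pred_mean = np.empty((n, 2, batch))
    pred_cov = np.empty((n, 3))
    LOG2PI = 1.8378770664093453

    for i in range(n):
        if i > 0:
            ei, ph = e[i - 1], phi[i - 1]
            fp = fp + ph * fv
            fv = ei * fv
            ppp = fpp + 2.0 * ph * fpv + ph * ph * fvv + qpp[i - 1]
            ppv = ei * (fpv + ph * fvv) + qpv[i - 1]
            pvv = ei * ei * fvv + qvv[i - 1]
        else:
            ppp, ppv, pvv = fpp, fpv, fvv
        pred_mean[i, 0] = fp
        pred_mean[i, 1] = fv
        pred_cov[i] = (ppp, ppv, pvv)

        if obs_mask[i]:
            r = rvar_obs[obs_ptr]
            y = yobs[obs_ptr]
            obs_ptr += 1
            S = ppp + r
            kp = ppp / S
            kv = ppv / S
            innov = y - fp
            ll -= 0.5 * (LOG2PI + np.log(S) + innov * innov / S)
            fp = fp + kp * innov
            fv = fv + kv * innov
            omk = 1.0 - kp
            fpp = omk * omk * ppp + kp * kp * r
            fpv = omk * (ppv - kv * ppp) + kp * kv * r
            fvv = pvv - 2.0 * kv * ppv + kv * kv * ppp + kv * kv * r
        else:
            fpp, fpv, fvv = ppp, ppv, pvv
        f_mean[i, 0] = fp
        f_mean[i, 1] = fv
        f_cov[i] = (fpp, fpv, fvv)

    # RTS backward pass
    s_mean = np.empty_like(f_mean)
    s_cov = np.empty_like(f_cov)
    s_mean[-1] = f_mean[-1]
    s_cov[-1] = f_cov[-1]
    for i in range(n - 2, -1, -1):
        fpp, fpv, fvv = f_cov[i]
        ei, ph = e[i], phi[i]
        a11 = fpp + fpv * ph
        a12 = fpv * ei
        a21 = fpv + fvv * ph
        a22 = fvv * ei
        ppp, ppv, pvv = pred_cov[i + 1]
        det = ppp * pvv - ppv * ppv
        if det > 1e-12 * max(ppp * pvv, 1e-300):
            g11 = (a11 * pvv - a12 * ppv) / det
            g12 = (-a11 * ppv + a12 * ppp) / det
            g21 = (a21 * pvv - a22 * ppv) / det
            g22 = (-a21 * ppv + a22 * ppp) / det
        else:
            pinv = np.linalg.pinv(np.array([[ppp, ppv], [ppv, pvv]]))
            g11, g12 = (np.array([[a11, a12]]) @ pinv)[0]
            g21, g22 = (np.array([[a21, a22]]) @ pinv)[0]
        dp = s_mean[i + 1, 0] - pred_mean[i + 1, 0]
        dv = s_mean[i + 1, 1] - pred_mean[i + 1, 1]
        s_mean[i, 0] = f_mean[i, 0] + g11 * dp + g12 * dv
        s_mean[i, 1] = f_mean[i, 1] + g21 * dp + g22 * dv
        dpp = s_cov[i + 1, 0] - ppp
        dpv = s_cov[i + 1, 1] - ppv
        dvv = s_cov[i + 1, 2] - pvv
        gd11 = g11 * dpp + g12 * dpv
        gd12 = g11 * dpv + g12 * dvv
        gd21 = g21 * dpp + g22 * dpv
        gd22 = g21 * dpv + g22 * dvv
        s_cov[i, 0] = fpp + gd11 * g11 + gd12 * g12
        s_cov[i, 1] = fpv + gd11 * g21 + gd12 * g22
        s_cov[i, 2] = fvv + gd21 * g21 + gd22 * g22

    return {"smoothed_mean": s_mean, "smoothed_cov": s_cov,
            "filtered_mean": f_mean, "filtered_cov": f_cov,
            "pred_mean": pred_mean, "pred_cov": pred_cov, "loglik": ll}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fixes_to_obs(fixes: pd.DataFrame, error_model: ErrorModel):
    """Project a deployment's fixes into the working plane.

    Returns (timestamps, t_days from first fix, x, y, sd_km).
    """
    times = pd.DatetimeIndex(fixes["timestamp"])
    t_days = (times.asi8 - times.asi8[0]) / 86400e9
    x, y = laea_forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    sd = error_model.sd_for(fixes["lc_class"].tolist())
    return times, np.asarray(t_days), x, y, sd


def build_time_grid(release: pd.Timestamp, last_fix: pd.Timestamp,
                    step_hours: float = 2.0) -> pd.DatetimeIndex:
    """Output clock: release + k*step up to the last fix, which is
    appended as the final node when it is off-grid."""
    span_h = (last_fix - release).total_seconds() / 3600.0
    k = int(np.floor(span_h / step_hours + 1e-9))
    grid = release + pd.to_timedelta(np.arange(k + 1) * step_hours, unit="h")
    if grid[-1] < last_fix:
        grid = grid.append(pd.DatetimeIndex([last_fix]))
    return pd.DatetimeIndex(grid)


def fit_ctcrw(fixes: pd.DataFrame, deployment_id: str,
              release_time: Optional[pd.Timestamp] = None,
              error_model: Optional[ErrorModel] = None,
              init: Optional[CtcrwParams] = None,
              step_hours: float = 2.0) -> CtcrwFit:
    """ML fit of (beta, sigma) by L-BFGS-B on log-parameters.

    Runs from the default initial point and one deterministically
    jittered restart, keeps the better optimum, then stores RTS-smoothed
    states on the union of the fix times and the 2-h clock from release
    (or the first fix) to the last fix.
    """
    error_model = error_model or ErrorModel()
    init = init or CtcrwParams()
    times, t_days, x, y, sd = fixes_to_obs(fixes, error_model)
    if len(times) < 2:
        raise ValueError("need at least 2 fixes to fit")

    def nll(theta):
        p = CtcrwParams.from_log(theta, error_scale=init.error_scale)
        try:
            return -kalman_loglik(p, t_days, x, y, sd)
        except (FloatingPointError, OverflowError):
            return 1e12

    starts = [init.to_log(), init.to_log() + np.array([0.7, -0.7])]
    best = None
    for theta0 in starts:
        res = minimize(nll, theta0, method="L-BFGS-B",
                       bounds=[(-8.0, 8.0), (-8.0, 12.0)])
        if best is None or res.fun < best.fun:
            best = res
    params = CtcrwParams.from_log(best.x, error_scale=init.error_scale)
    converged = bool(best.success) and np.isfinite(best.fun)

    release = pd.Timestamp(release_time) if release_time is not None else times[0]
    if release > times[0]:
        release = times[0]
    grid = build_time_grid(release, times[-1], step_hours)
    all_times = grid.union(times)
    t_all = (all_times.asi8 - all_times.asi8[0]) / 86400e9
    # merge nodes closer than ~1 ms to avoid zero dt steps
    keep = np.concatenate([[True], np.diff(t_all) > 1e-8])
    all_times = all_times[keep]
    t_all = t_all[keep]
    is_clock = np.asarray(all_times.isin(grid))
    obs_mask = np.asarray(all_times.isin(times))
    # map each fix to its node (fix times are a subset of all_times)
    yobs = np.column_stack([x, y])
    rvar = (sd * params.error_scale) ** 2
    m0 = np.array([[x[0], y[0]], [0.0, 0.0]])
    p0 = (rvar[0], 0.0, V0_DIFFUSE)
    out = _filter_smooth(params.beta, params.sigma, t_all, obs_mask, yobs,
                         rvar, m0, p0)
    ll = float(out["loglik"].sum())
    return CtcrwFit(deployment_id=deployment_id, params=params, loglik=ll,
                    converged=converged, message=str(best.message),
                    times=all_times.values, t_days=t_all,
                    is_clock=np.asarray(is_clock),
                    obs_mask=obs_mask, obs_xy=yobs, obs_sd=sd * params.error_scale,
                    smoothed_mean=out["smoothed_mean"],
                    smoothed_cov=out["smoothed_cov"])


# ---------------------------------------------------------------------------
# Multiple imputation by mean-corrected simulation smoothing
# ---------------------------------------------------------------------------

def impute_tracks(fit: CtcrwFit, n_draws: int = 100,
                  seed: int = 0) -> ImputedTrackSet:
    """Draw joint track paths from the smoothing distribution.

    Durbin-Koopman mean correction: simulate unconditional state paths
    and synthetic observations from the fitted model, smooth the
    synthetic observations with the same prior, and add the residual
    path to the real smoothed mean.  Draws are jointly correct in time
    (not independent per-node noise) and reproducible from the seed.
    """
    if not fit.converged:
        raise ValueError(f"cannot impute from unconverged fit {fit.deployment_id}")
    beta, sigma = fit.params.beta, fit.params.sigma
    if sigma <= 0:
        raise ValueError("degenerate innovation covariance")
    rng = np.random.default_rng(child_seed(seed, f"impute:{fit.deployment_id}"))

    t = fit.t_days
    n = t.size
    obs_mask = fit.obs_mask
    obs_idx = np.flatnonzero(obs_mask)
    rvar = fit.obs_sd ** 2
    batch = 2 * n_draws                   # x-draws then y-draws

    e, phi, qpp, qpv, qvv = ctcrw_transition(beta, sigma, np.diff(t))
    # per-step Cholesky of the 2x2 transition covariance
    l11 = np.sqrt(np.maximum(qpp, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        l21 = np.where(l11 > 0, qpv / np.where(l11 > 0, l11, 1.0), 0.0)
    l22 = np.sqrt(np.maximum(qvv - l21 ** 2, 0.0))

    m0 = np.array([[fit.obs_xy[0, 0], fit.obs_xy[0, 1]], [0.0, 0.0]])
    p0 = (rvar[0], 0.0, V0_DIFFUSE)

    # simulate unconditional paths from the prior
    p = np.repeat(m0[0], n_draws) + rng.standard_normal(batch) * np.sqrt(p0[0])
    v = rng.standard_normal(batch) * np.sqrt(p0[2])
    sim_p = np.empty((n, batch))
    sim_p[0] = p
    for i in range(n - 1):
        z1 = rng.standard_normal(batch)
        z2 = rng.standard_normal(batch)
        p = p + phi[i] * v + l11[i] * z1
        v = e[i] * v + l21[i] * z1 + l22[i] * z2
        sim_p[i + 1] = p

    sim_obs = (sim_p[obs_idx]
               + rng.standard_normal((obs_idx.size, batch))
               * np.sqrt(rvar)[:, None])
    m0_batch = np.vstack([np.repeat(m0[0], n_draws), np.zeros(batch)])
    sim_smooth = _filter_smooth(beta, sigma, t, obs_mask, sim_obs, rvar,
                                m0_batch, p0)["smoothed_mean"]

    # conditional draw = real smoothed mean + (simulated path - its smooth)
    real_p = fit.smoothed_mean[:, 0, :]            # (n, 2 axes)
    resid = sim_p - sim_smooth[:, 0, :]            # (n, batch)
    draws_x = real_p[:, 0][:, None] + resid[:, :n_draws]
    draws_y = real_p[:, 1][:, None] + resid[:, n_draws:]

    clock = fit.is_clock
    times_out = fit.times[clock]
    return ImputedTrackSet(deployment_id=fit.deployment_id,
                           times=times_out,
                           x=draws_x[clock].T.copy(),
                           y=draws_y[clock].T.copy(),
                           seed=seed)


def smoothed_mean_path(fit: CtcrwFit) -> pd.DataFrame:
    """Deterministic smoothed mean path on the 2-h clock (lon/lat + km)."""
    clock = fit.is_clock
    x = fit.smoothed_mean[clock, 0, 0]
    y = fit.smoothed_mean[clock, 0, 1]
    lon, lat = laea_inverse(x, y)
    return pd.DataFrame({"timestamp": fit.times[clock], "x": x, "y": y,
                         "lon": lon, "lat": lat})
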