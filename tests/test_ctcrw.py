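"""State-space model tests: likelihood oracle, fitting, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pengwinter.ctcrw import (V0_DIFFUSE, CtcrwParams, ErrorModel,
                              _filter_smooth, fit_ctcrw, impute_tracks,
                              kalman_loglik, smoothed_mean_path)
from pengwinter.synthetic import (SimulationConfig, ctcrw_transition,
                                  observe_argos, simulate_true_track)

from conftest import exact_obs_config


def joint_gaussian_loglik(params, t, x, y, sd):
    """Brute-force oracle: stack the state covariance of all fixes and
    evaluate the observed positions as one multivariate Gaussian per axis.

    Uses the same generative convention as the filter: the state prior at
    the first fix is N((first fix, 0), diag(sd_1^2, V0)) and every fix,
    including the first, is an observation of position.
    """
    n = len(t)
    e, phi, qpp, qpv, qvv = ctcrw_transition(params.beta, params.sigma,
                                             np.diff(t))
    Ts = [np.array([[1.0, phi[i]], [0.0, e[i]]]) for i in range(n - 1)]
    Qs = [np.array([[qpp[i], qpv[i]], [qpv[i], qvv[i]]]) for i in range(n - 1)]
    P = [np.diag([sd[0] ** 2, V0_DIFFUSE])]
    for i in range(n - 1):
        P.append(Ts[i] @ P[-1] @ Ts[i].T + Qs[i])
    Sig = np.zeros((2 * n, 2 * n))
    for i in range(n):
        Sig[2 * i:2 * i + 2, 2 * i:2 * i + 2] = P[i]
        for j in range(i + 1, n):
            C = P[i]
            for k in range(i, j):
                C = C @ Ts[k].T
            Sig[2 * i:2 * i + 2, 2 * j:2 * j + 2] = C
            Sig[2 * j:2 * j + 2, 2 * i:2 * i + 2] = C.T
    H = np.zeros((n, 2 * n))
    for i in range(n):
        H[i, 2 * i] = 1.0
    cov = H @ Sig @ H.T + np.diag(np.asarray(sd, float) ** 2)
    mx = multivariate_normal(mean=np.full(n, x[0]), cov=cov)
    my = multivariate_normal(mean=np.full(n, y[0]), cov=cov)
    return float(mx.logpdf(x) + my.logpdf(y))


class TestKalmanLoglik:
    @pytest.mark.parametrize("n_fixes", [2, 3, 4])
    @pytest.mark.parametrize("beta,sigma", [(0.7, 12.0), (2.5, 45.0)])
    def test_equals_joint_gaussian_oracle(self, n_fixes, beta, sigma):
        rng = np.random.default_rng(n_fixes * 17)
        t = np.sort(rng.uniform(0, 2, n_fixes))
        t[0] = 0.0
        x = rng.normal(0, 20, n_fixes)
        y = rng.normal(0, 20, n_fixes)
        sd = rng.uniform(0.2, 8.0, n_fixes)
        p = CtcrwParams(beta=beta, sigma=sigma)
        ll = kalman_loglik(p, t, x, y, sd)
        oracle = joint_gaussian_loglik(p, t, x, y, sd)
        assert ll == pytest.approx(oracle, rel=1e-8)

    def test_uninformative_second_fix(self):
        """With sd -> infinity on the second of two fixes, the likelihood
        stops depending on the movement parameters."""
        t = np.array([0.0, 0.5])
        x = np.array([0.0, 500.0])
        y = np.array([0.0, -500.0])
        sd = np.array([0.5, 1e7])
        lls = [kalman_loglik(CtcrwParams(beta=b, sigma=s), t, x, y, sd)
               for b, s in [(0.5, 10.0), (2.0, 60.0), (1.0, 5.0)]]
        assert np.ptp(lls) < 1e-6

    def test_transition_covariance_vanishes_with_dt(self):
        _, _, qpp, qpv, qvv = ctcrw_transition(1.0, 30.0,
                                               np.array([1e-12, 1e-6]))
        assert qpp[0] < qpp[1] < 1e-10
        assert qvv[0] < qvv[1] < 1e-3
        assert qpv[0] < qpv[1] < 1e-7

    def test_non_increasing_times_rejected(self):
        p = CtcrwParams()
        with pytest.raises(ValueError, match="increasing"):
            kalman_loglik(p, np.array([0.0, 1.0, 1.0]), np.zeros(3),
                          np.zeros(3), np.ones(3))

    def test_batched_filter_agrees_with_scalar_path(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 5, 40))
        t[0] = 0.0
        x = np.cumsum(rng.normal(0, 5, 40))
        y = np.cumsum(rng.normal(0, 5, 40))
        sd = rng.uniform(0.5, 3.0, 40)
        p = CtcrwParams(beta=1.2, sigma=25.0)
        ll_scalar = kalman_loglik(p, t, x, y, sd)
        out = _filter_smooth(p.beta, p.sigma, t, np.ones(40, dtype=bool),
                             np.column_stack([x, y]), sd ** 2,
                             np.array([[x[0], y[0]], [0.0, 0.0]]),
                             (sd[0] ** 2, 0.0, V0_DIFFUSE))
        assert float(out["loglik"].sum()) == pytest.approx(ll_scalar, rel=1e-10)


class TestFit:
    def _simulated_fixes(self, shirreff, seed, days=60.0):
        cfg = SimulationConfig(seed=7)
        cfg.drift_speed = 0.0
        cfg.front_attraction = 0.0
        cfg.argos_class_probs = {"3": 1.0, "2": 0, "1": 0, "0": 0,
                                 "A": 0, "B": 0, "Z": 0}
        cfg.missing_ellipse_frac = 0.0
        tr = simulate_true_track(shirreff, "west", cfg, days, seed=seed)
        return observe_argos(tr, cfg, seed=seed + 1), shirreff.release_time

    def test_fit_is_deterministic(self, shirreff):
        fx, release = self._simulated_fixes(shirreff, 61)
        a = fit_ctcrw(fx, "d", release_time=release)
        b = fit_ctcrw(fx, "d", release_time=release)
        assert a.params.beta == b.params.beta
        assert a.params.sigma == b.params.sigma

    def test_smoothed_variance_smaller_at_fix_than_between(self, shirreff):
        fx, release = self._simulated_fixes(shirreff, 63)
        fit = fit_ctcrw(fx, "d", release_time=release)
        obs_nodes = np.flatnonzero(fit.obs_mask)
        # a fix node and an adjacent clock-only node
        i = obs_nodes[len(obs_nodes) // 2]
        between = np.flatnonzero(~fit.obs_mask & fit.is_clock)
        j = between[np.argmin(np.abs(between - i))]
        assert fit.smoothed_cov[i, 0] <= fit.smoothed_cov[j, 0]

    def test_parameter_recovery(self, shirreff):
        """Median absolute relative error of (beta, sigma) < 15% over
        replicated 200-day class-3 tracks (beta=1/day, sigma=30)."""
        cfg = SimulationConfig(seed=3)
        cfg.drift_speed = 0.0
        cfg.front_attraction = 0.0
        cfg.argos_class_probs = {"3": 1.0, "2": 0, "1": 0, "0": 0,
                                 "A": 0, "B": 0, "Z": 0}
        cfg.missing_ellipse_frac = 0.0
        err_b, err_s = [], []
        for i in range(12):
            tr = simulate_true_track(shirreff, "west", cfg, 200.0,
                                     seed=70000 + i)
            fx = observe_argos(tr, cfg, seed=71000 + i)
            fit = fit_ctcrw(fx, f"rep{i}", release_time=shirreff.release_time)
            err_b.append(abs(fit.params.beta - 1.0))
            err_s.append(abs(fit.params.sigma - 30.0) / 30.0)
        assert np.median(err_b) < 0.15
        assert np.median(err_s) < 0.15


class TestImputation:
    def _fit(self, shirreff, seed=81, days=20.0):
        cfg = SimulationConfig(seed=4)
        cfg.drift_speed = 0.0
        cfg.front_attraction = 0.0
        cfg.argos_class_probs = {"3": 0.5, "2": 0.5, "1": 0, "0": 0,
                                 "A": 0, "B": 0, "Z": 0}
        cfg.missing_ellipse_frac = 0.0
        tr = simulate_true_track(shirreff, "west", cfg, days, seed=seed)
        fx = observe_argos(tr, cfg, seed=seed + 1)
        return fit_ctcrw(fx, "d", release_time=shirreff.release_time), fx

    def test_draws_on_exact_two_hour_clock(self, shirreff):
        fit, fx = self._fit(shirreff)
        imp = impute_tracks(fit, n_draws=5, seed=1)
        times = pd.DatetimeIndex(imp.times)
        assert times[0] == shirreff.release_time
        assert times[-1] == pd.Timestamp(fx["timestamp"].iloc[-1])
        interior = np.diff(times.asi8)[:-1] / 3.6e12
        np.testing.assert_allclose(interior, 2.0)

    def test_draw_mean_converges_to_smoothed_mean(self, shirreff):
        fit, _ = self._fit(shirreff)
        imp = impute_tracks(fit, n_draws=800, seed=2)
        sm = smoothed_mean_path(fit)
        sd = np.sqrt(np.maximum(fit.smoothed_cov[fit.is_clock, 0], 1e-12))
        z = np.abs(imp.x.mean(axis=0) - sm["x"].to_numpy()) / (sd / np.sqrt(800))
        # standardized MC error of the mean stays at O(1)
        assert np.median(z) < 3.0

    def test_draw_variance_matches_analytic_smoother(self, shirreff):
        """Empirical variance of 2000 joint draws at a between-fix node is
        within 10% of the RTS smoother's analytic variance."""
        fit, _ = self._fit(shirreff)
        imp = impute_tracks(fit, n_draws=2000, seed=3)
        var_analytic = fit.smoothed_cov[fit.is_clock, 0]
        j = int(np.argmax(var_analytic[1:-1])) + 1
        emp = imp.x[:, j].var(ddof=1)
        assert emp == pytest.approx(var_analytic[j], rel=0.10)

    def test_vanishing_sigma_reproduces_smoothed_mean(self, shirreff):
        """As sigma -> 0 the smoothing distribution collapses toward the
        deterministic smoothed mean path, and a single draw follows it."""
        fit, _ = self._fit(shirreff)
        fit.params.sigma = 1e-9
        out = _filter_smooth(fit.params.beta, fit.params.sigma, fit.t_days,
                             fit.obs_mask, fit.obs_xy, fit.obs_sd ** 2,
                             np.array([[fit.obs_xy[0, 0], fit.obs_xy[0, 1]],
                                       [0.0, 0.0]]),
                             (fit.obs_sd[0] ** 2, 0.0, V0_DIFFUSE))
        fit.smoothed_mean = out["smoothed_mean"]
        fit.smoothed_cov = out["smoothed_cov"]
        imp = impute_tracks(fit, n_draws=1, seed=4)
        sd_max = float(np.sqrt(out["smoothed_cov"][:, 0].max()))
        assert sd_max < 1.0          # near-deterministic given the fixes
        mean = smoothed_mean_path(fit)
        np.testing.assert_allclose(imp.x[0], mean["x"].to_numpy(),
                                   atol=max(5 * sd_max, 1e-6))

    def test_unconverged_fit_rejected(self, shirreff):
        fit, _ = self._fit(shirreff)
        fit.converged = False
        with pytest.raises(ValueError, match="unconverged"):
            impute_tracks(fit, n_draws=2, seed=5)

    def test_draws_reproducible_from_seed(self, shirreff):
        fit, _ = self._fit(shirreff)
        a = impute_tracks(fit, n_draws=3, seed=11)
        b = impute_tracks(fit, n_draws=3, seed=11)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
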