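"""Movement-model fitting and Gaussian home-range estimation.

A set of track segments is fitted by maximum likelihood under a shared
continuous-time movement model (OU, OUF, or IOU): segments are treated as
independent realizations of one process, so their exact Gaussian
log-likelihoods add.  The likelihood is evaluated by sequential
conditioning on the (position[, velocity]) state (see ``_kalman``), which
is algebraically identical to the dense-covariance Gaussian density but
linear in the number of fixes.

A fitted stationary model converts to a home-range area through the
Gaussian quantile formula

    H_q = -2 ln(1 - q) * pi * sigma^2,

where sigma^2 is the estimated per-axis positional variance; the effective
sample size of an area estimate is the number of observed range crossings,
duration / tau_p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import _kalman
from .movement import MovementParams, Track, TrackSegment

__all__ = [
    "MovementModelFit",
    "HomeRangeEstimate",
    "process_autocovariance",
    "iou_position_cov",
    "model_loglik",
    "fit_movement_model",
    "gaussian_home_range",
    "effective_sample_size",
    "diffusion_rate",
    "crossing_time",
]

#: relative floor applied to innovation variances, as a fraction of the
#: pooled data variance, to keep the filter positive definite
VAR_FLOOR_REL = 1e-10


def process_autocovariance(params: MovementParams, lag) -> float | np.ndarray:
    """Per-axis positional autocovariance of a stationary movement model.

    OU: sigma^2 e^(-lag/tau_p).  OUF: sigma^2 (tau_p e^(-lag/tau_p) -
    tau_v e^(-lag/tau_v)) / (tau_p - tau_v), with the analytic limit at
    tau_p = tau_v.  For the nonstationary IOU use ``iou_position_cov``.
    """
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be >= 0")
    if params.family == "OU":
        out = params.sigma_position * np.exp(-lag / params.tau_position)
    elif params.family == "OUF":
        tp, tv = params.tau_position, params.tau_velocity
        if abs(tp - tv) < 1e-12 * tp:
            # repeated-root limit: sigma^2 (1 + lag/tau) e^(-lag/tau)
            out = params.sigma_position * (1.0 + lag / tp) * np.exp(-lag / tp)
        else:
            out = params.sigma_position * (
                tp * np.exp(-lag / tp) - tv * np.exp(-lag / tv)) / (tp - tv)
    else:
        raise ValueError("IOU is nonstationary; use iou_position_cov(s, t)")
    return float(out) if out.ndim == 0 else out


def iou_position_cov(params: MovementParams, s, t) -> float | np.ndarray:
    """Two-time position covariance of an IOU track started at a known
    position at time 0 with stationary initial velocity."""
    if params.family != "IOU":
        raise ValueError("params.family must be IOU")
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s < 0) or np.any(t < 0):
        raise ValueError("times must be >= 0")
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    tv, sv2 = params.tau_velocity, params.sigma_velocity
    out = sv2 * tv * (
        2.0 * lo - tv * (1.0 - np.exp(-lo / tv))
        - tv * (np.exp(-(hi - lo) / tv) - np.exp(-hi / tv)))
    return float(out) if out.ndim == 0 else out


def _as_track(seg) -> Track:
    return seg.track if isinstance(seg, TrackSegment) else seg


def _pack(segments):
    """Concatenate segments into (dts, x, y, is_start) arrays."""
    tracks = [_as_track(s) for s in segments]
    if not tracks:
        raise ValueError("need at least one segment")
    for tr in tracks:
        if len(tr) < 2:
            raise ValueError("each segment needs at least 2 fixes")
    dts, xs, ys, starts = [], [], [], []
    for tr in tracks:
        d = np.empty(len(tr))
        d[0] = 0.0
        d[1:] = np.diff(tr.times)
        dts.append(d)
        xs.append(tr.positions[:, 0])
        ys.append(tr.positions[:, 1])
        st = np.zeros(len(tr), dtype=bool)
        st[0] = True
        starts.append(st)
    return (np.concatenate(dts), np.concatenate(xs), np.concatenate(ys),
            np.concatenate(starts))


def model_loglik(segments, params: MovementParams) -> float:
    """Exact joint Gaussian log-likelihood of independent segments.

    The x and y axes contribute independently; the value is invariant to
    segment ordering.  OU/OUF assume a zero-mean stationary process (center
    the data first if needed); IOU conditions on each segment's first fix.
    Degenerate parameter values yield -inf rather than an exception.
    """
    dts, xs, ys, starts = _pack(segments)
    floor = VAR_FLOOR_REL * max(np.var(xs) + np.var(ys), 1e-300)
    if params.family == "OU":
        ll = (_kalman.ou_axis_loglik(dts, xs, starts, params.sigma_position,
                                     params.tau_position)
              + _kalman.ou_axis_loglik(dts, ys, starts, params.sigma_position,
                                       params.tau_position))
    elif params.family == "OUF":
        ll = (_kalman.ouf_axis_loglik(dts, xs, starts, params.sigma_position,
                                      params.tau_position,
                                      params.tau_velocity, floor)
              + _kalman.ouf_axis_loglik(dts, ys, starts, params.sigma_position,
                                        params.tau_position,
                                        params.tau_velocity, floor))
    else:
        ll = (_kalman.iou_axis_loglik(dts, xs, starts, params.sigma_velocity,
                                      params.tau_velocity, floor)
              + _kalman.iou_axis_loglik(dts, ys, starts, params.sigma_velocity,
                                        params.tau_velocity, floor))
    return float(ll) if math.isfinite(ll) else -math.inf


@dataclass
class MovementModelFit:
    """Maximum-likelihood movement-model fit.

    ``coef_cov`` is the covariance of the log-scale parameter vector whose
    order is given by ``param_names`` (inverse numerical Hessian of the
    negative log-likelihood at the optimum).
    """

    family: str
    sigma_position: float | None
    tau_position: float | None
    tau_velocity: float | None
    sigma_velocity: float | None
    log_likelihood: float
    coef_cov: np.ndarray
    param_names: tuple[str, ...]
    n_obs: int
    converged: bool
    center: tuple[float, float] = (0.0, 0.0)

    def log_params(self) -> np.ndarray:
        vals = {"log_sigma_position": self.sigma_position,
                "log_tau_position": self.tau_position,
                "log_tau_velocity": self.tau_velocity,
                "log_sigma_velocity": self.sigma_velocity}
        return np.array([math.log(vals[n]) for n in self.param_names])

    def wald_interval(self, name: str, level: float = 0.95):
        """Wald CI for a natural-scale parameter (log-scale normal)."""
        from scipy.stats import norm

        i = self.param_names.index(name)
        se = math.sqrt(max(self.coef_cov[i, i], 0.0))
        z = norm.ppf(0.5 + level / 2.0)
        lo = self.log_params()[i] - z * se
        hi = self.log_params()[i] + z * se
        return math.exp(lo), math.exp(hi)


def _theta_to_params(theta: np.ndarray, family: str) -> MovementParams:
    e = np.exp(np.clip(theta, -700, 700))
    if family == "OU":
        return MovementParams("OU", sigma_position=e[0], tau_position=e[1])
    if family == "OUF":
        # symmetric in the two timescales; order them for validity
        t1, t2 = sorted((e[1], e[2]), reverse=True)
        if t1 == t2:
            t2 = t1 * (1.0 - 1e-9)
        return MovementParams("OUF", sigma_position=e[0], tau_position=t1,
                              tau_velocity=t2)
    return MovementParams("IOU", sigma_velocity=e[0], tau_velocity=e[1])


def _moment_init(segments, family: str) -> np.ndarray:
    tracks = [_as_track(s) for s in segments]
    xs = np.concatenate([t.positions[:, 0] for t in tracks])
    ys = np.concatenate([t.positions[:, 1] for t in tracks])
    durations = np.array([t.duration for t in tracks])
    med_dt = float(np.median(np.concatenate(
        [np.diff(t.times) for t in tracks if len(t) > 1])))
    if family == "IOU":
        # short-gap speed: Var(dx) ~ sigma_v^2 dt^2 for dt << tau_v
        num = 0.0
        den = 0.0
        r_num = 0.0
        r_den = 0.0
        for t in tracks:
            if len(t) < 3:
                continue
            for ax in range(2):
                v = np.diff(t.positions[:, ax]) / np.diff(t.times)
                num += float(np.sum(v * v))
                den += v.shape[0]
                r_num += float(np.sum(v[1:] * v[:-1]))
                r_den += v.shape[0] - 1
        sv2 = max(num / max(den, 1), 1e-12)
        rho = r_num / max(r_den, 1) / sv2 if r_den else 0.5
        tau_v = -med_dt / math.log(min(max(rho, 0.05), 0.95))
        return np.log([sv2, max(tau_v, med_dt / 10.0)])
    s2 = max(0.5 * (np.var(xs) + np.var(ys)), 1e-12)
    tau_p = max(float(np.median(durations)) / 4.0, 2.0 * med_dt)
    if family == "OU":
        return np.log([s2, tau_p])
    tau_v = max(min(2.0 * med_dt, tau_p / 4.0), tau_p * 1e-4)
    return np.log([s2, tau_p, tau_v])


def _numeric_hessian(f, theta: np.ndarray, rel_step: float = 1e-4):
    p = theta.shape[0]
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / (h[i] ** 2)
            else:
                val = (f(theta + ei + ej) - f(theta + ei - ej)
                       - f(theta - ei + ej) + f(theta - ei - ej)) / (
                          4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def fit_movement_model(segments, family: str, init=None,
                       center: bool = True) -> MovementModelFit:
    """Fit a shared movement model to pooled segments by maximum likelihood.

    Optimizes the log-transformed parameters by quasi-Newton search from a
    moment-based initialization plus two rescaled restarts (timescales x10
    and /10); ``coef_cov`` comes from the inverse numerical Hessian.  For
    the stationary families the pooled empirical mean location is
    subtracted first (profile estimate of the range center) and reported as
    ``center``.
    """
    if family not in ("OU", "OUF", "IOU"):
        raise ValueError(f"unknown family {family!r}")
    tracks = [_as_track(s) for s in segments]
    mean_xy = (0.0, 0.0)
    if center and family != "IOU":
        allpos = np.concatenate([t.positions for t in tracks])
        mean_xy = (float(allpos[:, 0].mean()), float(allpos[:, 1].mean()))
        tracks = [Track(t.times, t.positions - np.array(mean_xy))
                  for t in tracks]
    n_obs = sum(len(t) for t in tracks)

    def nll(theta):
        try:
            params = _theta_to_params(theta, family)
        except ValueError:
            return 1e300
        ll = model_loglik(tracks, params)
        return -ll if math.isfinite(ll) else 1e300

    theta0 = np.asarray(init, dtype=float) if init is not None \
        else _moment_init(tracks, family)
    inits = [theta0.copy()]
    for fac in (math.log(10.0), -math.log(10.0)):
        t = theta0.copy()
        t[1:] += fac  # rescale the timescale entries
        inits.append(t)
    best = None
    for t0 in inits:
        res = minimize(nll, t0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 4000})
        res = minimize(nll, res.x, method="BFGS",
                       options={"gtol": 1e-7, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    H = _numeric_hessian(nll, theta_hat)
    try:
        cov = np.linalg.inv(H)
        cov_ok = bool(np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0))
    except np.linalg.LinAlgError:
        cov = np.full((theta_hat.size, theta_hat.size), np.nan)
        cov_ok = False
    params = _theta_to_params(theta_hat, family)
    if family == "OUF":
        # relabel so coef_cov rows match (sigma, tau_p, tau_v) ordering
        if math.exp(theta_hat[1]) < math.exp(theta_hat[2]):
            perm = [0, 2, 1]
            cov = cov[np.ix_(perm, perm)]
        names = ("log_sigma_position", "log_tau_position", "log_tau_velocity")
        fit_vals = dict(sigma_position=params.sigma_position,
                        tau_position=params.tau_position,
                        tau_velocity=params.tau_velocity,
                        sigma_velocity=None)
    elif family == "OU":
        names = ("log_sigma_position", "log_tau_position")
        fit_vals = dict(sigma_position=params.sigma_position,
                        tau_position=params.tau_position,
                        tau_velocity=None, sigma_velocity=None)
    else:
        names = ("log_sigma_velocity", "log_tau_velocity")
        fit_vals = dict(sigma_position=None, tau_position=None,
                        tau_velocity=params.tau_velocity,
                        sigma_velocity=params.sigma_velocity)
    converged = bool(best.fun < 1e299 and cov_ok)
    return MovementModelFit(
        family=family, log_likelihood=-float(best.fun), coef_cov=cov,
        param_names=names, n_obs=n_obs, converged=converged,
        center=mean_xy, **fit_vals)


def gaussian_home_range(sigma_position: float, quantile: float = 0.95,
                        ) -> float:
    """Area of the central ``quantile`` region of a circular Gaussian
    utilization distribution with per-axis variance ``sigma_position``:
    -2 ln(1 - q) pi sigma^2."""
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie strictly in (0, 1)")
    if not sigma_position > 0.0:
        raise ValueError("sigma_position must be positive")
    return -2.0 * math.log(1.0 - quantile) * math.pi * sigma_position


@dataclass
class HomeRangeEstimate:
    """Home-range summary of a fitted stationary movement model."""

    quantile: float
    area: float
    ess_area: float
    crossing_time: float | None  # None when unresolved


def effective_sample_size(fit: MovementModelFit, total_duration: float,
                          ) -> float:
    """Number of range crossings observed: duration / tau_p."""
    if total_duration < 0:
        raise ValueError("total_duration must be >= 0")
    if fit.tau_position is None:
        raise ValueError("IOU fit has no range-crossing timescale")
    return total_duration / fit.tau_position


def crossing_time(fit: MovementModelFit, level: float = 0.95,
                  ) -> float | None:
    """Resolvable home-range crossing time, or None.

    Resolvable means a finite tau_p estimate with a finite Wald upper
    confidence bound; unresolved crossing times are excluded from
    summaries.
    """
    if fit.tau_position is None or not math.isfinite(fit.tau_position):
        return None
    try:
        _, hi = fit.wald_interval("log_tau_position", level)
    except (ValueError, IndexError):
        return None
    if not math.isfinite(hi):
        return None
    return fit.tau_position


def diffusion_rate(fit: MovementModelFit) -> float:
    """Per-axis area covered per unit time: sigma^2/tau_p for range-
    resident models, sigma_v^2 tau_v for the diffusive IOU limit."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.family in ("OU", "OUF"):
        return fit.sigma_position / fit.tau_position
    return fit.sigma_velocity * fit.tau_velocity


def home_range_estimate(fit: MovementModelFit, total_duration: float,
                        quantile: float = 0.95) -> HomeRangeEstimate:
    """Bundle area, effective sample size and crossing time for a fit."""
    area = gaussian_home_range(fit.sigma_position, quantile)
    return HomeRangeEstimate(
        quantile=quantile, area=area,
        ess_area=effective_sample_size(fit, total_duration),
        crossing_time=crossing_time(fit))
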