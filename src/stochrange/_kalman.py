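"""Sequential-conditioning (Kalman) log-likelihood kernels.

Each kernel evaluates the exact Gaussian log-likelihood of one coordinate
axis of a set of independent track segments under a continuous-time
movement model, by filtering the (position[, velocity]) state through the
exact process transition over each sampling gap.  Positions are observed
without measurement error, so the update step conditions the state on the
observation exactly.  Cost is linear in the number of fixes.

Segments are passed concatenated, with ``is_start`` flagging the first fix
of each segment (the filter re-initializes there).  The kernels are
compiled with numba when it is importable and run as plain Python
otherwise.
"""

from __future__ import annotations

import math

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_LOG2PI = math.log(2.0 * math.pi)
_BIG_NEG = -1.0e300


@njit(cache=False)
def ou_axis_loglik(dts, obs, is_start, sigma2, tau):
    """OU log-likelihood for one axis (state = observed position)."""
    if sigma2 <= 0.0 or tau <= 0.0:
        return _BIG_NEG
    ll = 0.0
    prev = 0.0
    for i in range(obs.shape[0]):
        if is_start[i]:
            mean = 0.0
            var = sigma2
        else:
            phi = math.exp(-dts[i] / tau)
            mean = phi * prev
            var = sigma2 * (1.0 - phi * phi)
        if var <= 0.0 or not math.isfinite(var):
            return _BIG_NEG
        r = obs[i] - mean
        ll += -0.5 * (_LOG2PI + math.log(var) + r * r / var)
        prev = obs[i]
    return ll


@njit(cache=False)
def ouf_axis_loglik(dts, obs, is_start, sigma2, tau_p, tau_v, var_floor):
    """OUF log-likelihood for one axis (state = position, velocity)."""
    if sigma2 <= 0.0 or tau_p <= 0.0 or tau_v <= 0.0:
        return _BIG_NEG
    lam1 = -1.0 / tau_p
    lam2 = -1.0 / tau_v
    p0 = sigma2                      # stationary Var(x)
    p1 = sigma2 / (tau_p * tau_v)    # stationary Var(v)
    pq = 1.0 / (tau_p * tau_v)       # -A10
    ll = 0.0
    z0 = 0.0
    z1 = 0.0
    P00 = p0
    P01 = 0.0
    P11 = p1
    for i in range(obs.shape[0]):
        if is_start[i]:
            z0 = 0.0
            z1 = 0.0
            P00 = p0
            P01 = 0.0
            P11 = p1
        else:
            dt = dts[i]
            dl = lam1 - lam2
            if abs(dl) < 1e-12 * abs(lam1):
                # repeated-root limit: Phi = e^(lam dt) (I + (A - lam I) dt)
                lam = 0.5 * (lam1 + lam2)
                e = math.exp(lam * dt)
                F00 = e * (1.0 - lam * dt)
                F01 = e * dt
                F10 = e * (-pq - lam) * dt
                F11 = e * (1.0 + lam * dt)
            else:
                e1 = math.exp(lam1 * dt)
                e2 = math.exp(lam2 * dt)
                F00 = (lam1 * e2 - lam2 * e1) / dl
                F01 = (e1 - e2) / dl
                F10 = -pq * F01
                F11 = (lam1 * e1 - lam2 * e2) / dl
            # Q = P_inf - Phi P_inf Phi^T  (P_inf = diag(p0, p1))
            Q00 = p0 - (F00 * F00 * p0 + F01 * F01 * p1)
            Q01 = -(F00 * F10 * p0 + F01 * F11 * p1)
            Q11 = p1 - (F10 * F10 * p0 + F11 * F11 * p1)
            # predict
            nz0 = F00 * z0 + F01 * z1
            nz1 = F10 * z0 + F11 * z1
            T00 = F00 * P00 + F01 * P01
            T01 = F00 * P01 + F01 * P11
            T10 = F10 * P00 + F11 * P01
            T11 = F10 * P01 + F11 * P11
            P00 = T00 * F00 + T01 * F01 + Q00
            P01 = T00 * F10 + T01 * F11 + Q01
            P11 = T10 * F10 + T11 * F11 + Q11
            z0 = nz0
            z1 = nz1
        S = P00
        if S < var_floor:
            S = var_floor
        if S <= 0.0 or not math.isfinite(S):
            return _BIG_NEG
        r = obs[i] - z0
        ll += -0.5 * (_LOG2PI + math.log(S) + r * r / S)
        # exact conditioning on the observation (no measurement error)
        K1 = P01 / S
        z0 = obs[i]
        z1 = z1 + K1 * r
        P11 = P11 - K1 * P01
        P00 = 0.0
        P01 = 0.0
        if P11 < 0.0:
            P11 = 0.0
    return ll


@njit(cache=False)
def iou_axis_loglik(dts, obs, is_start, sigma_v2, tau_v, var_floor):
    """IOU log-likelihood for one axis, conditional on each segment's
    first fix (velocity initialized from its stationary distribution)."""
    if sigma_v2 <= 0.0 or tau_v <= 0.0:
        return _BIG_NEG
    ll = 0.0
    z0 = 0.0
    z1 = 0.0
    P00 = 0.0
    P01 = 0.0
    P11 = sigma_v2
    for i in range(obs.shape[0]):
        if is_start[i]:
            z0 = obs[i]
            z1 = 0.0
            P00 = 0.0
            P01 = 0.0
            P11 = sigma_v2
            continue
        dt = dts[i]
        phi = math.exp(-dt / tau_v)
        a = tau_v * (1.0 - phi)
        Q00 = sigma_v2 * tau_v * tau_v * (
            2.0 * dt / tau_v - 3.0 + 4.0 * phi - phi * phi)
        Q01 = sigma_v2 * tau_v * (1.0 - phi) * (1.0 - phi)
        Q11 = sigma_v2 * (1.0 - phi * phi)
        # predict with Phi = [[1, a], [0, phi]]
        nz0 = z0 + a * z1
        nz1 = phi * z1
        T00 = P00 + a * P01
        T01 = P01 + a * P11
        T11 = phi * P01
        T12 = phi * P11
        P00 = T00 + T01 * a + Q00
        P01 = T01 * phi + Q01
        P11 = T12 * phi + Q11
        z0 = nz0
        z1 = nz1
        S = P00
        if S < var_floor:
            S = var_floor
        if S <= 0.0 or not math.isfinite(S):
            return _BIG_NEG
        r = obs[i] - z0
        ll += -0.5 * (_LOG2PI + math.log(S) + r * r / S)
        K1 = P01 / S
        z0 = obs[i]
        z1 = z1 + K1 * r
        P11 = P11 - K1 * P01
        P00 = 0.0
        P01 = 0.0
        if P11 < 0.0:
            P11 = 0.0
    return ll
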