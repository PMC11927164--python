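"""Independent dense-covariance Gaussian oracles.

Explicit closed-form process covariances and a brute-force multivariate
Gaussian log-density; deliberately independent of the package's filtering
implementation so the two likelihood routes can be cross-checked.
"""

import numpy as np


def ou_cov(times, sigma2, tau_p):
    lag = np.abs(times[:, None] - times[None, :])
    return sigma2 * np.exp(-lag / tau_p)


def ouf_cov(times, sigma2, tau_p, tau_v):
    lag = np.abs(times[:, None] - times[None, :])
    return sigma2 * (tau_p * np.exp(-lag / tau_p)
                     - tau_v * np.exp(-lag / tau_v)) / (tau_p - tau_v)


def iou_cov(times, sigma_v2, tau_v):
    """Covariance of positions relative to a known start at times[0] with
    stationary initial velocity: for elapsed s <= t,
    sv2 tv (2 s - tv (1 - e^(-s/tv)) - tv (e^(-(t-s)/tv) - e^(-t/tv)))."""
    el = times - times[0]
    s = np.minimum(el[:, None], el[None, :])
    t = np.maximum(el[:, None], el[None, :])
    return sigma_v2 * tau_v * (
        2.0 * s - tau_v * (1.0 - np.exp(-s / tau_v))
        - tau_v * (np.exp(-(t - s) / tau_v) - np.exp(-t / tau_v)))


def dense_gauss_loglik(y, C):
    """log N(y; 0, C) via slogdet (the brute-force GP oracle)."""
    n = y.shape[0]
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet
                         + y @ np.linalg.solve(C, y)))


def dense_loglik_for(track, family, **p):
    """Dense-covariance log-likelihood of one track (both axes)."""
    t = track.times
    if family == "OU":
        C = ou_cov(t, p["sigma2"], p["tau_p"])
        pos = track.positions
    elif family == "OUF":
        C = ouf_cov(t, p["sigma2"], p["tau_p"], p["tau_v"])
        pos = track.positions
    else:
        C = iou_cov(t, p["sigma_v2"], p["tau_v"])[1:, 1:]
        pos = track.positions[1:] - track.positions[0]
    return sum(dense_gauss_loglik(np.ascontiguousarray(pos[:, ax]), C)
               for ax in range(2))
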