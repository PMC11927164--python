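"""Penalized location-scale regression with smooth covariate effects.

Both the mean and the dispersion of the response are modeled as sums of
penalized spline smooths of covariates (a small GAMLSS):

- ``GammaLS`` — strictly positive responses (home-range areas).  The
  response is Gamma with mean ``mu`` (log link) and scale ``s`` (log link)
  under the convention Var(y) = s * mu^2, i.e. shape 1/s.
- ``BetaLS`` — responses strictly inside (0, 1) (NDVI-like indices).  Mean
  ``m`` (logit link) and precision ``phi`` (log link), with
  Var(y) = m (1 - m) / (1 + phi).

Smooths are cubic (quadratic at k = 3) B-spline bases with second-difference
penalties and a sum-to-zero identifiability constraint absorbed into the
columns; two-covariate interactions use the tensor product of constrained
marginal bases, which excludes both main effects.  Coefficients are
estimated by penalized maximum likelihood with full Newton iterations
(analytic gradient and Hessian, step halving), and the smoothing weights
are chosen by AIC over a log-spaced grid.  Uncertainty is propagated by
drawing coefficient vectors from a multivariate Gaussian centered at the
penalized MLE with the inverse penalized Hessian as covariance, mirroring
the usual empirical-Bayes posterior for penalized regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import digamma, polygamma, gammaln, expit

__all__ = [
    "SmoothTerm",
    "LSModelSpec",
    "LSFit",
    "PosteriorDraws",
    "build_smooth_basis",
    "fit_ls_model",
    "posterior_draws",
    "predict_surface",
]


# ---------------------------------------------------------------------------
# smooth bases

def _bspline_knots(x: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Knot vector giving exactly k basis functions of the given degree,
    with interior knots at quantiles of x."""
    n_interior = k - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int,
                    ) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    M = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return M


@dataclass
class SmoothBasis:
    """A constrained smooth basis: design columns, penalty and the metadata
    needed to rebuild the columns at new covariate values."""

    X: np.ndarray          # (n, k-1) constrained design
    S: np.ndarray          # (k-1, k-1) PSD penalty
    knots: np.ndarray
    degree: int
    Z: np.ndarray          # (k, k-1) constraint null-space transform
    X_raw: np.ndarray      # (n, k) unconstrained B-spline design

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return _bspline_design(np.asarray(x, float), self.knots,
                               self.degree) @ self.Z


def build_smooth_basis(x, k: int) -> SmoothBasis:
    """Penalized spline basis for one covariate.

    B-splines of degree 3 (degree 2 when k = 3) with k basis functions,
    second-difference penalty, and the sum-to-zero constraint over the
    observed covariate values absorbed via a QR null-space transform, which
    leaves k - 1 identifiable columns.
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError("k must be >= 3")
    if np.unique(x).size < k:
        raise ValueError(f"need at least k={k} distinct covariate values, "
                         f"got {np.unique(x).size}")
    degree = 3 if k >= 4 else 2
    knots = _bspline_knots(x, k, degree)
    X_raw = _bspline_design(x, knots, degree)
    D = np.diff(np.eye(k), n=2, axis=0)
    S_raw = D.T @ D
    c = X_raw.mean(axis=0)
    # null space of the constraint c^T beta = 0
    Q, _ = np.linalg.qr(c[:, None], mode="complete")
    Z = Q[:, 1:]
    return SmoothBasis(X=X_raw @ Z, S=Z.T @ S_raw @ Z, knots=knots,
                       degree=degree, Z=Z, X_raw=X_raw)


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


@dataclass(frozen=True)
class SmoothTerm:
    """A smooth model term: one covariate, or a two-covariate tensor
    interaction (which excludes the main effects, like a ti() term)."""

    covariates: tuple[str, ...]
    k: int = 5

    def __post_init__(self) -> None:
        if len(self.covariates) not in (1, 2):
            raise ValueError("SmoothTerm takes 1 or 2 covariates")

    @property
    def label(self) -> str:
        return ("s(" if len(self.covariates) == 1 else "ti(") + \
            ",".join(self.covariates) + ")"


@dataclass(frozen=True)
class LSModelSpec:
    """Specification of a location-scale model.

    ``smoothing`` is either "auto" (AIC grid search) or a sequence of fixed
    penalty weights, one per term, applied to the mean-block terms and then
    the scale-block terms.
    """

    family: str                       # "GammaLS" | "BetaLS"
    response: str
    mean_terms: tuple[SmoothTerm, ...]
    scale_terms: tuple[SmoothTerm, ...] = ()
    smoothing: str | tuple[float, ...] = "auto"

    def __post_init__(self) -> None:
        if self.family not in ("GammaLS", "BetaLS"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class _TermCols:
    term: SmoothTerm
    sl: slice                         # columns in the block design
    bases: list                       # 1 or 2 SmoothBasis
    S: np.ndarray                     # penalty on those columns
    ranges: dict                      # covariate -> (lo, hi) training range


def _build_block(data: dict, terms) -> tuple[np.ndarray, list[_TermCols]]:
    n = len(next(iter(data.values())))
    cols = [np.ones((n, 1))]
    metas: list[_TermCols] = []
    start = 1
    for term in terms:
        for c in term.covariates:
            if c not in data:
                raise ValueError(f"covariate {c!r} not in data")
        if len(term.covariates) == 1:
            b = build_smooth_basis(np.asarray(data[term.covariates[0]], float),
                                   term.k)
            X, S, bases = b.X, b.S, [b]
        else:
            b1 = build_smooth_basis(
                np.asarray(data[term.covariates[0]], float), term.k)
            b2 = build_smooth_basis(
                np.asarray(data[term.covariates[1]], float), term.k)
            X = _row_kron(b1.X, b2.X)
            I1 = np.eye(b1.X.shape[1])
            I2 = np.eye(b2.X.shape[1])
            S = np.kron(b1.S, I2) + np.kron(I1, b2.S)
            bases = [b1, b2]
        p = X.shape[1]
        ranges = {c: (float(np.min(data[c])), float(np.max(data[c])))
                  for c in term.covariates}
        metas.append(_TermCols(term=term, sl=slice(start, start + p),
                               bases=bases, S=S, ranges=ranges))
        cols.append(X)
        start += p
    return np.concatenate(cols, axis=1), metas


def _eval_block(metas: list[_TermCols], p_block: int, newdata: dict,
                ) -> tuple[np.ndarray, np.ndarray]:
    n = len(next(iter(newdata.values())))
    X = np.zeros((n, p_block))
    X[:, 0] = 1.0
    extrap = np.zeros(n, dtype=bool)
    for m in metas:
        vals = [np.asarray(newdata[c], float) for c in m.term.covariates]
        for v, c in zip(vals, m.term.covariates):
            lo, hi = m.ranges[c]
            extrap |= (v < lo) | (v > hi)
        if len(m.bases) == 1:
            X[:, m.sl] = m.bases[0].evaluate(vals[0])
        else:
            X[:, m.sl] = _row_kron(m.bases[0].evaluate(vals[0]),
                                   m.bases[1].evaluate(vals[1]))
    return X, extrap


# ---------------------------------------------------------------------------
# family log-likelihoods (per-observation value plus eta-scale derivatives)

def _gamma_ls(y, eta1, eta2):
    # Newton overshoots can produce transient non-finite values; they are
    # rejected by the step-halving line search, so warnings are suppressed
    with np.errstate(all="ignore"):
        mu = np.exp(eta1)
        s = np.exp(eta2)
        k = 1.0 / s
        theta = mu * s
        lny = np.log(y)
        ll = (k - 1.0) * lny - y / theta - k * np.log(theta) - gammaln(k)
        d1 = y / theta - k
        A = y / mu - lny + np.log(theta) - 1.0 + digamma(k)
        d2 = k * A
        h11 = -y / theta
        h12 = -y / theta + k
        h22 = -d2 + k - polygamma(1, k) * k * k
    return ll, d1, d2, h11, h12, h22


def _beta_ls(y, eta1, eta2):
    with np.errstate(all="ignore"):
        return _beta_ls_inner(y, eta1, eta2)


def _beta_ls_inner(y, eta1, eta2):
    m = expit(eta1)
    phi = np.exp(eta2)
    a = m * phi
    b = (1.0 - m) * phi
    lny = np.log(y)
    ln1y = np.log1p(-y)
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * lny \
        + (b - 1.0) * ln1y
    u = lny - ln1y
    gm = phi * (digamma(b) - digamma(a) + u)          # dll/dm
    w = m * (1.0 - m)
    d1 = w * gm
    gphi = digamma(phi) - m * digamma(a) - (1.0 - m) * digamma(b) \
        + m * lny + (1.0 - m) * ln1y
    d2 = phi * gphi
    d2m = -phi * phi * (polygamma(1, a) + polygamma(1, b))  # d2ll/dm2
    h11 = w * w * d2m + d1 * (1.0 - 2.0 * m)
    dgm_dphi = (digamma(b) - digamma(a) + u) + phi * (
        (1.0 - m) * polygamma(1, b) - m * polygamma(1, a))
    h12 = w * phi * dgm_dphi
    dgphi_dphi = polygamma(1, phi) - m * m * polygamma(1, a) \
        - (1.0 - m) ** 2 * polygamma(1, b)
    h22 = d2 + phi * phi * dgphi_dphi
    return ll, d1, d2, h11, h12, h22


_FAMILIES = {"GammaLS": _gamma_ls, "BetaLS": _beta_ls}


# ---------------------------------------------------------------------------
# fitting

@dataclass
class LSFit:
    """A fitted location-scale model."""

    spec: LSModelSpec
    coefficients: np.ndarray
    coef_cov: np.ndarray
    lambdas: np.ndarray               # one per term (mean block then scale)
    edf: dict                         # term label -> effective df
    deviance: float
    log_likelihood: float
    converged: bool
    n_obs: int
    p_mean: int
    mean_metas: list = field(repr=False, default_factory=list)
    scale_metas: list = field(repr=False, default_factory=list)
    newton_trace: np.ndarray | None = field(repr=False, default=None)
    medians: dict = field(default_factory=dict)

    def design(self, newdata: dict):
        p_scale = self.coefficients.size - self.p_mean
        Xm, ex1 = _eval_block(self.mean_metas, self.p_mean, newdata)
        Xs, ex2 = _eval_block(self.scale_metas, p_scale, newdata)
        return Xm, Xs, ex1 | ex2


def _null_penalty(S: np.ndarray) -> np.ndarray:
    """Projector onto the penalty's null space (e.g. the linear part of a
    second-difference penalty), used as an extra shrinkage component so a
    term can be penalized entirely out of the model."""
    w, V = np.linalg.eigh((S + S.T) / 2)
    null = V[:, w < 1e-10 * max(w.max(), 1.0)]
    return null @ null.T


def _penalty_components(metas_m, metas_s, p_m, p_s):
    """Per-component full-coefficient penalty matrices.

    Each term contributes two components: its curvature penalty and the
    projector on that penalty's null space (so a term can be shrunk out of
    the model entirely); components are returned with their column slice.
    """
    p = p_m + p_s
    components = []
    for off, metas in ((0, metas_m), (p_m, metas_s)):
        for m in metas:
            sl = slice(off + m.sl.start, off + m.sl.stop)
            for block in (m.S, _null_penalty(m.S)):
                Sfull = np.zeros((p, p))
                Sfull[sl, sl] = block
                components.append((sl, Sfull))
    return components


def _penalized_newton(y, Xm, Xs, fam, S, beta0, max_iter=200, tol=1e-9):
    """Minimize the penalized negative log-likelihood by full Newton with
    step halving; returns (beta, pnll, H_unpen, trace, converged)."""
    p_m = Xm.shape[1]
    beta = beta0.copy()

    def parts(b):
        with np.errstate(all="ignore"):
            ll, d1, d2, h11, h12, h22 = fam(y, Xm @ b[:p_m], Xs @ b[p_m:])
            pnll = -np.sum(ll) + 0.5 * b @ S @ b
            g = np.concatenate([-Xm.T @ d1, -Xs.T @ d2]) + S @ b
        return pnll, g, (h11, h12, h22)

    def hessian(b, h):
        h11, h12, h22 = h
        H = np.empty((b.size, b.size))
        H[:p_m, :p_m] = Xm.T @ (-h11[:, None] * Xm)
        H[:p_m, p_m:] = Xm.T @ (-h12[:, None] * Xs)
        H[p_m:, :p_m] = H[:p_m, p_m:].T
        H[p_m:, p_m:] = Xs.T @ (-h22[:, None] * Xs)
        return H + S

    pnll, g, h = parts(beta)
    trace = [pnll]
    converged = False
    for _ in range(max_iter):
        H = hessian(beta, h)
        ridge = 0.0
        for _try in range(8):
            try:
                step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), g)
                if g @ step > 0:
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = 1e-6 * np.trace(H) / H.shape[0] if ridge == 0 else ridge * 100
        else:
            step = g / max(np.linalg.norm(g), 1.0)
        alpha = 1.0
        for _half in range(40):
            cand = beta - alpha * step
            new_pnll, new_g, new_h = parts(cand)
            if np.isfinite(new_pnll) and new_pnll <= pnll + 1e-12:
                break
            alpha *= 0.5
        else:
            converged = True  # cannot decrease further
            break
        improve = pnll - new_pnll
        beta, pnll, g, h = cand, new_pnll, new_g, new_h
        trace.append(pnll)
        if improve < tol * (1.0 + abs(pnll)) and np.linalg.norm(g) < 1e-5 * (
                1.0 + abs(pnll)):
            converged = True
            break
    H_unpen = hessian(beta, h) - S
    return beta, pnll, H_unpen, np.array(trace), converged


def _init_beta(y, fam_name, p_m, p_s):
    beta = np.zeros(p_m + p_s)
    if fam_name == "GammaLS":
        mu0 = float(np.mean(y))
        s0 = max(float(np.var(y)) / mu0 ** 2, 1e-4)
        beta[0] = math.log(mu0)
        beta[p_m] = math.log(s0)
    else:
        m0 = float(np.mean(y))
        v0 = max(float(np.var(y)), 1e-8)
        phi0 = max(m0 * (1 - m0) / v0 - 1.0, 1e-2)
        beta[0] = math.log(m0 / (1 - m0))
        beta[p_m] = math.log(phi0)
    return beta


_LAMBDA_GRID = 10.0 ** np.arange(-3.0, 7.0)


def fit_ls_model(data, spec: LSModelSpec) -> LSFit:
    """Fit a penalized Gamma or Beta location-scale model.

    ``data`` is a mapping (or DataFrame) of equal-length arrays containing
    the response and every covariate named in the spec.  Responses must be
    strictly positive (GammaLS) or strictly inside (0, 1) (BetaLS); Beta
    responses sitting exactly on a boundary are shrunk toward the interior
    by (y (n-1) + 0.5) / n with a warning.
    """
    if hasattr(data, "columns"):
        data = {c: np.asarray(data[c]) for c in data.columns}
    else:
        data = {k: np.asarray(v) for k, v in data.items()}
    y = np.asarray(data[spec.response], dtype=float)
    n = y.shape[0]
    if spec.family == "GammaLS":
        if np.any(y <= 0):
            raise ValueError("GammaLS responses must be strictly positive")
    else:
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("BetaLS responses must lie in [0, 1]")
        if np.any(y == 0) or np.any(y == 1):
            warnings.warn("Beta responses on the boundary shrunk by "
                          "(y(n-1)+0.5)/n", UserWarning)
            y = (y * (n - 1) + 0.5) / n
    fam = _FAMILIES[spec.family]
    Xm, metas_m = _build_block(data, spec.mean_terms)
    Xs, metas_s = _build_block(data, spec.scale_terms)
    p_m, p_s = Xm.shape[1], Xs.shape[1]
    n_terms = len(metas_m) + len(metas_s)
    if n < p_m + p_s:
        raise ValueError("fewer observations than coefficients")

    beta0 = _init_beta(y, spec.family, p_m, p_s)

    # normalize every penalty component by the likelihood curvature on its
    # own coefficient block, so smoothing weights are dimensionless and one
    # log-spaced grid serves any response scale or sample size
    _, _, H0, _, _ = _penalized_newton(
        y, Xm, Xs, fam, np.zeros((p_m + p_s, p_m + p_s)), beta0, max_iter=0)
    components = []
    for sl, Sfull in _penalty_components(metas_m, metas_s, p_m, p_s):
        curv = max(float(np.trace(H0[sl, sl])), 1e-12)
        pen = max(float(np.trace(Sfull[sl, sl])), 1e-12)
        components.append(Sfull * (curv / pen))

    def fit_at(lambdas, start):
        S = np.zeros_like(H0)
        for lam, Sfull in zip(lambdas, components):
            S += lam * Sfull
        beta, pnll, H_unpen, trace, conv = _penalized_newton(
            y, Xm, Xs, fam, S, start)
        return beta, pnll, H_unpen, trace, conv, S, components

    n_comp = 2 * n_terms  # curvature + null-space shrinkage per term
    if spec.smoothing == "auto" and n_terms > 0:
        # start from a light penalty (rich fit) and let the AIC sweeps
        # shrink terms; starting heavy risks a degenerate local optimum
        # where one block absorbs all structure
        lambdas = np.full(n_comp, 1e-2)
        lambdas[1::2] = 1e-3
        beta = beta0
        for _sweep in range(2):
            for ci in range(n_comp):
                best = (np.inf, lambdas[ci])
                for lam in _LAMBDA_GRID:
                    trial = lambdas.copy()
                    trial[ci] = lam
                    b, pnll, H_unpen, _, _, S, _ = fit_at(trial, beta)
                    nll = pnll - 0.5 * b @ S @ b
                    Hp = H_unpen + S
                    try:
                        edf = float(np.trace(np.linalg.solve(Hp, H_unpen)))
                    except np.linalg.LinAlgError:
                        continue
                    aic = 2.0 * nll + 2.0 * edf
                    if aic < best[0]:
                        best = (aic, lam)
                        beta = b
                lambdas[ci] = best[1]
    elif spec.smoothing == "auto":
        lambdas = np.zeros(0)
    else:
        per_term = np.asarray(spec.smoothing, dtype=float)
        if per_term.shape[0] != n_terms:
            raise ValueError(f"need {n_terms} smoothing weights")
        lambdas = np.repeat(per_term, 2)

    beta, pnll, H_unpen, trace, conv, S, per_term = fit_at(lambdas, beta0)
    Hp = H_unpen + S
    # ridge-repair if the penalized Hessian is numerically singular
    try:
        cov = np.linalg.inv(Hp)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh((Hp + Hp.T) / 2)
        ridge = max(1e-8, -1.1 * w.min()) if w.min() < 1e-10 else 1e-8
        cov = np.linalg.pinv(Hp + ridge * np.eye(Hp.shape[0]))
    F = cov @ H_unpen                 # edf matrix
    edf = {}
    labels = [m.term.label for m in metas_m] + \
        [m.term.label for m in metas_s]
    offs = [0] * len(metas_m) + [p_m] * len(metas_s)
    for lab, off, m in zip(labels, offs,
                           list(metas_m) + list(metas_s)):
        sl = slice(off + m.sl.start, off + m.sl.stop)
        key = ("mean:" if off == 0 else "scale:") + lab
        edf[key] = float(np.sum(np.diag(F)[sl]))
    nll = pnll - 0.5 * beta @ S @ beta
    medians = {}
    for m in list(metas_m) + list(metas_s):
        for c in m.term.covariates:
            medians[c] = float(np.median(np.asarray(data[c], float)))
    return LSFit(spec=spec, coefficients=beta, coef_cov=(cov + cov.T) / 2,
                 lambdas=lambdas, edf=edf, deviance=2.0 * nll,
                 log_likelihood=-nll, converged=conv, n_obs=n, p_mean=p_m,
                 mean_metas=metas_m, scale_metas=metas_s,
                 newton_trace=trace, medians=medians)


# ---------------------------------------------------------------------------
# posterior simulation and prediction

@dataclass
class PosteriorDraws:
    draws: np.ndarray
    seed: int | None = None


def posterior_draws(fit: LSFit, n_draws: int,
                    rng: np.random.Generator | int | None = None,
                    ) -> PosteriorDraws:
    """Multivariate-Gaussian coefficient draws centered at the fit.

    A non-positive-semidefinite covariance (numerical artifact) is repaired
    by clipping negative eigenvalues to zero, with a warning.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    C = fit.coef_cov
    w, V = np.linalg.eigh((C + C.T) / 2)
    if np.any(w < -1e-10 * np.max(np.abs(w))):
        warnings.warn("coef_cov not PSD; clipping negative eigenvalues")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    Z = rng.standard_normal((n_draws, fit.coefficients.size))
    draws = fit.coefficients + Z @ L.T
    return PosteriorDraws(draws=draws, seed=seed)


def _inv_mean_link(fam: str, eta):
    return np.exp(eta) if fam == "GammaLS" else expit(eta)


def predict_surface(fit: LSFit, draws: PosteriorDraws, newdata: dict):
    """Pointwise mean/scale predictions with 95% credible bounds.

    Returns a DataFrame over ``newdata`` rows with the inverse-linked mean
    (point estimate and 2.5/50/97.5 posterior percentiles), the scale
    response, and an ``extrapolated`` flag for points beyond the training
    covariate hull (returned, not suppressed).
    """
    import pandas as pd

    newdata = {k: np.atleast_1d(np.asarray(v)) for k, v in newdata.items()}
    Xm, Xs, extrap = fit.design(newdata)
    b = fit.coefficients
    p_m = fit.p_mean
    eta_m = draws.draws[:, :p_m] @ Xm.T
    eta_s = draws.draws[:, p_m:] @ Xs.T
    mu = _inv_mean_link(fit.spec.family, eta_m)
    sc = np.exp(eta_s)
    lo, med, hi = np.percentile(mu, [2.5, 50.0, 97.5], axis=0)
    slo, smed, shi = np.percentile(sc, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame({
        **{k: v for k, v in newdata.items()},
        "mean": _inv_mean_link(fit.spec.family, Xm @ b[:p_m]),
        "mean_lo95": lo, "mean_med": med, "mean_hi95": hi,
        "scale": np.exp(Xs @ b[p_m:]),
        "scale_lo95": slo, "scale_med": smed, "scale_hi95": shi,
        "extrapolated": extrap,
    })
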