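"""Stochastic resource environments.

Resources are treated as a random variable R whose distribution at time t is
set by a pair of deterministic-in-law functions: a mean trajectory mu(t) and a
variance trajectory sigma2(t).  Five named temporal patterns are supported
(constant, linear, cyclical, drifting, erratic); the first three are fully
deterministic, the last two are frozen realizations of a seeded stochastic
process, so evaluation is reproducible and never consumes caller RNG state.

Resource amounts are drawn from a Gamma distribution (strictly positive
amounts, e.g. forage biomass) or a Beta distribution (quantities bounded in
(0, 1), e.g. NDVI), both parameterized directly by their first two moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioSpec",
    "MomentPair",
    "GridSpec",
    "evaluate_scenario",
    "gamma_from_moments",
    "beta_from_moments",
    "sample_resource",
    "cell_index",
    "scenario_to_dict",
    "scenario_from_dict",
    "dump_scenarios_csv",
]

SCENARIO_KINDS = ("constant", "linear", "cyclical", "drifting", "erratic")

#: positivity clamp floor for the stochastic patterns (resource units);
#: Gamma moments require strictly positive mean and variance
CLAMP_FLOOR = 1e-6

#: number of internal lattice points used by drifting/erratic patterns
LATTICE_SIZE = 101

_REQUIRED_PARAMS = {
    "constant": ("level",),
    "linear": ("intercept", "slope"),
    "cyclical": ("baseline", "amplitude", "period"),
    "drifting": ("baseline", "step_sd"),
    "erratic": ("median", "sdlog"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named temporal pattern for mu(t) or sigma2(t).

    Parameters
    ----------
    kind
        One of ``constant``, ``linear``, ``cyclical``, ``drifting``,
        ``erratic``.
    params
        Pattern-specific parameters:

        - constant: ``level``
        - linear: ``intercept``, ``slope``
        - cyclical: ``baseline``, ``amplitude``, ``period`` (optional
          ``phase``, default 0)
        - drifting: ``baseline``, ``step_sd`` (positive-clamped Gaussian
          random walk on a fixed internal time lattice, linearly
          interpolated between lattice points)
        - erratic: ``median``, ``sdlog`` (independent log-normal draw per
          lattice point, piecewise-constant between points)
    applies_to
        ``"mean"`` or ``"variance"`` — which moment trajectory this is.
    seed
        Required for ``drifting``/``erratic``; ignored otherwise.
    window
        Closed time window ``(t0, t1)`` over which the scenario is declared.
    """

    kind: str
    params: dict
    applies_to: str = "mean"
    seed: int | None = None
    window: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.applies_to not in ("mean", "variance"):
            raise ValueError("applies_to must be 'mean' or 'variance'")
        missing = [k for k in _REQUIRED_PARAMS[self.kind] if k not in self.params]
        if missing:
            raise ValueError(f"{self.kind} scenario missing params {missing}")
        if self.kind in ("drifting", "erratic") and self.seed is None:
            raise ValueError(f"{self.kind} scenario requires a seed")
        t0, t1 = self.window
        if not t1 > t0:
            raise ValueError("window must satisfy t1 > t0")

    # frozen dataclass with a dict field: hash by identity-relevant content
    def __hash__(self) -> int:  # pragma: no cover - trivial
        return hash((self.kind, tuple(sorted(self.params.items())),
                     self.applies_to, self.seed, self.window))


def _lattice(spec: ScenarioSpec) -> np.ndarray:
    t0, t1 = spec.window
    return np.linspace(t0, t1, LATTICE_SIZE)


def _lattice_values(spec: ScenarioSpec) -> np.ndarray:
    """Frozen realization of a drifting/erratic pattern on the lattice."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "drifting":
        steps = rng.normal(0.0, spec.params["step_sd"], LATTICE_SIZE - 1)
        walk = spec.params["baseline"] + np.concatenate([[0.0], np.cumsum(steps)])
        return np.maximum(walk, CLAMP_FLOOR)
    # erratic: independent positive draw per lattice time
    draws = rng.lognormal(math.log(spec.params["median"]),
                          spec.params["sdlog"], LATTICE_SIZE)
    return np.maximum(draws, CLAMP_FLOOR)


def evaluate_scenario(spec: ScenarioSpec, t):
    """Evaluate mu(t) or sigma2(t) at scalar or array ``t``.

    Deterministic kinds consume no RNG state; drifting/erratic are
    bit-reproducible functions of ``spec.seed``.  Raises ``ValueError`` if
    ``t`` falls outside the declared window or the evaluated value is not
    strictly positive.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    t0, t1 = spec.window
    if np.any(t_arr < t0) or np.any(t_arr > t1):
        raise ValueError(f"t outside declared window {spec.window} for "
                         f"{spec.kind} scenario")
    p = spec.params
    if spec.kind == "constant":
        out = np.full_like(t_arr, float(p["level"]))
    elif spec.kind == "linear":
        out = p["intercept"] + p["slope"] * t_arr
    elif spec.kind == "cyclical":
        phase = p.get("phase", 0.0)
        out = p["baseline"] + p["amplitude"] * np.sin(
            2.0 * np.pi * t_arr / p["period"] + phase)
    elif spec.kind == "drifting":
        out = np.interp(t_arr, _lattice(spec), _lattice_values(spec))
    else:  # erratic: piecewise constant on the lattice (floor index)
        lat = _lattice(spec)
        vals = _lattice_values(spec)
        idx = np.clip(np.searchsorted(lat, t_arr, side="right") - 1,
                      0, LATTICE_SIZE - 1)
        out = vals[idx]
    if np.any(out <= 0.0):
        bad = t_arr[np.asarray(out) <= 0.0][0]
        raise ValueError(
            f"{spec.kind} scenario ({spec.applies_to}) evaluated non-positive "
            f"at t={bad}")
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class MomentPair:
    """A (mean, variance) request for a resource distribution."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.mean > 0.0):
            raise ValueError(f"mean must be positive, got {self.mean}")
        if not (self.variance > 0.0):
            raise ValueError(f"variance must be positive, got {self.variance}")


def gamma_from_moments(m: MomentPair) -> tuple[float, float]:
    """Shape/scale of the Gamma distribution with the requested moments.

    shape = mean^2 / variance, scale = variance / mean; the coefficient of
    variation alone determines the shape.
    """
    shape = m.mean * m.mean / m.variance
    scale = m.variance / m.mean
    return shape, scale


def beta_from_moments(m: MomentPair) -> tuple[float, float]:
    """(alpha, beta) of the Beta distribution with the requested moments.

    Requires mean in (0, 1) and variance < mean*(1-mean); with
    nu = mean*(1-mean)/variance - 1, alpha = mean*nu and beta = (1-mean)*nu.
    """
    if not (0.0 < m.mean < 1.0):
        raise ValueError(f"Beta mean must lie in (0,1), got {m.mean}")
    bound = m.mean * (1.0 - m.mean)
    if not (m.variance < bound):
        raise ValueError(
            f"Beta variance must be below mean*(1-mean)={bound:.6g}, got "
            f"{m.variance} (degenerate/overdispersed request)")
    nu = bound / m.variance - 1.0
    return m.mean * nu, (1.0 - m.mean) * nu


def sample_resource(m: MomentPair, family: str, rng: np.random.Generator,
                    size: int | tuple | None = None):
    """Draw resource amounts with the requested moments.

    Gamma draws are strictly positive; Beta draws lie strictly inside (0, 1)
    (boundary draws, possible only through floating-point underflow, are
    nudged to the nearest representable interior value).
    """
    if family == "Gamma":
        shape, scale = gamma_from_moments(m)
        return rng.gamma(shape, scale, size)
    if family == "Beta":
        a, b = beta_from_moments(m)
        draws = rng.beta(a, b, size)
        tiny = np.finfo(float).tiny
        return np.clip(draws, tiny, 1.0 - 1e-16)
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class GridSpec:
    """Origin-anchored partition of the plane into half-open square cells."""

    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.cell_size > 0.0):
            raise ValueError("cell_size must be positive")


def cell_index(position, grid: GridSpec):
    """Integer cell index of planar position(s) under floor indexing.

    Points on a cell boundary belong to the cell on the +x/+y side.  Accepts
    a single (x, y) pair or an (n, 2) array; returns an int pair or an
    (n, 2) int array.
    """
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates passed to cell_index")
    ox, oy = grid.origin
    idx = np.floor((pos - np.array([ox, oy])) / grid.cell_size).astype(np.int64)
    if pos.ndim == 1:
        return int(idx[0]), int(idx[1])
    return idx


# ---------------------------------------------------------------------------
# serialization

def scenario_to_dict(spec: ScenarioSpec) -> dict:
    d = {"kind": spec.kind, "params": dict(spec.params),
         "applies_to": spec.applies_to, "window": list(spec.window)}
    if spec.seed is not None:
        d["seed"] = spec.seed
    return d


def scenario_from_dict(d: dict) -> ScenarioSpec:
    known = {"kind", "params", "applies_to", "seed", "window"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scenario keys {sorted(unknown)}")
    return ScenarioSpec(kind=d["kind"], params=dict(d["params"]),
                        applies_to=d.get("applies_to", "mean"),
                        seed=d.get("seed"),
                        window=tuple(d.get("window", (0.0, 100.0))))


def dump_scenarios_csv(mean_spec: ScenarioSpec, var_spec: ScenarioSpec,
                       times: Iterable[float], path) -> None:
    """Write the evaluated (t, mean, variance) trajectories to CSV."""
    import pandas as pd

    t = np.asarray(list(times), dtype=float)
    pd.DataFrame({
        "t": t,
        "mean": evaluate_scenario(mean_spec, t),
        "variance": evaluate_scenario(var_spec, t),
    }).to_csv(path, index=False)
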