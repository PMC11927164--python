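"""Exact simulation of continuous-time Gaussian movement and foraging.

Three movement families are supported, all with independent, identically
parameterized planar axes:

- ``IOU`` — integrated Ornstein-Uhlenbeck: OU-correlated velocity with
  decorrelation timescale tau_velocity and stationary per-axis velocity
  variance sigma_velocity; the position is the integral of the velocity, so
  the process is endlessly diffusive (exploratory, memoryless movement).
- ``OU`` — stationary position process with crossing timescale tau_position
  and stationary per-axis positional variance sigma_position (range
  residency, uncorrelated velocity).
- ``OUF`` — OU position with additionally OU-correlated velocity
  (tau_position > tau_velocity); per-axis positional autocovariance
  sigma_position * (tau_p e^(-lag/tau_p) - tau_v e^(-lag/tau_v)) / (tau_p - tau_v).

Sampling uses the exact joint Gaussian transition of the (position,
velocity) state over each time step — there is no Euler discretization
error, and halving the step leaves the law of the sampled positions
unchanged.

Foraging: a track is walked in time order over an origin-anchored grid;
every entry into a cell different from the currently occupied one yields one
independent Gamma resource draw (resources do not deplete, so revisits are
rewarded afresh).  The track is truncated at the first fix where cumulative
collection reaches the satiety target C; tracks that never reach satiety are
censored at their maximum duration and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import lfilter

from .resources import GridSpec, MomentPair, cell_index, gamma_from_moments

__all__ = [
    "MovementParams",
    "Track",
    "ForagingConfig",
    "TrackSegment",
    "simulate_iou",
    "simulate_ou",
    "simulate_ouf",
    "simulate_movement",
    "forage_truncate",
    "simulate_session",
]


@dataclass(frozen=True)
class MovementParams:
    """Parameters of a continuous-time movement model.

    ``sigma_position`` is the stationary per-axis positional variance
    (area units), ``sigma_velocity`` the stationary per-axis velocity
    variance (IOU parameterization).  For OUF both timescales are required
    with ``tau_position > tau_velocity``.
    """

    family: Literal["IOU", "OU", "OUF"]
    tau_position: float | None = None
    tau_velocity: float | None = None
    sigma_position: float | None = None
    sigma_velocity: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("IOU", "OU", "OUF"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "IOU":
            if not (self.tau_velocity and self.tau_velocity > 0):
                raise ValueError("IOU requires tau_velocity > 0")
            if not (self.sigma_velocity and self.sigma_velocity > 0):
                raise ValueError("IOU requires sigma_velocity > 0")
        else:
            if not (self.tau_position and self.tau_position > 0):
                raise ValueError(f"{self.family} requires tau_position > 0")
            if not (self.sigma_position and self.sigma_position > 0):
                raise ValueError(f"{self.family} requires sigma_position > 0")
        if self.family == "OUF":
            if not (self.tau_velocity and self.tau_velocity > 0):
                raise ValueError("OUF requires tau_velocity > 0")
            if not self.tau_position > self.tau_velocity:
                raise ValueError("OUF requires tau_position > tau_velocity")


@dataclass
class Track:
    """Timestamped planar positions (optionally with velocities)."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.times.shape[0], 2):
            raise ValueError("positions must be (n, 2) matching times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times))
                and np.all(np.isfinite(self.positions))):
            raise ValueError("non-finite values in track")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def slice(self, start: int, stop: int) -> "Track":
        vel = None if self.velocities is None else self.velocities[start:stop]
        return Track(self.times[start:stop], self.positions[start:stop], vel)


def _iou_step_moments(params: MovementParams, dt: float):
    """Exact one-step transition of the IOU (position, velocity) state."""
    tau, sv2 = params.tau_velocity, params.sigma_velocity
    phi = np.exp(-dt / tau)
    a = tau * (1.0 - phi)  # position loading on current velocity
    q_vv = sv2 * (1.0 - phi * phi)
    q_xv = sv2 * tau * (1.0 - phi) ** 2
    q_xx = sv2 * tau * tau * (2.0 * dt / tau - 3.0 + 4.0 * phi - phi * phi)
    return phi, a, np.array([[q_xx, q_xv], [q_xv, q_vv]])


def simulate_iou(params: MovementParams, duration: float, dt: float,
                 start=(0.0, 0.0), rng: np.random.Generator | None = None,
                 ) -> Track:
    """Exact IOU track on a regular time grid starting at ``start``.

    The initial velocity is drawn from its stationary distribution, so the
    per-axis position variance at elapsed time t is exactly
    ``2 sigma_v^2 tau_v (t - tau_v (1 - e^(-t/tau_v)))``.
    """
    if params.family != "IOU":
        raise ValueError("params.family must be IOU")
    if dt <= 0 or duration < 0:
        raise ValueError("require dt > 0 and duration >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    if n_steps == 0:
        return Track(times, np.array([start], dtype=float),
                     np.atleast_2d(rng.normal(
                         0.0, np.sqrt(params.sigma_velocity), 2)))
    phi, a, Q = _iou_step_moments(params, dt)
    L = np.linalg.cholesky(Q)
    pos = np.empty((n_steps + 1, 2))
    vel = np.empty((n_steps + 1, 2))
    for ax in range(2):
        v0 = rng.normal(0.0, np.sqrt(params.sigma_velocity))
        eta = rng.standard_normal((n_steps, 2)) @ L.T  # (eta_x, eta_v)
        v_rest, _ = lfilter([1.0], [1.0, -phi], eta[:, 1], zi=[phi * v0])
        v = np.concatenate([[v0], v_rest])
        dx = a * v[:-1] + eta[:, 0]
        pos[:, ax] = start[ax] + np.concatenate([[0.0], np.cumsum(dx)])
        vel[:, ax] = v
    return Track(times, pos, vel)


def _ouf_matrices(params: MovementParams):
    """Eigen-structure and stationary covariance of the OUF state."""
    tp, tv, s2 = params.tau_position, params.tau_velocity, params.sigma_position
    lam = np.array([-1.0 / tp, -1.0 / tv])
    V = np.array([[1.0, 1.0], lam])  # columns are eigenvectors (1, lambda)
    Vinv = np.linalg.inv(V)
    P_inf = np.diag([s2, s2 / (tp * tv)])
    return lam, V, Vinv, P_inf


def simulate_ouf(params: MovementParams, duration: float, dt: float,
                 rng: np.random.Generator | None = None,
                 center=(0.0, 0.0), initial_state: np.ndarray | None = None,
                 ) -> Track:
    """Exact stationary OUF track on a regular time grid.

    Started from the stationary distribution around ``center`` unless
    ``initial_state`` (a (2, 2) array of per-axis (position, velocity),
    positions relative to center) is supplied — used to stitch
    piecewise-stationary blocks continuously.
    """
    if params.family != "OUF":
        raise ValueError("params.family must be OUF")
    if dt <= 0 or duration < 0:
        raise ValueError("require dt > 0 and duration >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    lam, V, Vinv, P_inf = _ouf_matrices(params)
    if initial_state is None:
        L0 = np.linalg.cholesky(P_inf)
        z0 = rng.standard_normal((2, 2)) @ L0.T  # rows: axis; cols: (x, v)
    else:
        z0 = np.asarray(initial_state, dtype=float).copy()
    if n_steps == 0:
        pos = z0[:, 0] + np.asarray(center, dtype=float)
        return Track(times, pos[None, :], z0[:, 1][None, :])
    Phi = V @ np.diag(np.exp(lam * dt)) @ Vinv
    Q = P_inf - Phi @ P_inf @ Phi.T
    Q = (Q + Q.T) / 2.0
    # decouple the recursion in eigencoordinates: w' = e^(lam dt) w + noise
    Qw = Vinv @ Q @ Vinv.T
    Lw = np.linalg.cholesky(Qw + 1e-300 * np.eye(2))
    decay = np.exp(lam * dt)
    pos = np.empty((n_steps + 1, 2))
    vel = np.empty((n_steps + 1, 2))
    for ax in range(2):
        w0 = Vinv @ z0[ax]
        eta = rng.standard_normal((n_steps, 2)) @ Lw.T
        w = np.empty((n_steps + 1, 2))
        for comp in range(2):
            rest, _ = lfilter([1.0], [1.0, -decay[comp]], eta[:, comp],
                              zi=[decay[comp] * w0[comp]])
            w[:, comp] = np.concatenate([[w0[comp]], rest])
        z = w @ V.T  # back to (x, v)
        pos[:, ax] = z[:, 0] + center[ax]
        vel[:, ax] = z[:, 1]
    return Track(times, pos, vel)


def simulate_ou(params: MovementParams, duration: float, dt: float,
                rng: np.random.Generator | None = None,
                center=(0.0, 0.0)) -> Track:
    """Exact stationary OU track (uncorrelated velocity) on a regular grid."""
    if params.family != "OU":
        raise ValueError("params.family must be OU")
    if dt <= 0 or duration < 0:
        raise ValueError("require dt > 0 and duration >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    s2, tp = params.sigma_position, params.tau_position
    phi = np.exp(-dt / tp)
    q = s2 * (1.0 - phi * phi)
    pos = np.empty((n_steps + 1, 2))
    for ax in range(2):
        x0 = rng.normal(0.0, np.sqrt(s2))
        eta = rng.normal(0.0, np.sqrt(q), n_steps)
        rest, _ = lfilter([1.0], [1.0, -phi], eta, zi=[phi * x0])
        pos[:, ax] = np.concatenate([[x0], rest]) + center[ax]
    return Track(times, pos)


def simulate_movement(params: MovementParams, duration: float, dt: float,
                      rng: np.random.Generator | None = None, **kw) -> Track:
    """Family dispatch for the three simulators."""
    if params.family == "IOU":
        return simulate_iou(params, duration, dt, rng=rng, **kw)
    if params.family == "OUF":
        return simulate_ouf(params, duration, dt, rng=rng, **kw)
    return simulate_ou(params, duration, dt, rng=rng, **kw)


@dataclass(frozen=True)
class ForagingConfig:
    """Satiety target C (resource units) and censoring horizon."""

    satiety: float
    max_duration: float
    collection_rule: Literal["every_entry", "first_entry"] = "every_entry"

    def __post_init__(self) -> None:
        if not self.satiety > 0:
            raise ValueError("satiety must be positive")
        if not self.max_duration > 0:
            raise ValueError("max_duration must be positive")


@dataclass
class TrackSegment:
    """A satiety-truncated (or censored) foraging track."""

    track: Track
    collect_times: np.ndarray
    collect_cells: np.ndarray
    collect_amounts: np.ndarray
    censored: bool
    segment_id: int = 0

    @property
    def total_collected(self) -> float:
        return float(np.sum(self.collect_amounts))

    @property
    def n_collections(self) -> int:
        return int(self.collect_amounts.shape[0])


def forage_truncate(track: Track, grid: GridSpec, family: str,
                    m: MomentPair, cfg: ForagingConfig,
                    rng: np.random.Generator) -> TrackSegment:
    """Collect resources along a track and truncate at satiety.

    One independent draw per entry into a cell different from the current
    one (``every_entry``; revisited cells yield fresh draws because
    resources do not deplete).  ``first_entry`` restricts rewards to
    never-before-visited cells (sensitivity mode).  Truncation happens at
    the first fix where cumulative collection reaches ``cfg.satiety``;
    otherwise the segment is censored at the end of the track.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if family != "Gamma":
        raise ValueError("foraging draws are Gamma-distributed")
    cells = cell_index(track.positions, grid)
    if len(track) == 1:
        changed = np.zeros(0, dtype=bool)
    else:
        changed = np.any(cells[1:] != cells[:-1], axis=1)
    entry_idx = np.nonzero(changed)[0] + 1
    if cfg.collection_rule == "first_entry":
        seen = {tuple(cells[0])}
        keep = []
        for i in entry_idx:
            key = tuple(cells[i])
            if key not in seen:
                seen.add(key)
                keep.append(i)
        entry_idx = np.asarray(keep, dtype=np.int64)
    shape, scale = gamma_from_moments(m)
    amounts = rng.gamma(shape, scale, entry_idx.shape[0])
    cum = np.cumsum(amounts)
    hit = np.nonzero(cum >= cfg.satiety)[0]
    if hit.size:
        k = int(hit[0])
        stop_fix = int(entry_idx[k])
        sl = slice(0, k + 1)
        truncated = track.slice(0, stop_fix + 1)
        censored = False
    else:
        sl = slice(0, entry_idx.shape[0])
        truncated = track
        censored = True
    return TrackSegment(
        track=truncated,
        collect_times=track.times[entry_idx[sl]],
        collect_cells=cells[entry_idx[sl]],
        collect_amounts=amounts[sl],
        censored=censored,
    )


def simulate_session(n_tracks: int, params: MovementParams, grid: GridSpec,
                     m: MomentPair, cfg: ForagingConfig,
                     rng: np.random.Generator, dt: float) -> list[TrackSegment]:
    """Independent foraging tracks from a common origin.

    Each of the ``n_tracks`` tracks is an exact IOU realization started at
    (0, 0) with stationary initial velocity, independently foraged and
    truncated.  Tracks use child RNG streams spawned from ``rng``, so any
    single track is reproducible in isolation; the return-to-origin
    interlude between tracks is not simulated — independence between
    segments is the contract.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    segments = []
    children = rng.spawn(n_tracks)
    for i, child in enumerate(children):
        track = simulate_iou(params, cfg.max_duration, dt,
                             start=(0.0, 0.0), rng=child)
        seg = forage_truncate(track, grid, "Gamma", m, cfg, child)
        seg.segment_id = i
        segments.append(seg)
    return segments
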