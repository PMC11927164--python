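"""Movement simulation: exactness of the sampled processes and foraging."""

import math

import numpy as np
import pytest

from stochrange.movement import (ForagingConfig, MovementParams, Track,
                                 forage_truncate, simulate_iou,
                                 simulate_ouf, simulate_session)
from stochrange.resources import GridSpec, MomentPair

IOU = MovementParams("IOU", tau_velocity=1.0, sigma_velocity=2.0)
OUF = MovementParams("OUF", tau_position=4.0, tau_velocity=0.5,
                     sigma_position=3.0)


def iou_var(t, sv2=2.0, tv=1.0):
    return 2.0 * sv2 * tv * (t - tv * (1.0 - math.exp(-t / tv)))


class TestIOU:
    def test_zero_duration_single_point(self, rng):
        tr = simulate_iou(IOU, 0.0, 0.1, start=(1.0, -2.0), rng=rng)
        assert len(tr) == 1
        np.testing.assert_array_equal(tr.positions[0], [1.0, -2.0])

    def test_position_variance_matches_closed_form(self, rng):
        # stationary-velocity initial condition => known MSD at all lags
        n = 2000
        dt = 0.25
        tracks = np.array([simulate_iou(IOU, 5.0, dt, rng=r).positions
                           for r in rng.spawn(n)])
        for t in (0.5, 1.0, 5.0):
            i = int(round(t / dt))
            emp = 0.5 * (tracks[:, i, 0].var() + tracks[:, i, 1].var())
            assert emp == pytest.approx(iou_var(t), rel=0.05)

    def test_velocity_autocorrelation(self, rng):
        tr = simulate_iou(IOU, 2000.0, 0.2, rng=rng)
        v = tr.velocities[:, 0]
        for lag_steps, lag in ((1, 0.2), (5, 1.0)):
            emp = np.mean(v[:-lag_steps] * v[lag_steps:])
            assert emp == pytest.approx(2.0 * math.exp(-lag), rel=0.1)

    def test_dt_invariance_of_position_law(self, rng):
        # halving dt leaves the distribution at shared times unchanged
        # (exact transitions): compare variances at t=2 within MC error
        n = 1500
        va = np.array([simulate_iou(IOU, 2.0, 0.5, rng=r).positions[-1, 0]
                       for r in rng.spawn(n)]).var()
        vb = np.array([simulate_iou(IOU, 2.0, 0.25, rng=r).positions[-1, 0]
                       for r in rng.spawn(n)]).var()
        se = iou_var(2.0) * math.sqrt(2.0 / n)
        assert abs(va - vb) < 4.0 * se

    def test_bad_arguments(self, rng):
        with pytest.raises(ValueError):
            simulate_iou(IOU, 1.0, -0.1, rng=rng)
        with pytest.raises(ValueError):
            simulate_iou(OUF, 1.0, 0.1, rng=rng)


class TestOUF:
    def test_stationary_variance(self, rng):
        tr = simulate_ouf(OUF, 6000.0, 0.5, rng=rng)
        emp = 0.5 * (tr.positions[:, 0].var() + tr.positions[:, 1].var())
        assert emp == pytest.approx(3.0, rel=0.1)

    def test_ou_limit_of_autocovariance(self, rng):
        # tau_v -> 0: empirical autocovariance approaches the OU form
        p = MovementParams("OUF", tau_position=4.0, tau_velocity=0.004,
                           sigma_position=3.0)
        tr = simulate_ouf(p, 8000.0, 0.5, rng=rng)
        x = tr.positions[:, 0]
        lag = 8  # 4 time units = tau_p
        emp = np.mean(x[:-lag] * x[lag:])
        assert emp == pytest.approx(3.0 * math.exp(-1.0), rel=0.15)

    def test_zero_mean(self, rng):
        tr = simulate_ouf(OUF, 6000.0, 0.5, rng=rng)
        se = math.sqrt(3.0 / (6000.0 / 4.0))  # ~ESS range crossings
        assert abs(tr.positions[:, 0].mean()) < 4.0 * se

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau_position > tau_velocity"):
            MovementParams("OUF", tau_position=0.5, tau_velocity=4.0,
                           sigma_position=1.0)

    def test_block_stitching_is_continuous(self, rng):
        a = simulate_ouf(OUF, 10.0, 0.5, rng=rng)
        state = np.column_stack([a.positions[-1], a.velocities[-1]])
        b = simulate_ouf(OUF, 10.0, 0.5, rng=rng, initial_state=state)
        np.testing.assert_allclose(b.positions[0], a.positions[-1])


class TestSimulatorOracle:
    """Entrywise comparison of replicate 3-point track covariance with the
    analytic process covariance (the simulator exactness contract)."""

    def test_iou_three_point_covariance(self, rng):
        n = 4000
        times = np.array([0.0, 0.7, 1.4])
        reps = np.array([simulate_iou(IOU, 1.4, 0.7, rng=r).positions[:, 0]
                         for r in rng.spawn(n)])
        emp = np.cov(reps[:, 1:], rowvar=False)
        sv2, tv = 2.0, 1.0
        el = times[1:]
        s = np.minimum(el[:, None], el[None, :])
        t = np.maximum(el[:, None], el[None, :])
        th = sv2 * tv * (2 * s - tv * (1 - np.exp(-s / tv))
                         - tv * (np.exp(-(t - s) / tv) - np.exp(-t / tv)))
        np.testing.assert_allclose(emp, th, rtol=0.1)

    def test_ouf_three_point_covariance(self, rng):
        n = 4000
        reps = np.array([simulate_ouf(OUF, 2.0, 1.0, rng=r).positions[:, 0]
                         for r in rng.spawn(n)])
        emp = np.cov(reps, rowvar=False)
        lag = np.abs(np.arange(3.0)[:, None] - np.arange(3.0)[None, :])
        tp, tv, s2 = 4.0, 0.5, 3.0
        th = s2 * (tp * np.exp(-lag / tp) - tv * np.exp(-lag / tv)) / (tp - tv)
        np.testing.assert_allclose(emp, th, rtol=0.1)


class TestForaging:
    grid = GridSpec(cell_size=1.0)

    @staticmethod
    def _line_track(n, step=1.0):
        t = np.arange(n, dtype=float)
        pos = np.column_stack([t * step, np.zeros(n)])
        return Track(t, pos)

    def test_deterministic_reward_equal_to_satiety(self, rng):
        cfg = ForagingConfig(satiety=5.0, max_duration=100.0)
        seg = forage_truncate(self._line_track(20), self.grid, "Gamma",
                              MomentPair(5.0, 1e-12), cfg, rng)
        assert seg.n_collections == 1
        assert not seg.censored
        assert len(seg.track) == 2  # truncated at the first cell change

    def test_deterministic_reward_count(self, rng):
        cfg = ForagingConfig(satiety=5.0, max_duration=100.0)
        seg = forage_truncate(self._line_track(30), self.grid, "Gamma",
                              MomentPair(0.51, 1e-12), cfg, rng)
        assert seg.n_collections == 10  # ceil(C/mu) deterministic draws

    def test_never_leaving_cell_is_censored(self, rng):
        t = np.arange(10.0)
        tr = Track(t, np.full((10, 2), 0.25))
        cfg = ForagingConfig(satiety=1.0, max_duration=100.0)
        seg = forage_truncate(tr, self.grid, "Gamma", MomentPair(1.0, 1.0),
                              cfg, rng)
        assert seg.n_collections == 0
        assert seg.censored

    def test_conservation_and_truncation_bound(self, rng):
        cfg = ForagingConfig(satiety=3.0, max_duration=100.0)
        seg = forage_truncate(self._line_track(50), self.grid, "Gamma",
                              MomentPair(1.0, 2.0), cfg, rng)
        assert seg.total_collected == pytest.approx(
            float(np.sum(seg.collect_amounts)))
        assert seg.censored == (seg.total_collected < cfg.satiety)
        assert seg.collect_times[-1] <= seg.track.times[-1]

    def test_revisits_rewarded_but_not_in_first_entry_mode(self, rng):
        t = np.arange(5.0)
        pos = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 0.5], [1.5, 0.5],
                        [2.5, 0.5]])
        tr = Track(t, pos)
        cfg = ForagingConfig(satiety=1e9, max_duration=100.0)
        every = forage_truncate(tr, self.grid, "Gamma", MomentPair(1, 1),
                                cfg, rng)
        cfg2 = ForagingConfig(satiety=1e9, max_duration=100.0,
                              collection_rule="first_entry")
        first = forage_truncate(tr, self.grid, "Gamma", MomentPair(1, 1),
                                cfg2, np.random.default_rng(0))
        assert every.n_collections == 4   # every cell change
        assert first.n_collections == 2   # only novel cells

    def test_empty_track_rejected(self, rng):
        tr = Track(np.empty(0), np.empty((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            forage_truncate(tr, self.grid, "Gamma", MomentPair(1, 1),
                            ForagingConfig(satiety=1, max_duration=1), rng)


class TestSession:
    params = MovementParams("IOU", tau_velocity=1.0, sigma_velocity=1.0)
    grid = GridSpec(cell_size=0.3)
    cfg = ForagingConfig(satiety=2.0, max_duration=10.0)

    def test_reproducible_under_seed(self):
        a = simulate_session(10, self.params, self.grid, MomentPair(1, 1),
                             self.cfg, np.random.default_rng(11), dt=0.2)
        b = simulate_session(10, self.params, self.grid, MomentPair(1, 1),
                             self.cfg, np.random.default_rng(11), dt=0.2)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.track.positions,
                                          sb.track.positions)
            np.testing.assert_array_equal(sa.collect_amounts,
                                          sb.collect_amounts)

    def test_all_segments_start_at_origin(self, rng):
        segs = simulate_session(25, self.params, self.grid, MomentPair(1, 1),
                                self.cfg, rng, dt=0.2)
        for seg in segs:
            np.testing.assert_array_equal(seg.track.positions[0], [0.0, 0.0])

    def test_deterministic_reward_collection_count(self, rng):
        # variance -> 0 and mean C/k: every segment makes exactly k draws
        k = 4
        cfg = ForagingConfig(satiety=2.0, max_duration=50.0)
        segs = simulate_session(20, self.params, self.grid,
                                MomentPair(1.02 * 2.0 / k, 1e-12), cfg, rng,
                                dt=0.2)
        counts = {s.n_collections for s in segs if not s.censored}
        assert counts == {k}

    def test_mean_truncation_time_nonincreasing_in_abundance(self, rng):
        # the H = C/R intuition: richer environments end search sooner
        durs = []
        for mu in (0.5, 1.0, 2.0):
            segs = simulate_session(40, self.params, self.grid,
                                    MomentPair(mu, 1e-12), self.cfg,
                                    rng, dt=0.2)
            durs.append(np.mean([s.track.duration for s in segs]))
        assert durs[0] >= durs[1] >= durs[2]
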