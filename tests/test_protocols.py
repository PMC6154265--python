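"""Coupled simulation runs, outcome metrics, and sweep machinery."""

import numpy as np
import pytest

from airwaymorph import (ChallengeProtocol, SimulationConfig,
                         agonist_resolution_time, parameter_sweep,
                         remodelled_inner_radius, run_simulation, set_param)
from airwaymorph.protocols import SimulationResult


def make_result(t, k_total, last_event=0.0, xi1=None):
    """Minimal hand-built result for metric unit tests."""
    n = len(t)
    z = np.zeros(n)
    proto = ChallengeProtocol(event_times=(last_event,) if last_event or last_event == 0.0
                              else (), horizon=max(t[-1], 50.0), challenge_window=50.0)
    cfg = SimulationConfig(protocol=proto)
    return SimulationResult(
        t=np.asarray(t, float), mu=z, k_total=np.asarray(k_total, float),
        xi1=np.asarray(xi1, float) if xi1 is not None else np.full(n, 1.8),
        xi_int=z, r1=z, wall_thickness=z, mean_phi_c=z, mean_phi_p=z,
        mean_phi_e=z, min_tau=z, max_tau=z, config=cfg)


class TestRunSimulation:
    def test_zero_challenges_stays_at_steady_state(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(
            protocol=ChallengeProtocol(event_times=(), horizon=20.0,
                                       challenge_window=0.0))
        res = run_simulation(cfg)
        assert np.all(res.mu == 0.0)
        assert np.all(res.k_total == 0.0)
        assert np.ptp(res.xi1) == 0.0
        assert np.ptp(res.r1) < 1e-12

    def test_deterministic(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(
            protocol=ChallengeProtocol.periodic(omega=0.2, horizon=12.0,
                                                challenge_window=10.0))
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(a.xi1, b.xi1)
        assert np.array_equal(a.k_total, b.k_total)
        assert np.array_equal(a.mu, b.mu)

    def test_mode_algebra(self, coarse_cfg_factory):
        """inflammation_only is identical to combined with a_k = 0."""
        proto = ChallengeProtocol.periodic(omega=0.2, horizon=12.0,
                                           challenge_window=10.0)
        cfg_mode = coarse_cfg_factory(protocol=proto,
                                      challenge_mode="inflammation_only")
        cfg_manual = set_param(coarse_cfg_factory(protocol=proto), "rates.a_k", 0.0)
        a, b = run_simulation(cfg_mode), run_simulation(cfg_manual)
        assert np.array_equal(a.xi1, b.xi1)
        assert np.array_equal(a.k_total, b.k_total)

    def test_inflammation_challenges_thicken_then_recover(self, coarse_cfg_factory):
        """Wall volume rises during challenges and partially recovers after."""
        cfg = coarse_cfg_factory(challenge_mode="inflammation_only")
        res = run_simulation(cfg)
        assert not res.closed and res.aborted is None
        i50 = np.searchsorted(res.t, 50.0)
        assert res.xi1[i50] < res.xi1[0]                # inward growth by day 50
        assert res.wall_thickness[i50] > res.wall_thickness[0]
        assert res.xi1[-1] > res.xi1.min()              # partial recovery
        assert res.k_total[-1] < 1e-6                   # agonist eventually resolves

    def test_snapshots_recorded(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(
            protocol=ChallengeProtocol.periodic(omega=0.2, horizon=35.0,
                                                challenge_window=30.0),
            snapshot_days=(28.0, 30.0, 32.0), challenge_mode="inflammation_only")
        res = run_simulation(cfg)
        assert set(res.snapshots) == {28.0, 30.0, 32.0}
        snap = res.snapshots[30.0]
        assert snap["xi"].shape == snap["tau"].shape == (2 * cfg.nodes_per_layer,)


class TestMetrics:
    def test_remodelled_radius_unchallenged_is_reference(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(
            protocol=ChallengeProtocol(event_times=(1.0,), horizon=10.0,
                                       challenge_window=2.0),
            challenge_mode="inflammation_only")
        res = run_simulation(set_param(cfg, "rates.a_mu", 0.0))
        assert remodelled_inner_radius(res) == pytest.approx(1.8, abs=1e-12)

    def test_remodelled_radius_interpolation_oracle(self):
        t = np.linspace(0, 10, 21)
        xi1 = 1.8 - 0.05 * t
        res = make_result(t, np.zeros_like(t), last_event=0.0, xi1=xi1)
        assert remodelled_inner_radius(res, days_post=5.0) == pytest.approx(
            np.interp(5.0, t, xi1), rel=1e-14)

    def test_remodelled_radius_needs_coverage(self):
        res = make_result([0.0, 1.0], [0.0, 0.0], last_event=0.0)
        with pytest.raises(ValueError):
            remodelled_inner_radius(res, days_post=5.0)

    def test_resolution_time_zero_when_clear(self):
        res = make_result([0, 1, 2], [0.0, 0.0, 0.0])
        rt = agonist_resolution_time(res)
        assert rt == (0.0, False)

    def test_resolution_time_exponential_crossing(self):
        """k_total = exp(-t) crosses 1e-6 at t = 6 ln 10 ~ 13.8155 days."""
        t = np.linspace(0, 20, 81)
        res = make_result(t, np.exp(-t))
        rt = agonist_resolution_time(res)
        assert not rt.censored
        assert rt.days == pytest.approx(6 * np.log(10), rel=1e-6)

    def test_resolution_time_censored(self):
        t = np.linspace(0, 20, 11)
        res = make_result(t, np.full_like(t, 0.5))
        rt = agonist_resolution_time(res)
        assert rt.censored and rt.days is None


class TestParameterSweep:
    def test_1x1_sweep_equals_single_run(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(challenge_mode="inflammation_only")
        single = run_simulation(set_param(cfg, "rates.c_dmu", 0.7))
        sweep = parameter_sweep(cfg, ("rates.c_dmu", [0.7]),
                                ("protocol.omega", [0.2]))
        assert sweep.radius[0, 0] == pytest.approx(
            remodelled_inner_radius(single), rel=1e-12)
        rt = agonist_resolution_time(single)
        assert sweep.resolution_days[0, 0] == pytest.approx(rt.days, rel=1e-12)
        assert not sweep.closed_mask[0, 0]

    def test_closed_runs_are_masked(self, coarse_cfg_factory):
        cfg = coarse_cfg_factory(challenge_mode="inflammation_only")
        sweep = parameter_sweep(cfg, ("rates.c_dmu", [0.7, 0.2]),
                                ("protocol.omega", [0.2]))
        assert not sweep.closed_mask[0, 0]
        assert sweep.closed_mask[1, 0]          # very slow clearance: closure
        assert np.isnan(sweep.radius[1, 0])     # discarded from the surface
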