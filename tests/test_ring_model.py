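"""Ring field: input, convolution, noise, integration, switch detection."""

import math

import numpy as np
import pytest

from rivalnet.params import RingParams
from rivalnet.records import durations
from rivalnet.ring_analysis import dominance_time_ring, wta_half_width
from rivalnet.ring_model import (
    FieldState,
    bimodal_input,
    detect_dominance,
    grid,
    initial_state,
    recurrent_drive,
    sample_noise,
    simulate_ring,
)


class TestBimodalInput:
    @pytest.mark.parametrize(
        "x, I0, Ia, expected",
        [
            (math.pi / 4, 0.9, 0.0, 0.9),
            (0.0, 0.9, 0.0, -0.9),
            (math.pi / 4, 0.9, 0.02, 0.92),  # right peak = I_R = I0 + Ia
            (-math.pi / 4, 0.9, 0.02, 0.88),  # left peak = I_L = I0 - Ia
        ],
    )
    def test_values(self, x, I0, Ia, expected):
        assert bimodal_input(x, I0, Ia) == pytest.approx(expected, abs=1e-12)

    def test_peaks_at_orthogonal_angles(self):
        x = grid(1024)
        I = bimodal_input(x, 0.9, 0.02)
        assert x[np.argmax(I)] == pytest.approx(math.pi / 4, abs=0.01)


class TestRecurrentDrive:
    def _brute_force(self, state, params):
        """Direct O(n^2) quadrature of the convolution (independent oracle)."""
        x, dx = state.x, np.pi / params.n_grid
        f = (state.u >= params.kappa).astype(float)
        out = np.empty_like(state.u)
        for i in range(len(x)):
            out[i] = dx * np.sum(np.cos(2 * (x[i] - x)) * state.q * f)
        return out

    @pytest.mark.parametrize("n_grid", [64, 128, 256])
    def test_matches_direct_quadrature(self, n_grid):
        rng = np.random.default_rng(12345 + n_grid)
        params = RingParams(n_grid=n_grid)
        for _ in range(5):
            state = FieldState(
                x=grid(n_grid),
                u=rng.normal(0.5, 0.5, n_grid),
                q=rng.uniform(0.3, 1.0, n_grid),
            )
            fast = recurrent_drive(state, params)
            slow = self._brute_force(state, params)
            assert np.max(np.abs(fast - slow)) <= 1e-12 * max(1.0, np.max(np.abs(slow)))

    def test_zero_activity_gives_zero_drive(self):
        params = RingParams(n_grid=128)
        state = FieldState(x=grid(128), u=np.full(128, -1.0), q=np.ones(128))
        assert np.all(recurrent_drive(state, params) == 0.0)

    def test_single_bump_analytic_form(self):
        # q=1 and activity superthreshold exactly on (pi/4-a, pi/4+a)
        # gives drive = sin(2a) sin(2x) up to rectangle-rule error
        n = 4096
        params = RingParams(n_grid=n, beta=0.0)
        x = grid(n)
        a = 0.3
        u = np.where(np.abs(x - np.pi / 4) < a, 1.0, 0.0)
        state = FieldState(x=x, u=u, q=np.ones(n))
        drive = recurrent_drive(state, params)
        expected = math.sin(2 * a) * np.sin(2 * x)
        assert np.max(np.abs(drive - expected)) < 5e-3

    def test_length_mismatch_rejected(self):
        params = RingParams(n_grid=64)
        state = FieldState(x=grid(128), u=np.zeros(128), q=np.ones(128))
        with pytest.raises(ValueError):
            recurrent_drive(state, params)


class TestSampleNoise:
    def test_zero_eps_gives_zero(self):
        p = RingParams(eps=0.0, n_grid=64)
        assert np.all(sample_noise(p, 100) == 0.0)

    def test_pointwise_variance(self):
        # cos^2 + sin^2 = 1: variance at any x equals eps*scale*dt
        p = RingParams(eps=0.04, noise_corr_scale=1.0, n_grid=32, dt=1e-3, seed=7)
        xi = sample_noise(p, 100_000)
        var = xi.var(axis=0)
        expected = p.eps * p.noise_corr_scale * p.dt
        assert np.all(np.abs(var - expected) < 5 * expected * math.sqrt(2 / 100_000))

    def test_spatial_covariance_profile(self):
        p = RingParams(eps=0.04, noise_corr_scale=math.pi, n_grid=64, dt=1e-3, seed=11)
        xi = sample_noise(p, 100_000)
        x = grid(p.n_grid)
        i, j = 5, 40
        cov = np.mean(xi[:, i] * xi[:, j])
        expected = p.eps * p.noise_corr_scale * p.dt * math.cos(x[i] - x[j])
        scale = p.eps * p.noise_corr_scale * p.dt
        assert abs(cov - expected) < 5 * scale * math.sqrt(2 / 100_000)


class TestSimulateRing:
    def test_wta_state_is_stationary(self):
        # noise- and depression-free winner-take-all bump stays put with
        # threshold crossings at pi/4 +- a
        p = RingParams(I0=0.6, Ia=0.0, kappa=0.5, beta=0.0, eps=0.0,
                       t_total=200.0, n_grid=1024)
        traj, recs = simulate_ring(p, init="wta_right", peak_stride=0)
        assert recs == []  # no switches
        a = wta_half_width(0.6, 0.0, 0.5, 0.0)
        st = traj.final_state
        for edge in (np.pi / 4 - a, np.pi / 4 + a):
            u_edge = np.interp(edge, st.x, st.u)
            assert abs(u_edge - p.kappa) < 5e-3

    def test_noise_free_rivalry_alternates_evenly(self):
        p = RingParams(I0=0.84, beta=1.0, tau=50.0, eps=0.0, t_total=700.0, seed=0)
        _, recs = simulate_ring(p, init="wta_right", peak_stride=0)
        assert len(recs) >= 6
        labs = [r.percept for r in recs]
        assert all(a != b for a, b in zip(labs, labs[1:]))
        dL, dR = durations(recs[2:], "L"), durations(recs[2:], "R")
        assert abs(dL.mean() - dR.mean()) / dR.mean() < 5e-3

    def test_fusion_state_persists(self):
        p = RingParams(I0=1.0, beta=1.0, eps=0.0, t_total=400.0)
        traj, recs = simulate_ring(p, init="fusion", peak_stride=0)
        assert recs == []
        u = traj.final_state.u
        half = p.n_grid // 2
        assert u[:half].max() > p.kappa and u[half:].max() > p.kappa

    def test_depression_resource_bounds(self):
        p = RingParams(I0=0.84, beta=1.0, eps=0.01, t_total=300.0, seed=3)
        traj, _ = simulate_ring(p, init="wta_right", snap_stride=100, peak_stride=0)
        q = traj.q_snaps
        assert np.all(q > 0.0) and np.all(q <= 1.0 + 1e-12)
        # noise-free Heaviside long-run floor is 1/(1+beta)
        p0 = RingParams(I0=0.84, beta=1.0, eps=0.0, t_total=500.0)
        traj0, _ = simulate_ring(p0, init="wta_right", snap_stride=100, peak_stride=0)
        late = traj0.q_snaps[traj0.snap_times > 100.0]
        assert late.min() >= 1.0 / (1 + p0.beta) - 1e-3

    def test_same_seed_reproduces_records(self):
        p = RingParams(I0=0.9, beta=0.0, eps=0.04, t_total=400.0, seed=42)
        _, a = simulate_ring(p, peak_stride=0)
        _, b = simulate_ring(p, peak_stride=0)
        assert [(r.percept, r.t_on, r.duration) for r in a] == [
            (r.percept, r.t_on, r.duration) for r in b
        ]

    def test_nan_state_aborts_with_step_index(self):
        p = RingParams(t_total=10.0)
        st = initial_state(p, "wta_right")
        st.u[0] = np.nan
        with pytest.raises(FloatingPointError, match="step"):
            simulate_ring(p, init=st, peak_stride=0)

    def test_dt_halving_changes_durations_below_half_percent(self):
        base = {}
        for dt in (1e-3, 5e-4):
            p = RingParams(I0=0.84, beta=1.0, eps=0.0, t_total=500.0, dt=dt)
            _, recs = simulate_ring(p, init="wta_right", peak_stride=0)
            base[dt] = durations(recs[2:]).mean()
        assert abs(base[1e-3] - base[5e-4]) / base[5e-4] < 5e-3

    def test_sigmoid_gain_approaches_heaviside(self):
        p = RingParams(I0=0.84, beta=1.0, eps=0.0, t_total=500.0, gamma=200.0)
        _, recs = simulate_ring(p, init="wta_right", peak_stride=0)
        T_sig = durations(recs[2:]).mean()
        T_h, _ = dominance_time_ring(0.84, 0.0, 0.5, 1.0, 50.0)
        assert abs(T_sig - T_h) / T_h < 0.15


class TestDetectDominance:
    def test_offline_matches_online_detector(self):
        p = RingParams(I0=0.9, beta=0.0, eps=0.04, t_total=300.0, seed=5)
        traj, online = simulate_ring(p, peak_stride=1)
        offline = detect_dominance(traj)
        assert [(r.percept, round(r.t_on, 9)) for r in online] == [
            (r.percept, round(r.t_on, 9)) for r in offline
        ]

    def test_records_tile_interval_with_alternating_labels(self):
        p = RingParams(I0=0.9, beta=0.0, eps=0.04, t_total=2000.0, seed=8)
        _, recs = simulate_ring(p, peak_stride=0)
        assert len(recs) >= 2
        for r1, r2 in zip(recs, recs[1:]):
            assert r1.percept != r2.percept
            assert r2.t_on == pytest.approx(r1.t_on + r1.duration, abs=1e-9)
        assert all(r.duration > 0 for r in recs)
        assert all(r.duration_s == pytest.approx(r.duration * 0.01) for r in recs)

    def test_empty_trajectory_rejected(self):
        p = RingParams(t_total=50.0)
        traj, _ = simulate_ring(p, peak_stride=0)
        with pytest.raises(ValueError):
            detect_dominance(traj)
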