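"""Closed-form bump/oscillation analysis against independent numerics."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from rivalnet.params import RingParams
from rivalnet.records import durations
from rivalnet.ring_analysis import (
    NoRivalryError,
    classify_regime,
    dominance_time_ring,
    fusion_half_widths,
    pre_switch_resources,
    regime_partition,
    rivalry_exists,
    solve_escape_system,
    wta_exists,
    wta_half_width,
    wta_half_width_explicit,
    _fusion_residuals,
    _threshold_residual,
)
from rivalnet.ring_model import simulate_ring


class TestWtaHalfWidth:
    def test_threshold_residual_vanishes(self):
        a = wta_half_width(0.6, 0.0, 0.5, 1.0)
        assert abs(_threshold_residual(a, 0.6, 0.0, 0.5, 1.0)) < 1e-10

    def test_rootfind_equals_explicit_branch_on_random_sweep(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            kappa = rng.uniform(0.2, 0.8)
            I0 = rng.uniform(kappa * 1.01, 1.2)
            beta = rng.uniform(0.0, 2.0)
            explicit = wta_half_width_explicit(I0, kappa, beta)
            if explicit is None:
                continue
            numeric = wta_half_width(I0, 0.0, kappa, beta)
            assert numeric is not None
            assert abs(numeric - explicit) < 1e-10
            checked += 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        kappa=st.floats(0.2, 0.8),
        dI=st.floats(0.05, 0.6),
        beta=st.floats(0.0, 2.0),
    )
    def test_explicit_branch_solves_threshold_condition(self, kappa, dI, beta):
        I0 = kappa + dI
        a = wta_half_width_explicit(I0, kappa, beta)
        assume(a is not None)
        assert abs(_threshold_residual(a, I0, 0.0, kappa, beta)) < 1e-9

    def test_negative_discriminant_reports_nonexistence(self):
        # I0 < kappa with 1 + 4(1+beta)^2 (I0^2 - kappa^2) < 0
        I0, kappa, beta = 0.2, 0.6, 1.0
        assert 1 + 4 * (1 + beta) ** 2 * (I0**2 - kappa**2) < 0
        assert wta_half_width_explicit(I0, kappa, beta) is None
        assert wta_half_width(I0, 0.0, kappa, beta) is None


class TestWtaExists:
    def test_anchor_points(self):
        assert wta_exists(0.6, 0.0, 0.5, 1.0)[0] is True
        assert wta_exists(0.84, 0.0, 0.5, 1.0)[0] is False

    def test_margin_vanishes_on_bifurcation_boundary(self):
        # find the boundary I0 where the suppressed peak reaches threshold
        from scipy.optimize import brentq

        f = lambda I0: wta_exists(I0, 0.0, 0.5, 1.0)[1]
        I0_star = brentq(f, 0.6, 0.84, xtol=1e-12)
        assert abs(wta_exists(I0_star, 0.0, 0.5, 1.0)[1]) < 1e-8


class TestFusion:
    def test_symmetric_solution_is_equal_width_with_tiny_residual(self):
        a, b = fusion_half_widths(1.0, 0.0, 0.5, 1.0)
        assert a == b
        res = _fusion_residuals([a, b], 1.0, 0.0, 0.5, 1.0)
        assert max(abs(r) for r in res) < 1e-10

    def test_asymmetric_solution_matches_grid_search(self):
        I0, Ia, kappa, beta = 1.0, 0.03, 0.5, 1.0
        a, b = fusion_half_widths(I0, Ia, kappa, beta)
        # brute-force 2D scan oracle
        grid = np.linspace(0.05, math.pi / 4 - 0.05, 200)
        A, B = np.meshgrid(grid, grid, indexing="ij")
        R = np.array(
            [
                np.abs(_fusion_residuals([ga, gb], I0, Ia, kappa, beta)).max()
                for ga, gb in zip(A.ravel(), B.ravel())
            ]
        ).reshape(A.shape)
        ia, ib = np.unravel_index(np.argmin(R), R.shape)
        step = grid[1] - grid[0]
        assert abs(grid[ia] - a) < 2 * step and abs(grid[ib] - b) < 2 * step

    def test_nonexistence_below_threshold_input(self):
        assert fusion_half_widths(0.4, 0.0, 0.5, 1.0) is None


class TestPreSwitchResources:
    def test_closed_forms_match_defining_system(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            kappa = rng.uniform(0.3, 0.6)
            I0 = rng.uniform(kappa + 0.05, kappa + 0.6)
            Ia = rng.uniform(0.0, 0.05 * I0)
            sv = pre_switch_resources(I0, Ia, kappa)
            a_num, qR_num = solve_escape_system(I0, Ia, kappa)
            assert abs(a_num - sv.aR) < 1e-8
            assert abs(qR_num - sv.qR) < 1e-8
            a_num, qL_num = solve_escape_system(I0, -Ia, kappa)
            assert abs(qL_num - sv.qL) < 1e-8

    def test_symmetric_input_collapses_to_single_value(self):
        sv = pre_switch_resources(0.84, 0.0, 0.5)
        assert sv.qR == sv.qL == sv.q0

    def test_rivalry_point_resource_in_valid_range(self):
        sv = pre_switch_resources(0.84, 0.0, 0.5)
        assert 0.5 < sv.q0 < 1.0  # (1/(1+beta), 1) at beta = 1


class TestDominanceTime:
    def test_symmetric_inputs_give_equal_times(self):
        TR, TL = dominance_time_ring(0.84, 0.0, 0.5, 1.0, 50.0)
        assert TR == TL

    def test_asymmetric_reduces_continuously_to_symmetric(self):
        T0 = dominance_time_ring(0.84, 0.0, 0.5, 1.0, 50.0)[0]
        TR, TL = dominance_time_ring(0.84, 1e-9, 0.5, 1.0, 50.0)
        assert TR == pytest.approx(T0, rel=1e-5)
        assert TL == pytest.approx(T0, rel=1e-5)

    def test_matches_noise_free_simulation_in_slow_regime(self):
        # at the slow end of the rivalry range the adiabatic result is
        # accurate to a couple of percent at tau = 50
        T_an = dominance_time_ring(0.80, 0.0, 0.5, 1.0, 50.0)[0]
        p = RingParams(I0=0.80, beta=1.0, tau=50.0, eps=0.0, t_total=700.0)
        _, recs = simulate_ring(p, init="wta_right", peak_stride=0)
        T_sim = durations(recs[2:]).mean()
        assert abs(T_sim - T_an) / T_sim < 0.02

    def test_levelt_second_proposition(self):
        # raising I_R (fixed I_L) moves T_L much more than T_R
        IL = 0.82
        base_R, base_L = dominance_time_ring(0.84, 0.02, 0.5, 1.0, 50.0)
        IR2 = 0.88
        I0, Ia = (IR2 + IL) / 2, (IR2 - IL) / 2
        TR2, TL2 = dominance_time_ring(I0, Ia, 0.5, 1.0, 50.0)
        dTR, dTL = abs(TR2 - base_R), abs(TL2 - base_L)
        assert dTL > 3 * dTR

    def test_out_of_regime_reports_no_rivalry(self):
        with pytest.raises(NoRivalryError):
            dominance_time_ring(1.2, 0.0, 0.5, 1.0, 50.0)


class TestRegimes:
    @pytest.mark.parametrize(
        "I0, expected",
        [(0.6, "winner_take_all"), (0.84, "rivalry"), (1.0, "fusion")],
    )
    def test_anchor_points(self, I0, expected):
        assert classify_regime(I0, 0.0, 0.5, 1.0).label == expected

    def test_labels_partition_and_order_along_I0(self):
        betas = np.array([1.0])
        I0s = np.linspace(0.55, 1.1, 40)
        labels = regime_partition(betas, I0s, kappa=0.5)[0]
        # one label per point, ordered wta -> rivalry -> fusion
        order = {"winner_take_all": 0, "rivalry": 1, "fusion": 2}
        codes = [order[l] for l in labels if l in order]
        assert codes == sorted(codes)

    def test_rivalry_range_widens_with_depression_strength(self):
        I0s = np.linspace(0.55, 1.1, 80)
        n_weak = sum(rivalry_exists(i, 0.0, 0.5, 0.6) for i in I0s)
        n_strong = sum(rivalry_exists(i, 0.0, 0.5, 1.5) for i in I0s)
        assert n_strong > n_weak
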