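"""Rolling ODE: hydrodynamic loads, steady states, folds, energy audit."""

import dataclasses

import numpy as np
import pytest

import catchroll as cr
from catchroll.rolling_dynamics import (
    _WorkBar,
    critical_shear_rates,
    hydrodynamic_load,
    integrate_rolling,
    rolling_rhs,
    steady_states,
)


class TestHydrodynamicLoad:
    def test_free_rolling_no_load(self, cell):
        f, m = hydrodynamic_load(cell.R * 50.0, 50.0, cell)
        assert f == pytest.approx(0.0, abs=1e-14)
        assert m == pytest.approx(0.0, abs=1e-14)

    def test_stationary_cylinder_values(self, cell):
        gamma = 100.0
        f, m = hydrodynamic_load(0.0, gamma, cell)
        assert f == pytest.approx(4 * np.pi * cell.eta * cell.R * gamma)
        assert m == pytest.approx(2 * np.pi * cell.eta * cell.R**2 * gamma)

    def test_overspeed_decelerates(self, cell):
        f, m = hydrodynamic_load(cell.R * 10.0 + 1.0, 10.0, cell)
        assert f < 0.0 and m < 0.0

    def test_inertia_ratio(self, cell):
        assert cell.J0 / (cell.m * (cell.R * 1e-6) ** 2) == pytest.approx(1.5)


class TestSteadyStates:
    def test_no_hysteresis_free_rolling_fixed_point(self, zero_work_bar):
        roots = steady_states(2.5, zero_work_bar)
        assert len(roots) == 1
        assert roots[0].v_bar == pytest.approx(2.5, rel=1e-10)
        assert roots[0].stable
        assert roots[0].residual < 1e-10

    def test_root_residuals_refined(self, diagram_catch, work_bar_catch, cell, work_catch):
        g = diagram_catch.gamma_grid[60]
        for r in steady_states(cell.gamma_bar(g, work_catch.w_qs), work_bar_catch):
            assert r.residual < 1e-8

    def test_scan_sign_changes_odd(self, work_bar_catch, cell, work_catch):
        for gamma in [20.0, 200.0, 380.0]:
            gbar = cell.gamma_bar(gamma, work_catch.w_qs)
            grid = np.linspace(1e-9, 1.2 * gbar, 4001)
            vals = rolling_rhs(grid, gbar, work_bar_catch)
            signs = np.sign(vals)
            changes = np.sum(signs[:-1] * signs[1:] < 0)
            assert changes % 2 == 1

    def test_window_has_three_roots_outer_stable(self, diagram_catch):
        gl, gu = diagram_catch.gamma_lower, diagram_catch.gamma_upper
        assert np.isfinite(gl) and np.isfinite(gu) and gl < gu
        mid = [
            roots
            for g, roots in zip(diagram_catch.gamma_grid, diagram_catch.branches)
            if gl < g < gu
        ]
        assert len(mid) > 0
        for roots in mid:
            assert len(roots) == 3
            assert roots[0].stable and roots[2].stable and not roots[1].stable

    def test_single_root_outside_window(self, diagram_catch):
        for g, roots in zip(diagram_catch.gamma_grid, diagram_catch.branches):
            if g < diagram_catch.gamma_lower - 1 or g > diagram_catch.gamma_upper + 1:
                assert len(roots) == 1

    def test_high_shear_approaches_free_rolling(self, work_bar_catch, cell, work_catch):
        gbar = cell.gamma_bar(390.0, work_catch.w_qs)
        roots = steady_states(gbar, work_bar_catch)
        assert len(roots) == 1
        assert roots[0].v_bar == pytest.approx(gbar, rel=0.10)
        # the gap to free rolling is exactly the residual hysteresis torque
        gap = gbar - roots[0].v_bar
        dw = work_bar_catch(roots[0].v_bar)
        assert gap == pytest.approx(dw / (6.0 * np.pi), rel=1e-6)

    def test_free_rolling_bounds_all_roots(self, diagram_catch, cell):
        for g, roots in zip(diagram_catch.gamma_grid, diagram_catch.branches):
            gbar = cell.gamma_bar(g, diagram_catch.w_qs)
            for r in roots:
                assert r.v_bar <= gbar * (1 + 1e-9)


class TestBranches:
    def test_descending_branch_monotone(self, diagram_catch):
        """Flow-enhanced adhesion: the branch ending at the upper fold
        slows down as the shear rate grows."""
        desc = diagram_catch.descending_branch()
        v = [x[1] for x in desc]
        assert len(v) > 5
        assert np.all(np.diff(v) < 0.0)

    def test_rolling_branch_speed_increases(self, diagram_catch):
        roll = diagram_catch.rolling_branch()
        v = [x[1] for x in roll]
        assert np.all(np.diff(v) > 0.0)

    def test_scaling_invariance_of_thresholds(self, work_catch, cell):
        """Scaling η and the work scale together leaves γ thresholds fixed."""
        gl, gu, _ = critical_shear_rates(
            work_catch, cell, gamma_scan=np.linspace(50.0, 400.0, 40)
        )
        c = 3.0
        scaled_work = cr.WorkCurve(
            vc_grid=work_catch.vc_grid,  # physical speeds are unchanged
            wa=c * work_catch.wa,
            wr=c * work_catch.wr,
            w_qs=c * work_catch.w_qs,
        )
        scaled_cell = dataclasses.replace(cell, eta=c * cell.eta)
        gl2, gu2, _ = critical_shear_rates(
            scaled_work, scaled_cell, gamma_scan=np.linspace(50.0, 400.0, 40)
        )
        assert gu2 == pytest.approx(gu, abs=0.5)
        assert gl2 == pytest.approx(gl, abs=0.5)


class TestIntegration:
    def test_zero_work_exponential_relaxation(self, zero_work_bar):
        traj = integrate_rolling(0.5, 3.0, zero_work_bar, 2.0)
        expect = 3.0 - 2.5 * np.exp(-4 * np.pi * traj.t_bar)
        assert np.max(np.abs(traj.v_bar - expect)) < 1e-7

    def test_stable_root_is_invariant(self, work_bar_catch, cell, work_catch):
        gbar = cell.gamma_bar(200.0, work_catch.w_qs)
        root = [r for r in steady_states(gbar, work_bar_catch) if r.stable][0]
        traj = integrate_rolling(root.v_bar, gbar, work_bar_catch, 1.0, audit=False)
        assert np.max(np.abs(traj.v_bar - root.v_bar)) < 1e-8

    def test_energy_conservation_along_trajectory(self, work_bar_catch, cell, work_catch):
        gbar = cell.gamma_bar(200.0, work_catch.w_qs)
        traj = integrate_rolling(0.0, gbar, work_bar_catch, 3.0)
        assert traj.energy_residual < 1e-6

    def test_oversized_step_raises(self, work_bar_catch, cell, work_catch):
        gbar = cell.gamma_bar(200.0, work_catch.w_qs)
        with pytest.raises(RuntimeError, match="step"):
            integrate_rolling(0.0, gbar, work_bar_catch, 50.0, dt_bar=0.5)
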