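"""Mean-field bond density at moving edges and works of adhesion."""

import dataclasses

import numpy as np
import pytest

import catchroll as cr
from catchroll.adhesion_work import (
    bond_density_leading,
    bond_density_trailing,
    equilibrium_density,
    quasi_static_work,
    work_curves,
)
from catchroll.bond_kinetics import bond_force, off_rate, on_rate


def frozen_rate_oracle(bond, kin, delta_of_t, t_end, xi0, n_steps=40000):
    """Independent oracle for the density equation: freeze (kon, koff) on
    fine sub-intervals and apply the exact linear relaxation step
    ξ(t+h) = ξeq + (ξ − ξeq)·exp(−(kon+koff)h)."""
    xi = xi0
    h = t_end / n_steps
    for k in range(n_steps):
        t_mid = (k + 0.5) * h
        delta = delta_of_t(t_mid)
        kon = float(on_rate(delta, bond))
        koff = float(off_rate(bond_force(delta, bond), bond))
        xi_eq = kin.xi_all * kon / (kon + koff)
        xi = xi_eq + (xi - xi_eq) * np.exp(-(kon + koff) * h)
    return xi


class TestLeadingEdge:
    @pytest.mark.parametrize("vc", [1.0, 10.0])
    def test_matches_frozen_rate_oracle(self, bond, kin, vc):
        traj = bond_density_leading(vc, kin, bond)
        delta0 = kin.resolved_delta0(bond)
        speed = kin.edge_ratio * vc * 1e3
        oracle = frozen_rate_oracle(
            bond, kin, lambda t: delta0 - speed * t, traj.t[-1], 0.0
        )
        assert traj.xi_end == pytest.approx(oracle, rel=1e-4)

    def test_density_monotone_increasing(self, bond, kin):
        for vc in [1.0, 10.0]:
            traj = bond_density_leading(vc, kin, bond)
            assert np.all(np.diff(traj.xi_t) >= -1e-9)

    def test_fast_approach_binds_nothing(self, bond, kin):
        traj = bond_density_leading(1e4, kin, bond)
        assert traj.xi_end < 1e-3 * kin.xi_all

    def test_density_bounded(self, bond, kin):
        for vc in [0.05, 1.0, 100.0]:
            traj = bond_density_leading(vc, kin, bond)
            assert np.all(traj.xi_t >= 0.0)
            assert np.all(traj.xi_t <= kin.xi_all * (1 + 1e-9))

    def test_zero_speed_redirects(self, bond, kin):
        with pytest.raises(ValueError, match="quasi_static"):
            bond_density_leading(0.0, kin, bond)


class TestTrailingEdge:
    def test_matches_frozen_rate_oracle(self, bond, kin):
        vc = 10.0
        traj = bond_density_trailing(vc, kin, bond)
        speed = kin.edge_ratio * vc * 1e3
        rest = bond.rest_separation
        # compare at an interior time (the endpoint density is ~1e-6 xi0)
        t_half = traj.t[-1] / 2.0
        oracle = frozen_rate_oracle(
            bond, kin, lambda t: rest + speed * t, t_half, float(traj.xi_t[0])
        )
        xi_half = float(np.interp(t_half, traj.t, traj.xi_t))
        assert xi_half == pytest.approx(oracle, rel=1e-4)

    def test_initial_density_limits(self, bond, kin):
        rest = bond.rest_separation
        xi_eq = equilibrium_density(rest, kin, bond)
        # slow transit: full relaxation to the contact-zone equilibrium
        slow = bond_density_trailing(1e-3, kin, bond)
        assert slow.xi_t[0] == pytest.approx(xi_eq, rel=1e-6)
        # finite speed: exact interpolation by the transit-relaxation factor
        vc = 1e4
        lead = bond_density_leading(vc, kin, bond)
        kon = float(on_rate(rest, bond))
        koff = float(off_rate(0.0, bond))
        relax = 1.0 - np.exp(-(kon + koff) * 2.0 * kin.edge_ratio * kin.R / vc)
        expected = lead.xi_end + (xi_eq - lead.xi_end) * relax
        fast = bond_density_trailing(vc, kin, bond, xi_ld_end=lead.xi_end)
        assert fast.xi_t[0] == pytest.approx(expected, rel=1e-9)
        # the relaxation correction vanishes as the transit time shrinks
        assert fast.xi_t[0] - lead.xi_end < 1e-3 * kin.xi_all

    def test_rises_then_decays_to_zero(self, bond, kin):
        """At speeds where the trailing edge starts under-equilibrated the
        density first grows by rebinding, then ruptures as the gap opens."""
        traj = bond_density_trailing(10.0, kin, bond)
        i = int(np.argmax(traj.xi_t))
        assert 0 < i < len(traj.xi_t) - 1
        assert traj.xi_t[-1] <= 1.1e-6 * traj.xi_t[0]

    def test_density_bounded(self, bond, kin):
        for vc in [0.05, 1.0, 100.0]:
            traj = bond_density_trailing(vc, kin, bond)
            assert np.all((traj.xi_t >= 0.0) & (traj.xi_t <= kin.xi_all * (1 + 1e-9)))


class TestQuasiStaticWork:
    def test_zero_density_zero_work(self, bond, kin):
        empty = dataclasses.replace(kin, xi_all=0.0)
        assert quasi_static_work(bond, empty) == 0.0

    def test_linear_in_bond_density(self, bond, kin):
        w1 = quasi_static_work(bond, kin)
        w2 = quasi_static_work(bond, dataclasses.replace(kin, xi_all=2 * kin.xi_all))
        assert w2 == pytest.approx(2.0 * w1, rel=1e-9)

    def test_both_works_converge_to_quasi_static(self, bond, kin):
        """wa and wr share the limit wQS as the rolling speed vanishes."""
        w_qs = quasi_static_work(bond, kin)
        vc = 1e-3
        lead = bond_density_leading(vc, kin, bond)
        wr = cr.receding_work(vc, kin, bond, xi_ld_end=lead.xi_end)
        assert lead.work == pytest.approx(w_qs, rel=0.02)
        assert wr == pytest.approx(w_qs, rel=0.02)


class TestWorkCurves:
    def test_advancing_monotone_nonincreasing(self, work_catch):
        assert np.all(np.diff(work_catch.wa) <= 1e-12)

    def test_advancing_vanishes_at_high_speed(self, work_catch):
        assert work_catch.wa[-1] < 1e-3 * work_catch.wa[0]

    def test_receding_unimodal(self, work_catch):
        wr = work_catch.wr
        i = int(np.argmax(wr))
        assert 0 < i < len(wr) - 1
        signs = np.sign(np.diff(wr))
        assert np.sum(np.diff(signs[signs != 0]) != 0) == 1

    def test_receding_max_exceeds_quasi_static(self, work_catch):
        assert work_catch.wr.max() > work_catch.w_qs

    def test_hysteresis_nonnegative(self, work_catch):
        assert np.all(work_catch.wr - work_catch.wa >= -1e-9)

    def test_endpoints(self, work_catch):
        assert work_catch.wa[0] == pytest.approx(work_catch.w_qs, rel=0.05)
        assert work_catch.wr[0] == pytest.approx(work_catch.w_qs, rel=0.05)
        assert work_catch.wr[-1] < 0.05 * work_catch.wr.max()

    def test_interpolant_clamps_and_matches_nodes(self, work_catch):
        wc = work_catch
        assert wc.wa_of(1e-5) == pytest.approx(wc.wa[0])
        assert wc.wr_of(1e6) == pytest.approx(wc.wr[-1])
        mid = wc.vc_grid[37]
        assert wc.wa_of(mid) == pytest.approx(wc.wa[37], rel=1e-12)

    def test_slip_curves_same_invariants(self, work_slip):
        assert np.all(np.diff(work_slip.wa) <= 1e-12)
        wr = work_slip.wr
        i = int(np.argmax(wr))
        assert 0 < i < len(wr) - 1
        assert np.all(wr - work_slip.wa >= -1e-9)
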