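"""Shared fixtures.

The expensive objects (tabulated work curves and the steady-state
continuation, for both the catch and slip-comparison bonds) are built
once per session on a moderately coarse speed grid; the physics checked
by the tests is insensitive to the tabulation density.
"""

from __future__ import annotations

import numpy as np
import pytest

import catchroll as cr
from catchroll.rolling_dynamics import _WorkBar, steady_state_diagram


@pytest.fixture(scope="session")
def bond() -> cr.BondParams:
    return cr.BondParams()


@pytest.fixture(scope="session")
def slip_bond(bond) -> cr.BondParams:
    return bond.comparison_slip()


@pytest.fixture(scope="session")
def kin() -> cr.EdgeKinematics:
    return cr.EdgeKinematics(vc=1.0)


@pytest.fixture(scope="session")
def cell() -> cr.FlowCell:
    return cr.FlowCell()


@pytest.fixture(scope="session")
def work_catch(kin, bond) -> cr.WorkCurve:
    return cr.work_curves(kin, bond, vc_grid=np.geomspace(1e-2, 1e4, 80), rtol=1e-7)


@pytest.fixture(scope="session")
def work_slip(kin, slip_bond) -> cr.WorkCurve:
    return cr.work_curves(kin, slip_bond, vc_grid=np.geomspace(1e-2, 1e4, 80), rtol=1e-7)


@pytest.fixture(scope="session")
def work_bar_catch(work_catch, cell) -> _WorkBar:
    return _WorkBar(work_catch, cell)


@pytest.fixture(scope="session")
def diagram_catch(work_catch, cell):
    return steady_state_diagram(
        work_catch, cell, np.linspace(1.0, 400.0, 120), fold_tol=0.1
    )


@pytest.fixture(scope="session")
def diagram_slip(work_slip, cell):
    return steady_state_diagram(
        work_slip, cell, np.linspace(1.0, 200.0, 120), fold_tol=0.1
    )


@pytest.fixture
def zero_work_bar():
    """No adhesion hysteresis: the rolling ODE reduces to viscous drag."""

    def wb(v_bar):
        return np.zeros_like(np.asarray(v_bar, dtype=float))

    return wb
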