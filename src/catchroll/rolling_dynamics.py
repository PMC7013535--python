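"""Cell rolling dynamics in shear flow from energy conservation.

A rigid cylindrical cell of radius R rolling without slip (ω = vc/R) in
a linear shear flow of rate γ experiences hydrodynamic loads per unit
thickness

    F = 4πηR·(γ − vc/R),    M = 2πηR²·(γ − vc/R),

while the adhesion hysteresis wr − wa exerts the resistant torque
Mr = R·(wr − wa).  Balancing the work done by the flow against kinetic
energy and adhesive dissipation gives, in nondimensional variables
v̄ = η·vc/wQS, γ̄ = η·R·γ/wQS, t̄ = η·t/m,

    dv̄/dt̄ = 4π(γ̄ − v̄) − (2/3)[w̄r(v̄) − w̄a(v̄)] .

Setting dv̄/dt̄ = 0 yields the steady-state diagram: a slow firm-adhesion
branch, a fast rolling branch asymptoting to free rolling v = Rγ, and —
between two fold points (the lower and upper critical shear rates) — a
bistable window in which the realized state depends on the loading
history of the flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .adhesion_work import WorkCurve
from .params import FlowCell

__all__ = [
    "RollingTrajectory",
    "SteadyRoot",
    "SteadyStateDiagram",
    "critical_shear_rates",
    "energy_audit",
    "hydrodynamic_load",
    "hysteresis_sweep",
    "integrate_rolling",
    "rolling_rhs",
    "steady_state_diagram",
    "steady_states",
]


def hydrodynamic_load(
    vc: float, gamma: float, cell: FlowCell
) -> tuple[float, float]:
    """Propulsive force (pN/μm) and torque (pN) per unit thickness.

    F = 4πηR(γ − vc/R), M = 2πηR²(γ − vc/R): the loads on a stationary
    cylinder scaled by the slip velocity γ − vc/R.  Inputs in μm/s and
    1/s; η in Pa·s.  (1 Pa·μm² = 1 pN/μm of force per unit thickness.)
    """
    slip = gamma - vc / cell.R  # 1/s
    f = 4.0 * np.pi * cell.eta * cell.R * slip  # Pa·μm = pN/μm²·μm = pN/μm
    m = 2.0 * np.pi * cell.eta * cell.R**2 * slip  # Pa·μm² = pN
    return f, m


class _WorkBar:
    """w̄r(v̄) − w̄a(v̄) with out-of-range evaluations clamped (warn once)."""

    def __init__(self, work: WorkCurve, cell: FlowCell):
        self.work = work
        self.cell = cell
        self._warned = False
        self._stiffness = None

    @property
    def stiffness_bar(self) -> float:
        """max |d(Δw̄)/dv̄| over the tabulated range; sets the RK4 step.

        The adhesion term, not the viscous drag, is the stiffest part of
        the rolling ODE when the hysteresis rises steeply at low speed.
        """
        if self._stiffness is None:
            v = np.geomspace(self.work.vc_grid[0], self.work.vc_grid[-1], 2000)
            dwbar = self.work.hysteresis_of(v) / self.work.w_qs
            v_bar = self.cell.eta * v / self.work.w_qs
            self._stiffness = float(np.max(np.abs(np.diff(dwbar) / np.diff(v_bar))))
        return self._stiffness

    def v_phys(self, v_bar):
        return np.asarray(v_bar) * self.work.w_qs / self.cell.eta

    def __call__(self, v_bar):
        v = self.v_phys(np.maximum(v_bar, 0.0))
        hi = self.work.vc_grid[-1]
        # below the grid both works sit at the quasi-static value, so the
        # clamp is the physically correct continuation and needs no warning
        if not self._warned and np.any(np.asarray(v) > hi):
            self._warned = True
            warnings.warn(
                "speed above tabulated work curve; using clamped endpoint values",
                stacklevel=2,
            )
        return self.work.hysteresis_of(v) / self.work.w_qs


def rolling_rhs(v_bar, gamma_bar: float, work_bar) -> NDArray[np.float64] | float:
    """dv̄/dt̄ = 4π(γ̄ − v̄) − (2/3)·Δw̄(v̄)."""
    v_bar = np.asarray(v_bar, dtype=float)
    out = 4.0 * np.pi * (gamma_bar - v_bar) - (2.0 / 3.0) * np.asarray(work_bar(v_bar))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RollingTrajectory:
    """Nondimensional rolling history under a (possibly time-varying) γ̄."""

    t_bar: NDArray[np.float64]
    v_bar: NDArray[np.float64]
    gamma_bar: NDArray[np.float64]
    energy_residual: float  # max |U2−U2(0)−U1+U3| / max(|U1|+|U2(0)|)


def energy_audit(
    t_bar: NDArray[np.float64],
    v_bar: NDArray[np.float64],
    gamma_bar: NDArray[np.float64],
    work_bar,
) -> float:
    """Post-hoc energy-conservation check of a rolling trajectory.

    In nondimensional form (energies per unit thickness scaled by
    m·wQS²/η²): flow input u1 = ∫6π(γ̄−v̄)v̄ dt̄, kinetic energy
    u2 = (3/4)v̄², adhesive dissipation u3 = ∫Δw̄·v̄ dt̄.  Returns the
    largest violation of u1 + u2(0) = u2 + u3 relative to the total
    energy throughput.
    """
    dw = np.asarray(work_bar(v_bar))
    g1 = 6.0 * np.pi * (gamma_bar - v_bar) * v_bar
    g3 = dw * v_bar
    from scipy.integrate import cumulative_simpson

    u1 = cumulative_simpson(g1, x=t_bar, initial=0.0)
    u3 = cumulative_simpson(g3, x=t_bar, initial=0.0)
    u2 = 0.75 * v_bar**2
    residual = u2 - u2[0] - u1 + u3
    scale = np.max(np.abs(u1)) + np.abs(u2[0]) + np.max(np.abs(u3))
    if scale == 0.0:
        return 0.0
    return float(np.max(np.abs(residual)) / scale)


def integrate_rolling(
    v0_bar: float,
    gamma_path,
    work_bar,
    t_end_bar: float,
    dt_bar: float | None = None,
    audit: bool = True,
) -> RollingTrajectory:
    """Classical fixed-step RK4 integration of the rolling ODE.

    ``gamma_path`` is either a constant γ̄ or a callable γ̄(t̄)
    (piecewise-constant staircases for loading-history studies).  The
    default step keeps |λ|·Δt̄ ≤ 1 for the stiffest linearized rate
    λ = 4π + (2/3)·max|dΔw̄/dv̄| (the adhesion hysteresis can be much
    stiffer than the viscous drag), and never exceeds 0.1/(4π).
    """
    if dt_bar is None:
        lam = 4.0 * np.pi
        if hasattr(work_bar, "stiffness_bar"):
            lam += (2.0 / 3.0) * work_bar.stiffness_bar
        dt_bar = min(0.02 / (4.0 * np.pi), 0.5 / lam)
    gamma_of = gamma_path if callable(gamma_path) else (lambda t: gamma_path)
    n = max(2, int(np.ceil(t_end_bar / dt_bar)) + 1)
    t = np.linspace(0.0, t_end_bar, n)
    h = t[1] - t[0]
    v = np.empty(n)
    v[0] = v0_bar
    g = np.empty(n)
    g[0] = gamma_of(0.0)

    def f(tk: float, vk: float) -> float:
        return rolling_rhs(vk, gamma_of(tk), work_bar)

    for k in range(n - 1):
        tk, vk = t[k], v[k]
        k1 = f(tk, vk)
        k2 = f(tk + 0.5 * h, vk + 0.5 * h * k1)
        k3 = f(tk + 0.5 * h, vk + 0.5 * h * k2)
        k4 = f(tk + h, vk + h * k3)
        v[k + 1] = vk + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        g[k + 1] = gamma_of(t[k + 1])
        if not np.isfinite(v[k + 1]) or abs(v[k + 1]) > 1e6 * (1.0 + abs(g[k + 1])):
            raise RuntimeError(
                "rolling integration diverged; reduce the RK4 step dt_bar"
            )
    residual = energy_audit(t, v, g, work_bar) if audit else np.nan
    return RollingTrajectory(t_bar=t, v_bar=v, gamma_bar=g, energy_residual=residual)


@dataclass(frozen=True)
class SteadyRoot:
    v_bar: float
    stable: bool
    residual: float


def _scan_grid(gamma_bar: float, n: int = 2000) -> NDArray[np.float64]:
    """v̄ scan: linear over [0, 1.2 γ̄] plus log refinement near 0.

    Free rolling bounds all steady speeds, so 1.2·γ̄ safely brackets the
    fast branch; the log points resolve the slow firm branch.
    """
    hi = 1.2 * gamma_bar
    lin = np.linspace(0.0, hi, n)
    log = np.geomspace(max(hi * 1e-8, 1e-12), hi * 0.1, 200)
    return np.unique(np.concatenate((lin, log)))


def steady_states(
    gamma_bar: float, work_bar, n_scan: int = 2000
) -> list[SteadyRoot]:
    """All steady speeds at shear rate γ̄, with linear-stability flags.

    Roots of the rhs are bracketed by a dense scan and refined by
    bisection (Brent); a root is stable when d(rhs)/dv̄ < 0 there
    (finite difference, relative step 1e-6).
    """
    from scipy.optimize import brentq

    grid = _scan_grid(gamma_bar, n_scan)
    vals = rolling_rhs(grid, gamma_bar, work_bar)
    roots: list[SteadyRoot] = []
    sign = np.sign(vals)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        r = brentq(
            lambda v: rolling_rhs(v, gamma_bar, work_bar),
            grid[i],
            grid[i + 1],
            xtol=1e-14,
            rtol=1e-12,
        )
        step = max(abs(r), 1e-6) * 1e-6
        d = (
            rolling_rhs(r + step, gamma_bar, work_bar)
            - rolling_rhs(r - step, gamma_bar, work_bar)
        ) / (2.0 * step)
        roots.append(
            SteadyRoot(
                v_bar=float(r),
                stable=bool(d < 0.0),
                residual=abs(rolling_rhs(r, gamma_bar, work_bar)),
            )
        )
    # exact roots sitting on grid nodes (e.g. v̄ = γ̄ with zero hysteresis)
    if not roots:
        j = int(np.argmin(np.abs(vals)))
        if abs(vals[j]) < 1e-12:
            roots.append(SteadyRoot(v_bar=float(grid[j]), stable=True, residual=0.0))
    return roots


@dataclass(frozen=True)
class SteadyStateDiagram:
    """Steady rolling speeds vs shear rate with branch stability.

    ``gamma_grid`` in 1/s; ``branches[i]`` lists the SteadyRoot objects
    at gamma_grid[i] (v̄ nondimensional); fold points in 1/s (NaN when
    the diagram is monostable).
    """

    gamma_grid: NDArray[np.float64]
    branches: list[list[SteadyRoot]]
    gamma_lower: float
    gamma_upper: float
    cell: FlowCell
    w_qs: float

    def v_phys(self, v_bar: float) -> float:
        return v_bar * self.w_qs / self.cell.eta

    def firm_branch(self) -> list[tuple[float, float]]:
        """(γ, v μm/s) of the slowest stable root wherever ≥ 3 roots exist
        or γ is below the bistable window."""
        out = []
        for gamma, roots in zip(self.gamma_grid, self.branches):
            stable = [r for r in roots if r.stable]
            if stable and (len(roots) >= 3 or gamma <= self.gamma_lower):
                out.append((float(gamma), self.v_phys(stable[0].v_bar)))
        return out

    def descending_branch(self) -> list[tuple[float, float]]:
        """(γ, v μm/s) of the middle root inside the bistable window.

        This is the branch that terminates at the upper fold; along it
        the steady speed *decreases* as the shear rate increases —
        the flow-enhanced-adhesion signature.  It is unstable under the
        deterministic rolling ODE (the outer two roots are the stable
        ones).
        """
        out = []
        for gamma, roots in zip(self.gamma_grid, self.branches):
            if len(roots) >= 3:
                out.append((float(gamma), self.v_phys(roots[1].v_bar)))
        return out

    def rolling_branch(self) -> list[tuple[float, float]]:
        """(γ, v μm/s) of the fastest stable root wherever it is distinct."""
        out = []
        for gamma, roots in zip(self.gamma_grid, self.branches):
            stable = [r for r in roots if r.stable]
            if stable and (len(roots) >= 3 or gamma >= self.gamma_upper):
                out.append((float(gamma), self.v_phys(stable[-1].v_bar)))
        return out


def steady_state_diagram(
    work: WorkCurve,
    cell: FlowCell,
    gamma_grid: NDArray[np.float64],
    refine_folds: bool = True,
    fold_tol: float = 0.1,
) -> SteadyStateDiagram:
    """Continuation of steady states over a physical shear-rate grid."""
    wb = _WorkBar(work, cell)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    branches = [
        steady_states(cell.gamma_bar(g, work.w_qs), wb) for g in gamma_grid
    ]
    gamma_lower = gamma_upper = float("nan")
    counts = np.array([len(b) for b in branches])
    multi = np.flatnonzero(counts >= 3)
    if multi.size and refine_folds:
        n_roots = lambda g: len(steady_states(cell.gamma_bar(g, work.w_qs), wb))
        # upper fold: firm branch disappears (3 roots -> 1 fast root)
        g_lo = gamma_grid[multi[-1]]
        g_hi = gamma_grid[min(multi[-1] + 1, len(gamma_grid) - 1)]
        gamma_upper = _bisect_transition(n_roots, g_lo, g_hi, fold_tol)
        # lower fold: rolling branch disappears (3 roots -> 1 slow root)
        g_hi2 = gamma_grid[multi[0]]
        g_lo2 = gamma_grid[max(multi[0] - 1, 0)]
        gamma_lower = _bisect_transition(
            n_roots, g_hi2, g_lo2, fold_tol
        )
    return SteadyStateDiagram(
        gamma_grid=gamma_grid,
        branches=branches,
        gamma_lower=gamma_lower,
        gamma_upper=gamma_upper,
        cell=cell,
        w_qs=work.w_qs,
    )


def _bisect_transition(n_roots, g_multi: float, g_mono: float, tol: float) -> float:
    """Bisect on root-count (3 vs 1) between a multistable and a
    monostable shear rate; returns the last multistable γ to within tol."""
    if n_roots(g_mono) >= 3:
        return float(g_mono)
    while abs(g_mono - g_multi) > tol:
        mid = 0.5 * (g_multi + g_mono)
        if n_roots(mid) >= 3:
            g_multi = mid
        else:
            g_mono = mid
    return float(g_multi)


def critical_shear_rates(
    work: WorkCurve,
    cell: FlowCell,
    gamma_scan: NDArray[np.float64] | None = None,
    fold_tol: float = 0.1,
) -> tuple[float, float, float]:
    """(γ_lower, γ_upper, v_at_upper): fold points of the diagram (1/s)
    and the firm-branch steady speed (μm/s) at the upper threshold.

    γ_upper is the largest shear rate at which the firm (low-speed)
    stable branch still exists; γ_lower the smallest at which the fast
    rolling branch exists.  Both are refined by bisection on branch
    existence to ``fold_tol`` (s⁻¹).  Returns NaNs for a monostable
    diagram (possible for uncalibrated parameters).
    """
    if gamma_scan is None:
        gamma_scan = np.linspace(1.0, 400.0, 160)
    diag = steady_state_diagram(work, cell, gamma_scan, fold_tol=fold_tol)
    if not np.isfinite(diag.gamma_upper):
        return float("nan"), float("nan"), float("nan")
    wb = _WorkBar(work, cell)
    roots = steady_states(cell.gamma_bar(diag.gamma_upper, work.w_qs), wb)
    stable = [r for r in roots if r.stable]
    v_at_upper = diag.v_phys(stable[0].v_bar) if stable else float("nan")
    return diag.gamma_lower, diag.gamma_upper, v_at_upper


def hysteresis_sweep(
    work: WorkCurve,
    cell: FlowCell,
    gamma_steps: NDArray[np.float64],
    v0_bar: float = 0.0,
    settle_tol: float = 1e-8,
    max_t_bar: float = 50.0,
) -> NDArray[np.float64]:
    """Quasi-static staircase shear-rate sweep; returns settled v̄ per step.

    At each γ the rolling ODE is integrated from the previous settled
    state until |dv̄/dt̄| < ``settle_tol``, operationalizing a loading
    history that starts from the last realized state (attachment
    history when sweeping up from γ = 0, rolling history when sweeping
    down from above the upper threshold).
    """
    wb = _WorkBar(work, cell)
    v = v0_bar
    settled = np.empty(len(gamma_steps))
    for i, gamma in enumerate(gamma_steps):
        gbar = cell.gamma_bar(float(gamma), work.w_qs)
        t_chunk = 0.5
        total = 0.0
        while abs(rolling_rhs(v, gbar, wb)) > settle_tol and total < max_t_bar:
            traj = integrate_rolling(v, gbar, wb, t_chunk, audit=False)
            v = float(traj.v_bar[-1])
            total += t_chunk
            t_chunk = min(2.0 * t_chunk, 8.0)
        settled[i] = v
    return settled
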