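"""Velocity-dependent works of adhesion at the moving contact edges.

As the cell rolls at centre speed ``vc``, the cell--substrate gap just
outside the leading edge closes at normal speed (a/R)·vc and the gap at
the trailing edge opens at (b/R)·vc, with a/R = b/R ≈ 0.05.  The mean
closed-bond density ξ obeys the mean-field (first-moment) equation

    dξ/dt = kon(δ(t))·ξall − [kon(δ(t)) + koff(f(δ(t)))]·ξ,

exact for this linear scheme of independent bonds.  The adhesive
traction is σ = kLR·(δ − lb − lbind)·ξ and the works of adhesion per
unit area swept are path integrals of the traction over the separation:

  * advancing work  wa = 0.05·vc ∫₀^{ts} σ_LD dt  (bond formation while
    the gap closes from δ0 to contact, ξ_LD(0) = 0),
  * receding work   wr = 0.05·vc ∫₀^{tc} σ_TR dt  (bond stretching and
    rupture while the gap opens, cut off when 99.9999% of the initial
    trailing bonds have broken).

The trailing-edge initial density accounts for relaxation toward the
contact-zone equilibrium during the transit time (a+b)/vc.  In the
quasi-static limit vc → 0 both works reduce to the common value wQS
computed with the bond reaction equilibrated at every separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import PchipInterpolator

from .bond_kinetics import off_rate, on_rate
from .params import BondParams, EdgeKinematics
from .units import PER_UM2_TO_PER_NM2, PN_PER_NM_TO_UJ_PER_M2, UM_PER_S_TO_NM_PER_S

__all__ = [
    "DensityTrajectory",
    "WorkCurve",
    "advancing_work",
    "bond_density_leading",
    "bond_density_trailing",
    "equilibrium_density",
    "quasi_static_work",
    "receding_work",
    "work_curves",
]

#: trailing-edge cutoff: integrate until this fraction of ξTR(0) survives
TRAILING_SURVIVAL_CUTOFF = 1.0e-6
#: hard cap on the trailing-edge integration horizon (s)
TRAILING_TIME_CAP = 1.0e6


@dataclass(frozen=True)
class DensityTrajectory:
    """Closed-bond density history at a moving contact edge.

    t in s, delta_t in nm, xi_t in μm⁻², sigma_t (traction) in μJ/m² per
    nm of separation (equivalently 10⁻³ pN/nm²); ``work`` is the
    accumulated work of adhesion in μJ/m².
    """

    t: NDArray[np.float64]
    delta_t: NDArray[np.float64]
    xi_t: NDArray[np.float64]
    sigma_t: NDArray[np.float64]
    work: float
    xi_end: float


def _edge_speed_nm_s(kin: EdgeKinematics) -> float:
    return kin.edge_ratio * kin.vc * UM_PER_S_TO_NM_PER_S


def equilibrium_density(delta: float, kin: EdgeKinematics, bond: BondParams) -> float:
    """Equilibrium closed-bond density ξeq = kon·ξall/(kon+koff) (μm⁻²)."""
    from .bond_kinetics import bond_force

    kon = float(on_rate(delta, bond))
    koff = float(off_rate(bond_force(delta, bond), bond))
    return kin.xi_all * kon / (kon + koff)


def _solve_edge(
    vc: float,
    kin: EdgeKinematics,
    bond: BondParams,
    delta_of_t,
    t_end: float,
    xi0: float,
    rtol: float = 1e-8,
    n_out: int = 400,
    event=None,
) -> DensityTrajectory:
    """Integrate the mean-field density plus the running work integral."""
    from .bond_kinetics import bond_force

    xi_all_nm = kin.xi_all * PER_UM2_TO_PER_NM2  # nm⁻²
    speed = _edge_speed_nm_s(kin)  # |dδ/dt|, nm/s

    def rates(t: float) -> tuple[float, float, float]:
        delta = delta_of_t(t)
        kon = float(on_rate(delta, bond))
        koff = float(off_rate(bond_force(delta, bond), bond))
        return delta, kon, koff

    def rhs(t: float, y: NDArray[np.float64]) -> list[float]:
        delta, kon, koff = rates(t)
        xi = y[0]
        ext = max(0.0, delta - bond.rest_separation)
        sigma = bond.kLR * ext * xi  # pN/nm² with xi in nm⁻²
        return [kon * xi_all_nm - (kon + koff) * xi, sigma * speed]

    def jac(t: float, y: NDArray[np.float64]) -> NDArray[np.float64]:
        delta, kon, koff = rates(t)
        ext = max(0.0, delta - bond.rest_separation)
        return np.array([[-(kon + koff), 0.0], [bond.kLR * ext * speed, 0.0]])

    events = None
    if event is not None:
        event.terminal = True
        event.direction = -1
        events = [event]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [xi0 * PER_UM2_TO_PER_NM2, 0.0],
        method="LSODA",
        rtol=rtol,
        atol=[1e-14 * max(xi_all_nm, 1e-30), 1e-18],
        jac=jac,
        dense_output=True,
        events=events,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"edge density integration failed: {sol.message}")
    t_stop = sol.t[-1]
    t = np.linspace(0.0, t_stop, n_out)
    y = sol.sol(t)
    xi_nm = np.clip(y[0], 0.0, xi_all_nm)
    delta = np.array([delta_of_t(ti) for ti in t])
    ext = np.maximum(0.0, delta - bond.rest_separation)
    sigma = bond.kLR * ext * xi_nm * PN_PER_NM_TO_UJ_PER_M2  # μJ/m² per nm
    work = float(y[1, -1]) * PN_PER_NM_TO_UJ_PER_M2  # pN/nm → μJ/m²
    return DensityTrajectory(
        t=t,
        delta_t=delta,
        xi_t=xi_nm / PER_UM2_TO_PER_NM2,
        sigma_t=sigma,
        work=max(0.0, work),
        xi_end=float(xi_nm[-1] / PER_UM2_TO_PER_NM2),
    )


def bond_density_leading(
    vc: float, kin: EdgeKinematics, bond: BondParams, rtol: float = 1e-8
) -> DensityTrajectory:
    """Bond formation while the leading-edge gap closes from δ0 to contact.

    δ(t) = δ0 − 0.05·vc·t, starting from ξ_LD(0) = 0 and stopping at
    t_s = (δ0 − lb − lbind)/(0.05·vc) when the gap reaches the bond rest
    separation.
    """
    if vc <= 0.0:
        raise ValueError("vc must be > 0; use quasi_static_work for the vc→0 limit")
    kin = _with_vc(kin, vc)
    delta0 = kin.resolved_delta0(bond)
    speed = _edge_speed_nm_s(kin)
    t_s = (delta0 - bond.rest_separation) / speed
    return _solve_edge(
        vc, kin, bond, lambda t: delta0 - speed * t, t_s, 0.0, rtol=rtol
    )


def bond_density_trailing(
    vc: float,
    kin: EdgeKinematics,
    bond: BondParams,
    xi_ld_end: float | None = None,
    rtol: float = 1e-8,
) -> DensityTrajectory:
    """Bond stretching and rupture as the trailing-edge gap opens.

    δ(t) = lb + lbind + 0.05·vc·t.  The initial density interpolates
    between the leading-edge arrival density and the contact-zone
    equilibrium according to the relaxation accumulated over the transit
    time (a+b)/vc:

        ξTR(0) = ξLD(ts) + (ξeq − ξLD(ts))·[1 − e^{−(kon+koff)(a+b)/vc}]

    with kon, koff evaluated at contact (δ = lb + lbind).  Integration
    stops at the cutoff time tc when ξTR has fallen to 10⁻⁶ of ξTR(0).
    """
    if vc <= 0.0:
        raise ValueError("vc must be > 0; use quasi_static_work for the vc→0 limit")
    kin = _with_vc(kin, vc)
    if xi_ld_end is None:
        xi_ld_end = bond_density_leading(vc, kin, bond, rtol=rtol).xi_end
    rest = bond.rest_separation
    kon_c = float(on_rate(rest, bond))
    koff_c = float(off_rate(0.0, bond))
    xi_eq = kin.xi_all * kon_c / (kon_c + koff_c)
    relax = 1.0 - np.exp(-(kon_c + koff_c) * kin.transit_time)
    xi0 = xi_ld_end + (xi_eq - xi_ld_end) * relax

    speed = _edge_speed_nm_s(kin)
    t_end = min((200.0 * bond.thermal_length) / speed, TRAILING_TIME_CAP)
    if t_end >= TRAILING_TIME_CAP:  # pragma: no cover
        warnings.warn("trailing-edge horizon hit the 1e6 s cap", stacklevel=2)
    threshold = TRAILING_SURVIVAL_CUTOFF * xi0 * PER_UM2_TO_PER_NM2

    def ruptured(t: float, y: NDArray[np.float64]) -> float:
        return y[0] - threshold

    return _solve_edge(
        vc,
        kin,
        bond,
        lambda t: rest + speed * t,
        t_end,
        xi0,
        rtol=rtol,
        event=ruptured,
    )


def _with_vc(kin: EdgeKinematics, vc: float) -> EdgeKinematics:
    from dataclasses import replace

    return kin if kin.vc == vc else replace(kin, vc=vc)


def advancing_work(
    vc: float, kin: EdgeKinematics, bond: BondParams, rtol: float = 1e-8
) -> float:
    """Advancing work of adhesion wa(vc) in μJ/m²."""
    return bond_density_leading(vc, kin, bond, rtol=rtol).work


def receding_work(
    vc: float,
    kin: EdgeKinematics,
    bond: BondParams,
    xi_ld_end: float | None = None,
    rtol: float = 1e-8,
) -> float:
    """Receding work of adhesion wr(vc) in μJ/m²."""
    return bond_density_trailing(vc, kin, bond, xi_ld_end=xi_ld_end, rtol=rtol).work


def quasi_static_work(
    bond: BondParams, kin: EdgeKinematics, ext_max: float | None = None
) -> float:
    """Quasi-static work of adhesion wQS (μJ/m²).

    With reactions equilibrated at every separation, the traction path
    integral over the trailing separation becomes

        wQS = ∫ kLR·(δ − lb − lbind) · ξeq(δ) dδ,
        ξeq(δ) = kon(δ)·ξall / (kon(δ) + koff(f(δ))),

    which is also the vc → 0 limit of both wa and wr.
    """
    from .bond_kinetics import bond_force

    xi_all_nm = kin.xi_all * PER_UM2_TO_PER_NM2
    rest = bond.rest_separation
    if ext_max is None:
        # the association rate is Gaussian-suppressed as exp(-(x/thermal)²);
        # beyond ~8 thermal lengths the integrand is below 1e-25 of peak
        ext_max = 8.0 * bond.thermal_length

    def integrand(x: float) -> float:
        delta = rest + x
        kon = float(on_rate(delta, bond))
        koff = float(off_rate(bond_force(delta, bond), bond))
        return bond.kLR * x * xi_all_nm * kon / (kon + koff)

    val, _ = quad(integrand, 0.0, ext_max, limit=200)
    return val * PN_PER_NM_TO_UJ_PER_M2


@dataclass(frozen=True)
class WorkCurve:
    """Tabulated works of adhesion over a cell-speed grid.

    Exposes shape-preserving (monotone piecewise-cubic in log-speed)
    interpolants, clamped to the tabulated range: below the smallest
    tabulated speed both works are the quasi-static value, far above it
    both tend to zero.
    """

    vc_grid: NDArray[np.float64]
    wa: NDArray[np.float64]
    wr: NDArray[np.float64]
    w_qs: float
    _wa_interp: PchipInterpolator = field(repr=False, compare=False, default=None)
    _wr_interp: PchipInterpolator = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        logv = np.log10(self.vc_grid)
        object.__setattr__(self, "_wa_interp", PchipInterpolator(logv, self.wa))
        object.__setattr__(self, "_wr_interp", PchipInterpolator(logv, self.wr))

    def _eval(self, interp: PchipInterpolator, endpoints: tuple[float, float], vc):
        scalar = np.isscalar(vc) or np.asarray(vc).ndim == 0
        v = np.atleast_1d(np.asarray(vc, dtype=float))
        lo, hi = self.vc_grid[0], self.vc_grid[-1]
        out = np.empty(v.shape)
        below, above = v <= lo, v >= hi
        mid = ~(below | above)
        out[below] = endpoints[0]
        out[above] = endpoints[1]
        out[mid] = interp(np.log10(v[mid]))
        return float(out[0]) if scalar else out

    def wa_of(self, vc):
        """wa(vc) (μJ/m²), interpolated; clamped outside the grid."""
        return self._eval(self._wa_interp, (self.wa[0], self.wa[-1]), vc)

    def wr_of(self, vc):
        """wr(vc) (μJ/m²), interpolated; clamped outside the grid."""
        return self._eval(self._wr_interp, (self.wr[0], self.wr[-1]), vc)

    def hysteresis_of(self, vc):
        """wr − wa (μJ/m²), the adhesion hysteresis resisting rolling."""
        return self.wr_of(vc) - self.wa_of(vc)

    @property
    def v_star(self) -> float:
        """Speed (μm/s) of the receding-work maximum, parabolic-refined."""
        i = int(np.argmax(self.wr))
        if 0 < i < len(self.vc_grid) - 1:
            x0, x1, x2 = np.log10(self.vc_grid[i - 1 : i + 2])
            y0, y1, y2 = self.wr[i - 1 : i + 2]
            num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
            den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
            if den != 0.0:
                return float(10.0 ** (x1 - 0.5 * num / den))
        return float(self.vc_grid[i])


def default_speed_grid(n: int = 200) -> NDArray[np.float64]:
    """200 log-spaced speeds from 0.01 to 1e4 μm/s."""
    return np.geomspace(1.0e-2, 1.0e4, n)


def work_curves(
    kin: EdgeKinematics,
    bond: BondParams,
    vc_grid: NDArray[np.float64] | None = None,
    rtol: float = 1e-8,
) -> WorkCurve:
    """Tabulate wa(vc) and wr(vc) over a log-spaced speed grid."""
    if vc_grid is None:
        vc_grid = default_speed_grid()
    vc_grid = np.asarray(vc_grid, dtype=float)
    wa = np.empty_like(vc_grid)
    wr = np.empty_like(vc_grid)
    for i, vc in enumerate(vc_grid):
        lead = bond_density_leading(vc, kin, bond, rtol=rtol)
        wa[i] = lead.work
        wr[i] = receding_work(vc, kin, bond, xi_ld_end=lead.xi_end, rtol=rtol)
    w_qs = quasi_static_work(bond, kin)
    return WorkCurve(vc_grid=vc_grid, wa=wa, wr=wr, w_qs=w_qs)
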