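"""Parameter containers for bonds, clusters, contact-edge kinematics and flow.

Default numeric values are the model's reference parameter set for a
leukocyte-like cell rolling on a selectin-ligand-coated substrate:
cell radius 4.25 μm, density 1.1 g/cm³, plasma-like viscosity 1 mPa·s,
total bond density 140 μm⁻², bond rest length 11 nm, reaction radius
1 nm, bond stiffness 0.5 pN/nm, spontaneous association rate 25 s⁻¹ and
spontaneous slip/catch-pathway dissociation rates 1 s⁻¹ / 15 s⁻¹.

The two-pathway landscape constants (``f_beta``, ``f_cs``, ``phi0``)
have no reference values; the package ships calibrated defaults (see
:mod:`catchroll.calibrate` and ``docs/methods.md``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

from .units import KBT_PN_NM

__all__ = ["BondParams", "ClusterSpec", "EdgeKinematics", "FlowCell"]

#: calibrated two-pathway constants (see calibrate.py); NOT reference values.
#: Shape-based calibration: koff(0) = 14/s (phi0 = 13 > 1, slip barrier above
#: the catch barrier), off-rate minimum at 10 pN with ~4.8x dynamic range.
CALIBRATED_F_BETA = 10.845908  # pN
CALIBRATED_F_CS = 1.663636  # pN
CALIBRATED_PHI0 = 13.0  # dimensionless

#: Bell force scale of the slip-bond comparison model, set so the Nt = 10
#: catch/slip mean-lifetime crossover falls at 5 pN (closed form:
#: f_beta_slip = 5 / ln(koff_catch(5 pN)/ks)).  Independently, this value
#: puts the slip bond's quasi-static work of adhesion at 0.54 μJ/m².
SLIP_COMPARISON_F_BETA = 2.600597  # pN


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0.0 or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class BondParams:
    """Single-bond constants for the harmonic-spring receptor--ligand bond.

    Parameters
    ----------
    kLR : float
        Bond spring stiffness (pN/nm).
    lb : float
        Bond rest length (nm).
    lbind : float
        Reaction radius around the binding site (nm).
    kon0 : float
        Spontaneous association rate (1/s).
    ks, kc : float
        Spontaneous dissociation rates through the slip and catch
        pathways at zero force (1/s).
    f_beta : float
        Slip characteristic force kBT/Δxs (pN).
    f_cs : float
        Inter-barrier characteristic force kBT/Δxcs (pN).
    phi0 : float
        Unstressed equilibrium constant between the two escape
        pathways, exp[(ΔEs − ΔEc)/kBT] (dimensionless).
    kBT : float
        Thermal energy (pN·nm).
    mode : {"catch", "slip"}
        "catch" uses the two-pathway off-rate; "slip" the Bell rate
        with the same ``ks`` and ``f_beta``.
    """

    kLR: float = 0.5
    lb: float = 11.0
    lbind: float = 1.0
    kon0: float = 25.0
    ks: float = 1.0
    kc: float = 15.0
    f_beta: float = CALIBRATED_F_BETA
    f_cs: float = CALIBRATED_F_CS
    phi0: float = CALIBRATED_PHI0
    kBT: float = KBT_PN_NM
    mode: Literal["catch", "slip"] = "catch"

    def __post_init__(self) -> None:
        _require_positive(
            kLR=self.kLR, lb=self.lb, lbind=self.lbind, kon0=self.kon0,
            ks=self.ks, kc=self.kc, f_beta=self.f_beta, f_cs=self.f_cs,
            phi0=self.phi0, kBT=self.kBT,
        )
        if self.mode not in ("catch", "slip"):
            raise ValueError(f"mode must be 'catch' or 'slip', got {self.mode!r}")

    @property
    def rest_separation(self) -> float:
        """Separation at which a closed bond is unstretched (nm)."""
        return self.lb + self.lbind

    @property
    def thermal_length(self) -> float:
        """Width sqrt(2 kBT / kLR) of the bond's thermal stretch (nm)."""
        return math.sqrt(2.0 * self.kBT / self.kLR)

    def as_slip(self) -> "BondParams":
        """Pure mode switch: Bell rate with this parameter set's f_beta.

        This is the Φ0 → 0 limit of the two-pathway rate.  For the
        slip-*bond* comparison model (its own Bell force scale) use
        :meth:`comparison_slip`.
        """
        return replace(self, mode="slip")

    def comparison_slip(self, f_beta_slip: float = SLIP_COMPARISON_F_BETA) -> "BondParams":
        """The slip-bond comparison model.

        A slip bond is not the slip *pathway* of the catch bond: it has
        its own Bell force scale, calibrated so the catch/slip cluster
        mean-lifetime crossover (Nt = 10) falls at 5 pN.
        """
        return replace(self, mode="slip", f_beta=f_beta_slip)

    def as_catch(self) -> "BondParams":
        return replace(self, mode="catch")


@dataclass(frozen=True)
class ClusterSpec:
    """A bond cluster at the trailing edge held at fixed per-bond force.

    All closed bonds share the same separation ``delta`` and therefore
    the same tensile force ``f``; ``f`` and ``delta`` must be mutually
    consistent through the spring law.
    """

    Nt: int
    f: float
    bond: BondParams = field(default_factory=BondParams)
    delta: float | None = None

    def __post_init__(self) -> None:
        if int(self.Nt) != self.Nt or self.Nt < 1:
            raise ValueError(f"Nt must be an integer >= 1, got {self.Nt!r}")
        if self.f < 0.0:
            raise ValueError(f"per-bond force must be >= 0, got {self.f!r}")
        if self.delta is None:
            object.__setattr__(
                self, "delta", self.bond.rest_separation + self.f / self.bond.kLR
            )
        else:
            from .bond_kinetics import bond_force

            if not math.isclose(
                bond_force(self.delta, self.bond), self.f, rel_tol=1e-9, abs_tol=1e-9
            ):
                raise ValueError(
                    f"delta={self.delta} is inconsistent with per-bond force f={self.f}"
                )


@dataclass(frozen=True)
class EdgeKinematics:
    """Prescribed motion of the contact edges for a rolling cell.

    The leading (advancing) edge approaches the substrate and the
    trailing (receding) edge separates from it at normal speed
    ``edge_ratio * vc`` where ``edge_ratio`` = a/R = b/R ≈ 0.05.
    """

    vc: float = 1.0  # cell centre speed, μm/s
    edge_ratio: float = 0.05
    delta0: float | None = None  # initial leading-edge separation, nm
    xi_all: float = 140.0  # total bond density, 1/μm²
    R: float = 4.25  # cell radius, μm (sets the contact transit time)

    def __post_init__(self) -> None:
        if self.vc < 0.0:
            raise ValueError(f"vc must be >= 0, got {self.vc!r}")
        if not 0.0 < self.edge_ratio < 1.0:
            raise ValueError(f"edge_ratio must be in (0, 1), got {self.edge_ratio!r}")
        if self.xi_all < 0.0:
            raise ValueError(f"xi_all must be >= 0, got {self.xi_all!r}")
        _require_positive(R=self.R)

    @property
    def transit_time(self) -> float:
        """Time (a+b)/vc (s) the contact zone takes to pass a material point."""
        if self.vc == 0.0:
            raise ValueError("transit time undefined at vc = 0")
        return 2.0 * self.edge_ratio * self.R / self.vc

    def resolved_delta0(self, bond: BondParams) -> float:
        """Initial separation δ0 (nm), default rest + 5 thermal lengths.

        Far enough out that the association rate is negligible
        (kon(δ0)/kon0 < 1e-5), honouring δ0 ≫ lb without wasting
        integration time.
        """
        floor = bond.rest_separation + 5.0 * bond.thermal_length
        if self.delta0 is None:
            return floor
        if self.delta0 < floor:
            raise ValueError(
                f"delta0={self.delta0} nm is too close to contact; need >= {floor:.2f} nm"
            )
        return self.delta0


@dataclass(frozen=True)
class FlowCell:
    """Hydrodynamic and geometric parameters of the rolling cell.

    The cell is a rigid circular cylinder (2D model) of radius ``R``
    rolling without slip, so the angular velocity is ω = vc/R.  Mass and
    rotational inertia are per unit thickness: m = π ρ R² and
    J0 = 3 m R²/2 about the contact apex.
    """

    R: float = 4.25  # μm
    rho: float = 1.1  # g/cm³
    eta: float = 1.0e-3  # Pa·s

    def __post_init__(self) -> None:
        _require_positive(R=self.R, rho=self.rho, eta=self.eta)

    @property
    def m(self) -> float:
        """Mass per unit thickness, kg/m."""
        rho_si = self.rho * 1.0e3  # kg/m³
        r_si = self.R * 1.0e-6  # m
        return math.pi * rho_si * r_si**2

    @property
    def J0(self) -> float:
        """Rotational inertia per unit thickness about the contact apex, kg·m."""
        return 1.5 * self.m * (self.R * 1.0e-6) ** 2

    # --- nondimensionalization helpers (η in Pa·s, v in μm/s, w in μJ/m²) ---

    def v_bar(self, vc_um_s: float, w_qs: float) -> float:
        """Nondimensional speed v̄ = η vc / wQS."""
        return self.eta * vc_um_s / w_qs

    def v_from_bar(self, v_bar: float, w_qs: float) -> float:
        return v_bar * w_qs / self.eta

    def gamma_bar(self, gamma_s: float, w_qs: float) -> float:
        """Nondimensional shear rate γ̄ = η R γ / wQS."""
        return self.eta * self.R * gamma_s / w_qs

    def gamma_from_bar(self, gamma_bar: float, w_qs: float) -> float:
        return gamma_bar * w_qs / (self.eta * self.R)

    def t_bar(self, t_s: float) -> float:
        """Nondimensional time t̄ = η t / m."""
        return self.eta * t_s / self.m
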