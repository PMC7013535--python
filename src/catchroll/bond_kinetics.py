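"""Single-bond rate laws.

A closed receptor--ligand bond is a thermalized harmonic spring of
stiffness ``kLR`` and rest length ``lb`` binding across the cell--
substrate gap δ; the tensile force on a closed bond is
``f = kLR (δ − lb − lbind)``, clamped at zero for compressed bonds.

Dissociation follows the two-pathway picture of a Brownian particle
escaping a single well over either a low *catch* barrier or a
force-lowered *slip* barrier:

    koff(f) = [Φ0 kc + e^{f/f_cs} ks e^{f/f_β}] / [Φ0 + e^{f/f_cs}]

where Φ0 = exp[(ΔEs − ΔEc)/kBT] weighs the two pathways at zero force.
In the limit Φ0 → 0 (slip barrier far below the catch barrier) this
reduces exactly to the Bell rate ks·e^{f/f_β}, which is what
``mode="slip"`` evaluates.

Association is separation-dependent: a thermally fluctuating free
binder of stiffness kLR reaches the reaction radius lbind with Boltzmann
weight exp[−kLR(δ−lb−lbind)²/2kBT] normalized by the partition function
Z(δ) of the confined binder.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import erf

from .params import BondParams

__all__ = ["bond_force", "off_rate", "on_rate", "partition_function"]


def bond_force(delta: ArrayLike, p: BondParams) -> NDArray[np.float64] | float:
    """Tensile force (pN) on a closed bond at separation ``delta`` (nm).

    Compressed bonds (δ < lb + lbind) carry zero force: the off-rate law
    is derived for tensile escape, so the force is clamped at zero
    before entering it.
    """
    delta = np.asarray(delta, dtype=float)
    f = np.maximum(0.0, p.kLR * (delta - p.rest_separation))
    return f if f.ndim else float(f)


def off_rate(f: ArrayLike, p: BondParams) -> NDArray[np.float64] | float:
    """Dissociation rate (1/s) of a closed bond under tensile force ``f`` (pN).

    ``mode="catch"`` evaluates the two-pathway rate; ``mode="slip"`` the
    Bell rate ks·exp(f/f_beta).  Negative forces are the caller's
    responsibility to clamp (see :func:`bond_force`) and raise.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("off_rate requires f >= 0; clamp compressive forces first")
    bell = p.ks * np.exp(f / p.f_beta)
    if p.mode == "slip":
        return bell if bell.ndim else float(bell)
    # numerically stable form: multiply through by exp(-f/f_cs) so the
    # catch-pathway weight u = phi0*exp(-f/f_cs) decays instead of the
    # slip weight overflowing
    u = p.phi0 * np.exp(-f / p.f_cs)
    k = (u * p.kc + bell) / (u + 1.0)
    return k if k.ndim else float(k)


def partition_function(delta: ArrayLike, p: BondParams) -> NDArray[np.float64] | float:
    """Partition function Z(δ) of the free binder confined to the gap.

    Z = (1/lbind)·sqrt(π kBT / 2 kLR)·[erf((δ−lb)·sqrt(kLR/2kBT))
                                        + erf(lb·sqrt(kLR/2kBT))],
    i.e. the Gaussian integral of the spring's Boltzmann weight over
    binder positions 0 ≤ x ≤ δ, in units of the reaction radius.
    Positive and nondecreasing in δ.
    """
    delta = np.asarray(delta, dtype=float)
    alpha = np.sqrt(p.kLR / (2.0 * p.kBT))  # 1/nm
    pref = np.sqrt(np.pi * p.kBT / (2.0 * p.kLR)) / p.lbind
    z = pref * (erf((delta - p.lb) * alpha) + erf(p.lb * alpha))
    return z if z.ndim else float(z)


def on_rate(delta: ArrayLike, p: BondParams) -> NDArray[np.float64] | float:
    """Association rate (1/s) at separation ``delta`` (nm).

    kon = (kon0/Z)·exp[−kLR(δ−lb−lbind)²/2kBT]; maximal at zero
    extension and Gaussian-suppressed at large gaps.
    """
    delta = np.asarray(delta, dtype=float)
    z = partition_function(delta, p)
    k = (p.kon0 / np.asarray(z)) * np.exp(
        -p.kLR * (delta - p.rest_separation) ** 2 / (2.0 * p.kBT)
    )
    return k if k.ndim else float(k)
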