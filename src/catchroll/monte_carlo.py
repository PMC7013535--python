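"""Exact stochastic simulation of the bond cluster.

Validation engine for the deterministic solutions: a direct Gillespie
algorithm for the cluster at fixed force (rupture-time samples against
the master-equation lifetime density) and a thinning (rejection)
algorithm for the time-inhomogeneous single-bond chains at a moving
contact edge (ensemble mean against the mean-field density, which is
exact for this linear scheme of non-interacting bonds).

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds and parameters reproduce
bit-identical event sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .bond_kinetics import bond_force, off_rate, on_rate
from .params import BondParams, ClusterSpec, EdgeKinematics

__all__ = ["SSARun", "EdgeEnsemble", "gillespie_lifetime", "ssa_moving_edge"]


@dataclass(frozen=True)
class SSARun:
    """Rupture-time samples of a bond cluster at fixed force."""

    seed: int
    samples: NDArray[np.float64]  # per-replicate rupture times, s

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def se(self) -> float:
        return float(self.samples.std(ddof=1) / np.sqrt(len(self.samples)))


def gillespie_lifetime(spec: ClusterSpec, n_samples: int, seed: int) -> SSARun:
    """Sample cluster rupture times by the direct Gillespie algorithm.

    States n ∈ {0..Nt} with propensities n·koff (opening) and
    (Nt−n)·kon (closing); every replicate starts fully closed and stops
    on first arrival at n = 0.  Replicates are advanced in lockstep
    (vectorized over the ensemble) from one generator stream.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100 for meaningful statistics")
    from .cluster_lifetime import cluster_rates

    kon, koff = cluster_rates(spec)
    rng = np.random.default_rng(seed)
    n = np.full(n_samples, spec.Nt, dtype=np.int64)
    t = np.zeros(n_samples)
    alive = n > 0
    while alive.any():
        idx = np.flatnonzero(alive)
        a_off = n[idx] * koff
        a_on = (spec.Nt - n[idx]) * kon
        a_tot = a_off + a_on
        t[idx] += rng.exponential(1.0 / a_tot)
        open_event = rng.random(idx.size) < a_off / a_tot
        n[idx] += np.where(open_event, -1, 1)
        alive[idx] = n[idx] > 0
    return SSARun(seed=seed, samples=t)


@dataclass(frozen=True)
class EdgeEnsemble:
    """Ensemble closed-bond density at a moving edge.

    ``xi_mean`` and ``xi_se`` are in μm⁻² (fraction closed × ξall).
    """

    seed: int
    t: NDArray[np.float64]
    xi_mean: NDArray[np.float64]
    xi_se: NDArray[np.float64]
    n_samples: int


def ssa_moving_edge(
    vc: float,
    edge: str,
    kin: EdgeKinematics,
    bond: BondParams,
    n_samples: int,
    seed: int,
    n_out: int = 60,
    n_segments: int = 400,
) -> EdgeEnsemble:
    """Stochastic single-bond channels under the moving-edge separation.

    Each of ``n_samples`` independent binding sites is a two-state
    (open/closed) Markov chain with time-dependent rates kon(δ(t)),
    koff(f(δ(t))).  Events are generated exactly by thinning: time is
    split into ``n_segments`` intervals, candidate events are proposed
    at the per-state rate bound of the interval and accepted with
    probability rate(t)/bound.  The ensemble mean times ξall estimates
    the closed-bond density.

    ``edge="leading"`` runs the approach δ0 → contact from all-open
    initial conditions over [0, ts]; ``edge="trailing"`` runs the
    separation from contact, starting closed with probability
    ξTR(0)/ξall (the mean-field initial density), until the mean-field
    cutoff time.
    """
    from dataclasses import replace

    from .adhesion_work import bond_density_leading, bond_density_trailing

    kin = kin if kin.vc == vc else replace(kin, vc=vc)
    if edge == "leading":
        traj = bond_density_leading(vc, kin, bond)
        p_closed0 = 0.0
    elif edge == "trailing":
        traj = bond_density_trailing(vc, kin, bond)
        p_closed0 = float(traj.xi_t[0] / kin.xi_all)
    else:
        raise ValueError(f"edge must be 'leading' or 'trailing', got {edge!r}")
    t_end = float(traj.t[-1])
    delta_of_t = _delta_path(traj)

    rng = np.random.default_rng(seed)
    closed = rng.random(n_samples) < p_closed0 if p_closed0 > 0 else np.zeros(
        n_samples, dtype=bool
    )

    # align segment boundaries with output times so snapshots are exact
    per = max(1, int(np.ceil(n_segments / (n_out - 1))))
    n_segments = per * (n_out - 1)
    t_out = np.linspace(0.0, t_end, n_out)
    records = np.empty((n_out, n_samples), dtype=bool)
    records[0] = closed
    out_idx = 1

    edges_t = np.linspace(0.0, t_end, n_segments + 1)
    for k in range(n_segments):
        t0, t1 = edges_t[k], edges_t[k + 1]
        # per-state rate bounds on this segment (rates are monotone in δ
        # only piecewise, so take the max over a fine probe)
        probe = np.linspace(t0, t1, 5)
        dl = delta_of_t(probe)
        kon_b = float(np.max(on_rate(dl, bond))) * 1.000001 + 1e-300
        koff_b = float(np.max(off_rate(bond_force(dl, bond), bond))) * 1.000001
        # thinning within [t0, t1): each channel proposes candidates at
        # its state's bound until past t1
        t_now = np.full(n_samples, t0)
        active = np.ones(n_samples, dtype=bool)
        while active.any():
            idx = np.flatnonzero(active)
            bound = np.where(closed[idx], koff_b, kon_b)
            t_now[idx] += rng.exponential(1.0, idx.size) / bound
            past = t_now[idx] >= t1
            active[idx[past]] = False
            cand = idx[~past]
            if cand.size:
                dl_c = delta_of_t(t_now[cand])
                rate = np.where(
                    closed[cand],
                    off_rate(bond_force(dl_c, bond), bond),
                    on_rate(dl_c, bond),
                )
                accept = rng.random(cand.size) < rate / np.where(
                    closed[cand], koff_b, kon_b
                )
                closed[cand[accept]] = ~closed[cand[accept]]
        if (k + 1) % per == 0:
            records[out_idx] = closed
            out_idx += 1
    while out_idx < n_out:  # pragma: no cover
        records[out_idx] = closed
        out_idx += 1

    frac_mean = records.mean(axis=1)
    frac_se = records.std(axis=1, ddof=1) / np.sqrt(n_samples)
    return EdgeEnsemble(
        seed=seed,
        t=t_out,
        xi_mean=frac_mean * kin.xi_all,
        xi_se=frac_se * kin.xi_all,
        n_samples=n_samples,
    )


def _delta_path(traj):
    """Vectorized linear-in-time separation path from a trajectory."""
    t = traj.t
    d = traj.delta_t

    def delta_of_t(tt):
        return np.interp(np.asarray(tt, dtype=float), t, d)

    return delta_of_t
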