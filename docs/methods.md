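# Methods

## Model

A rigid circular cylinder of radius R (a 2D stand-in for a cell) rolls
without slip (ω = v_c/R) on a ligand-coated substrate under a linear
shear flow of rate γ. Adhesion is carried by a dilute cluster of
receptor–ligand bonds, modelled as thermalized harmonic springs of
stiffness k_LR and rest length l_b binding across the local
cell–substrate gap δ; a closed bond at gap δ carries tensile force
f = k_LR(δ − l_b − l_bind), clamped at zero under compression (the
escape-rate law below is derived for tensile escape, and a compressed
bond should neither be stabilized nor destabilized by it).

**Dissociation.** A closed bond escapes its well over either a low
*catch* barrier or a force-lowered *slip* barrier:

    koff(f) = [Φ₀·k_c + e^{f/f_cs}·k_s·e^{f/f_β}] / [Φ₀ + e^{f/f_cs}]

with spontaneous pathway rates k_c, k_s, characteristic forces
f_β = k_BT/Δx_s and f_cs = k_BT/Δx_cs, and the unstressed pathway
equilibrium constant Φ₀ = exp[(ΔE_s − ΔE_c)/k_BT]. The rate is a
Φ₀e^{−f/f_cs}-weighted mean of k_c and the Bell rate, so it always lies
between them; for Φ₀ → 0 it reduces exactly to the Bell rate, which is
what `mode="slip"` evaluates. Numerically the expression is evaluated
with the catch weight u = Φ₀e^{−f/f_cs} so nothing overflows at large f.

**Association.** A free binder of the same stiffness reaches the
reaction radius l_bind with Boltzmann weight
exp[−k_LR(δ−l_b−l_bind)²/2k_BT], normalized by the partition function
Z(δ) of the binder confined to 0 ≤ x ≤ δ (closed form in error
functions): kon(δ) = (kon⁰/Z)·exp[...]. On the tensile range
δ ≥ l_b + l_bind, kon is maximal at zero extension and Gaussian-
suppressed with scale √(2k_BT/k_LR) ≈ 4.1 nm; Z grows mildly
(≈ 4.6 → 7.2) over that range.

**Cluster lifetime.** N_t bonds share one gap (hence one per-bond
force; the gap follows the force through the spring law, so rebinding
switches itself off beyond ~4 pN where the gap exceeds a few thermal
lengths). The closed-bond count n performs a birth–death process,
absorbing at n = 0 — rupture of the last bond detaches the interface
and rebinding from the detached state is excluded — and reflecting at
n = N_t. The lifetime density is the flux into the absorbed state,
P(t) = dp₀/dt = k_off·p₁(t), and τ = ∫t·P dt. The solver propagates
matrix exponentials of the (N_t+1)² generator on a geometric time grid
(or, as a cross-check, a BDF integrator at rtol 1e-9; both agree to
1e-6), truncates when survival < 1e-8, and adds the analytic
exponential tail S(T)(T + 1/λ_slow) from the slowest generator
eigenvalue; the closed-form birth–death mean-first-passage recursion
provides the same quantity exactly and is what force sweeps use.

**Works of adhesion.** Near the leading (trailing) edge the gap closes
(opens) at normal speed (a/R)v_c with a/R = b/R = 0.05. The mean closed
density obeys dξ/dt = kon·ξ_all − (kon+koff)·ξ — exact for independent
bonds — with ξ_LD(0) = 0 and δ(t) = δ₀ − 0.05v_c t at the leading edge,
and δ(t) = l_b + l_bind + 0.05v_c t at the trailing edge starting from

    ξ_TR(0) = ξ_LD(t_s) + (ξ_eq − ξ_LD(t_s))·[1 − e^{−(kon+koff)(a+b)/v_c}],

the relaxation toward the contact-zone equilibrium accumulated during
the transit time (a+b)/v_c. The works are traction path integrals
w = ∫σ dδ with σ = k_LR·(δ−l_b−l_bind)·ξ, accumulated as an auxiliary
ODE state so the quadrature shares the integrator's error control
(LSODA, rtol 1e-8, analytic Jacobian). The trailing integration stops
when ξ has fallen to 10⁻⁶ of ξ_TR(0) (hard cap 10⁶ s). In the
quasi-static limit both works reduce to
w_QS = ∫k_LR·x·ξ_eq(δ) dδ, evaluated by adaptive quadrature out to
8 thermal lengths; the finite-speed works converge to it linearly in
v_c (≈0.35% at 10⁻³ μm/s).

**Rolling.** The flow exerts F = 4πηR(γ − v_c/R) and
M = 2πηR²(γ − v_c/R) per unit thickness (stationary-cylinder loads
scaled by the slip velocity); the adhesion hysteresis exerts the
resistant torque R(w_r − w_a). Energy conservation
(flow input = kinetic energy + adhesive dissipation) gives, with
v̄ = ηv_c/w_QS, γ̄ = ηRγ/w_QS, t̄ = ηt/m, m = πρR², J₀ = 3mR²/2:

    dv̄/dt̄ = 4π(γ̄ − v̄) − ⅔[w̄_r(v̄) − w̄_a(v̄)].

Steady states solve γ(v) = v/R + (w_r−w_a)/(6πηR); the diagram's folds
are that function's local extrema. Because ∂(rhs)/∂v̄ < 0 exactly where
dγ/dv > 0, stable branches always have speed increasing with shear
rate; the *decreasing* branch (flow-enhanced adhesion) is the middle
root, which terminates at the upper fold — at the fold the firm and
middle branches merge, so "the firm-branch speed at the upper
threshold" is unambiguous.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| R, ρ, η | cell radius, density, flow viscosity | 4.25, 1.1, 10⁻³ | μm, g/cm³, Pa·s |
| ξ_all | total bond density | 140 | μm⁻² |
| l_b, l_bind, k_LR | rest length, reaction radius, stiffness | 11, 1, 0.5 | nm, nm, pN/nm |
| kon⁰, k_s, k_c | spontaneous association / slip / catch rates | 25, 1, 15 | s⁻¹ |
| k_BT | thermal energy (T ≈ 300 K; configurable) | 4.14 | pN·nm |
| f_β, f_cs, Φ₀ | two-pathway landscape (calibrated, below) | 10.846, 1.664, 13 | pN, pN, – |
| f_β(slip) | slip-comparison Bell force (calibrated) | 2.601 | pN |
| δ₀ | initial leading-edge gap | l_b+l_bind+5√(2k_BT/k_LR) ≈ 32.3 | nm |
| a/R = b/R | contact-edge geometry | 0.05 | – |
| N_t | trailing-edge cluster size | 10 | – |

δ₀ is chosen so kon(δ₀)/kon⁰ < 10⁻⁵: far enough to represent an
unbound approach without wasting integration time; results are
insensitive to it. Internal units are pN/nm/s at the bond scale, μm/s
for cell speeds, μJ/m² for works (1 pN/nm = 10³ μJ/m²; conversions are
centralized in `units.py`).

## Calibration of the landscape constants

f_β, f_cs, Φ₀ and the slip-comparison Bell force are not part of the
reference parameter set and must be calibrated. Three observations
constrain the choice made here:

1. In the two-pathway picture the slip barrier lies *above* the catch
   barrier, so Φ₀ > 1 and the zero-force off-rate is catch-dominated
   (close to k_c). This is also what a catch-*cluster* lifetime with an
   interior maximum requires: with kon(contact) ≈ 5.5 s⁻¹, a cluster
   whose koff(0) is small lives enormously long at zero force and no
   force can improve on it.
2. The two-pathway rate never falls below its own slip pathway
   k_s·e^{f/f_β}. A pronounced off-rate minimum near 10 pN therefore
   needs f_β ≫ Δx-scale forces of a few pN — and consequently the slip
   *comparison* bond cannot share the catch model's f_β: with a shared
   value the desired low-force crossover between catch and slip cluster
   lifetimes and the interior lifetime maximum exclude each other.
   The comparison bond gets its own Bell force.
3. Both bond flavours share kon(δ), so catch and slip cluster lifetimes
   cross exactly where the off-rates cross, giving the slip Bell force
   in closed form from the chosen crossover.

The shipped defaults are therefore shape-based: Φ₀ = 13 from
koff(0) = 14 s⁻¹ (closed form), (f_β, f_cs) root-solved so the
off-rate minimum is 2.9 s⁻¹ at 10 pN (a selectin-like ~5× dynamic
range, minimum inside the 10–60 pN band), and
f_β(slip) = 5 pN/ln(koff_catch(5 pN)/k_s) placing the 10-bond lifetime
crossover at exactly 5 pN. `calibrate.py` exposes the recipe so any
other shape can be fitted. Two consequences are worth knowing:

* The calibration fixes the model's energy and speed scales as
  *outputs*: with these defaults w_QS ≈ 0.16 μJ/m², the receding work
  peaks near 14 μm/s at ≈ 22 μJ/m², and the rolling diagram folds near
  141 and 281 s⁻¹ (all recomputed by `scripts/acceptance.py`).
  Calibrations that instead pin the quasi-static work to larger values
  (≳ 0.5 μJ/m²) require a small Φ₀ and provably flatten the catch
  signature — the cluster lifetime becomes monotone in force — so they
  were rejected; with this model structure and the reference rate
  constants, the energy scale and the catch-lifetime shape cannot be
  set independently.
* Pleasingly, the slip-comparison bond's own quasi-static work computes
  to 0.54 μJ/m² with the crossover-derived Bell force.

## Synthetic data and what the tests show

There is no external data; the "synthetic data" of this package are the
canonical fixtures (`default_catch`, `default_slip`, `no_adhesion`) and
the stochastic ensembles the Monte Carlo module draws. Those ensembles
emulate exactly the model's assumptions — independent bonds, shared
gap, Markovian switching, prescribed edge motion — so their agreement
with the deterministic solutions validates the *numerics* (solver,
boundary conditions, time-dependent thinning), not the biology. Real
rolling cells have deformable membranes, discrete microvilli,
force-sharing between bonds, 3D hydrodynamics with wall corrections,
and measurement noise, none of which is represented; passing tests say
nothing about those effects.

## Numerical choices

* Master equation: dense matrix exponentials (N_t ≤ ~50); geometric
  time grids with ~800 points; probability conservation holds to 1e-8.
* Gillespie: replicates advanced in lockstep from one seeded
  `default_rng` stream; identical seed ⇒ bit-identical samples.
  Time-dependent rates use state-dependent thinning with per-segment
  rate bounds on intervals aligned with the output grid (candidate
  times beyond a segment are discarded — exact by memorylessness).
* Work curves: 200 log-spaced speeds over 10⁻²–10⁴ μm/s; monotone
  shape-preserving (PCHIP in log-speed) interpolants, clamped to the
  quasi-static value below the grid and to the last node above it.
* Rolling ODE: classical RK4 with step Δt̄ = min(0.02/4π, 0.5/λ) where
  λ = 4π + ⅔·max|dΔw̄/dv̄| — the adhesion hysteresis, not the viscous
  drag, is the stiff term with calibrated work curves (λ ~ 4·10³).
  Energy-conservation residual along trajectories < 10⁻⁶ relative,
  rechecked post hoc by cumulative Simpson quadrature.
* Steady states: dense v̄ scan (linear plus log refinement near zero)
  brackets roots for Brent refinement; stability by the sign of the
  finite-difference derivative (relative step 10⁻⁶); fold points by
  bisection on root count to 0.1 s⁻¹ — robust to interpolation noise,
  unlike curvature-based detection.
* Degenerate inputs: compressed bonds carry zero force; ξ_all = 0 gives
  zero works and free rolling; a vanishing shear rate leaves the single
  firm root; `vc = 0` in the edge solvers raises and points to the
  quasi-static routine.

## Known limitations

2D cylinder hydrodynamics without wall corrections (no
Goldman–Cox–Brenner mobility); rigid cell and substrate; mean-field
(non-interacting) bonds with no force sharing; deterministic rolling
speed given the work curves (no velocity fluctuations); the
works-of-adhesion interpolation treats w_r, w_a as functions of the
instantaneous speed (quasi-steady contact); and the landscape-constant
calibration is by shape, not by fit to single-molecule data.
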