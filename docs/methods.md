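# Methods

`vasoring` simulates the isometric force response of an arterial ring
segment mounted on the hooks of a wire myograph. Three coupled models act
at two scales: ionic Ca²⁺ dynamics in a network of smooth muscle cells
(SMCs), four-state actin–myosin cross-bridge (CB) kinetics catalysed by
cytosolic Ca²⁺, and a quasi-static fibre-reinforced hyperelastic
finite-element (FE) model of the ring whose active stress comes from a
contractile-unit (CU) model evaluated at every Gauss point.

## Cellular Ca²⁺ dynamics

Each SMC carries three states: cytosolic Ca²⁺ `χ` (µM), sarcoplasmic
reticulum (SR) Ca²⁺ `ζ` (µM), and membrane potential `η` (V). The balance
laws are

    dχ/dt = Φ_A + Φ_S + Φ_V + Φ_N − Φ_B + Φ_C + Φ_L − Φ_D + J_Ca
    dζ/dt = Φ_B − Φ_C − Φ_L
    dη/dt = γ (2Φ_V − Φ_N − Φ_Cl − Φ_K) + J_V

with flux laws (units µM s⁻¹ throughout; all parameters in
`CellParams`, defaults from the reference parameter set):

| flux | pathway | form |
|------|---------|------|
| Φ_A  | non-selective cation channels (NSCC) | constant |
| Φ_S  | store-operated channels (SOCC) | `A_S ζ_S²/(ζ_S²+ζ²)` |
| Φ_V  | voltage-operated channels (VOCC) | `E_Ca (z_Ca1−η) σ((η−z_Ca2)/R_Ca)` |
| Φ_N  | reverse-mode Na⁺/Ca²⁺ exchange | `E_NCX χ/(χ+x_NCX) (η−z_NCX)` |
| Φ_B  | SERCA uptake | `B_SR χ^n/(χ^n+x_SR^n)`, n = 2 |
| Φ_C  | ryanodine-receptor CICR | `C_Ry ζ^m/(ζ^m+y_Ry^m) · χ^p/(χ^p+x_Ry^p)`, m = 2, p = 4 |
| Φ_L  | SR leak | `L_SR ζ` |
| Φ_D  | plasma-membrane ATPase | `D_EX χ^k (1+(η−z_Ex)/R_Ex)`, k = 2 |
| Φ_Cl | Cl⁻ channels | `E_Cl g(χ; x_Cl) (η−z_Cl)` |
| Φ_K  | Ca²⁺-gated K⁺ channels | `E_K g(χ; β_K) (η−z_K) σ((η−z_Ca3)/R_K)` |

`σ` is the logistic function and `g(χ; c) = χ/(χ+c)` with `g ≡ 1` when the
sensitivity constant is zero (the defaults disable both Ca²⁺ gates).
Voltage-gated fluxes vanish exactly at their reversal potentials. In the
membrane balance, the VOCC charge counts twice (divalent ion), the
reverse-mode exchanger contributes a net outward (repolarising) current,
and Cl⁻/K⁺ restore `η` towards their reversal potentials; `γ` (V µM⁻¹)
converts net ion movement into a potential rate.

These flux laws are a *reconstruction*: the model is assembled from the
minimal-vasomotion family of SMC models that this parameter set descends
from (an intracellular ryanodine-sensitive store oscillator coupled to a
membrane VOCC/K/Cl system), constrained by the parameter names, units,
values and half-point roles of the parameter table and by the reported
qualitative behaviour. Under the defaults it yields sustained Ca²⁺
oscillations for NSCC influx Φ_A between roughly 0.3 and 1.5 µM s⁻¹ with
period ≈ 1.26 s at Φ_A = 0.8 (the regression value frozen in the tests),
slower oscillations with elevated store content under the ryanodine
end-state, and robust, slightly damped oscillation under the CPA
end-state. Known limitation: a single mean-parameter cell is quiescent at
Φ_A = 4.2 µM s⁻¹, i.e. the oscillatory window closes above ≈ 1.5 µM s⁻¹,
so the post-phenylephrine regime is not oscillatory in this
reconstruction.

**Intercellular coupling.** Cells exchange Ca²⁺ and voltage through gap
junctions: `J_Ca,i = α_C (Σ_j χ_j − nNeigh·χ_i)` over the neighbour set
(likewise `J_V` with `α_V`). The sum over the network vanishes identically
for any graph (pairwise antisymmetry), which is the form the conservation
tests rely on. Units of `α` (s⁻¹) presuppose uniform cell volume/surface
ratio; the adjacency graph is the face-sharing graph of the hexahedral
mesh (6-neighbour; a vertex-sharing variant is available).

**Integration.** The network is advanced by the explicit adaptive
Runge–Kutta–Merson pair (5 stages, 4th order, PI step control; defaults
rtol 1e-7, atol 1e-9). Gap-junction currents are frozen at the start of
each reporting step `dt_cell` and refreshed on that grid, matching the
segregated architecture. Concentrations below −1e-9 raise an error rather
than being clamped, so transcription mistakes surface instead of being
masked.

## Cross-bridge kinetics

Four myosin states (detached/attached × dephosphorylated/phosphorylated)
with the transition graph declared as an edge list: phosphorylation
(`τ₁(χ) = θ τ₀ χ²/(χ²+χ₀²)`) on M→Mp and AM→AMp, dephosphorylation `τ₂`
on Mp→M and AMp→AM, attachment `τ₃` Mp→AMp, detachment `τ₄` AMp→Mp, and
latch-bridge detachment `τ₅` AM→M. The mapping reproduces the classical
four-state constants for `τ₂`–`τ₄` exactly, which supports the edge
assignment. `n_M` is eliminated algebraically (three-ODE system), making
`Σ n = 1` structural. Kinetics advance by forward Euler at `dt_cell`; a
guard rejects steps that push any fraction outside [0, 1] by more than
1e-9. `θ` ("enhancement" coefficient) multiplies τ₁ and is the
protocol-modifiable knob.

## Contractile-unit mechanics

At each Gauss point a CU carries the relative filament sliding `u_fs`
(negative in contraction, normalised to the reference CU length), split
into a chemical component `u_fs_c` and a mechanical component `u_fs_m`.
Here `u_fs_m` is eliminated: external deformation enters only through the
CU stretch `λ` in the elastic elongation `ū_e = λ − 1 − u_fs`, so
`u_fs_m ≡ 0` (kept as a field for the decomposition-closure contract).
The filament-resistance stress (the CU-averaged first Piola–Kirchhoff
stress) is `P_a = μ_a L_fo(u_fs) (n_AMp+n_AM) ū_e` with the parabolic
overlap `L_fo = max(0, 1 − s_overlap (u_fs + u_opt)²)`, clamped at zero
(a negative overlap is unphysical and destabilises `P_a`). The vertex sits
at `u_fs = −u_opt`: sliding in the contraction direction moves the
filaments towards optimal overlap, consistent with the sign convention.
The chemical sliding evolves by a stick-slip force balance with mobility
`β_a/α_a` (kPa⁻¹ s⁻¹): contraction when the cycling drive
`κ_AMp n_AMp` exceeds `P_a`, extension when `P_a` exceeds
`κ_AMp n_AMp + κ_AM n_AM` (latch bridges bear force only against
extension), and a stuck band in between — continuous across both
thresholds. Under saturating Ca²⁺ at λ = 1 the sliding contracts
monotonically and plateaus at `u_fs = −0.03306`, where
`P_a = P_c = 66.61 kPa` (frozen regression values).

The active free energy handed to the continuum is
`Ψ_a = ½ μ_a L_fo (n_AMp+n_AM) ū_e²` with `λ = √Ī₄`; its first and second
derivatives with respect to the fourth invariant are analytic and
FD-verified.

## Continuum finite elements

Trilinear hexahedra with 2×2×2 Gauss quadrature; the volumetric penalty
`Ψ_vol = κ/2 (J̄−1)²` acts on the element-mean Jacobian (the condensed
Q1/P0 treatment; element pressure `p = κ(J̄−1)`). The isochoric passive
energy is `μ_p/2 (Ī₁−3) + c_p1/(2 c_p2)[exp(c_p2 (Ī₄−1)²) − 1]` with one
fibre family along the circumferential direction; active and passive fibre
terms both use the deviatoric invariant `Ī₄`. The reference `κ = 4.0 kPa`
is honoured as the default although it enforces incompressibility only
weakly against the active modulus (5301 kPa): converged states show
|J̄−1| up to ≈ 0.5, and a property test documents that J̄→1 monotonically
as κ is scaled ×10 and ×100. A consequence worth knowing: the weak penalty
lets volume change absorb part of the deviatoric active stress, so
isometric active force saturates noticeably below the raw CU driving
stress.

Stresses are analytic energy derivatives; the consistent tangent is
obtained by complex-step differentiation of the analytically assembled
element internal-force vector (exact to machine precision, deterministic,
and symmetric to round-off). Newton–Raphson with backtracking line search
solves each quasi-static step; when the plain direction stalls (the thin,
weakly-penalised ring passes local element-level snap-throughs during
loading) a Levenberg-damped direction is tried with increasing damping.
The linear solver is a sparse direct factorisation with deterministic
ordering. Loads enter only through prescribed displacements; hook forces
are reactions read off the internal-force vector (mm/kPa units give mN).

**Ring model.** One-eighth symmetry (quarter circumference × half width)
with symmetry-plane constraints; the hook contact is replaced by a
prescribed-displacement node strip on the inner surface within the arc
subtended by the hook radius. The strip is clamped in the loading plane
(u_x prescribed, u_y = 0) — the ring is clamped at the hooks, and an
x-only constraint lets the contact elements collapse through folds. The
hook force reported multiplies the strip reaction by the symmetry factor
4; a full-ring model with mirrored resolution reproduces it to 0.1%.
The default desk-scale mesh is 2×24×5 = 240 elements (the published
5750-element discretisation is reachable, e.g. 5×46×25, but not required
by any test); each element doubles as one SMC, and each of its 8 Gauss
points carries one CU.

**Loading phase.** The passive ring is driven to the 1 mN resting preload
by adaptive incremental continuation in the hook displacement plus a
secant/bisection refinement on the displacement–force curve (tolerance
0.5%). The response is bending-dominated (soft) until the ring ovalises,
then stiffens sharply as the fibres take tension; the preload lands in the
stiff branch at a hook displacement of ≈ 0.4 mm.

## Orchestration

Block-segregated loop with no feedback inside a step: cells (and CB) at
`dt_cell` (default 1 ms), CU update and implicit continuum solve at
`dt_solid` (default 0.1 s), CU fed with the stretch of the *previous*
continuum step (lagged coupling, no sub-iteration). CB states land on the
`dt_solid` grid by construction when `dt_solid` is a multiple of
`dt_cell`; a linear-in-time interpolation helper covers the general case.
A time-step refinement test (dt_solid = dt_cell vs 10×) bounds the
splitting error at 2% RMS in the hook force.

A run is: (1) passive loading to the preload; (2) a stationarity pre-roll
(default 200 s model time) that runs the *full* coupled loop from the
detached CB state (n_M = n_Mp = 0.5, u_fs = 0, χ/ζ/η = 0.1 µM/0.2 µM/
−0.02 V) with the protocol held at its onset values — running mechanics
during the pre-roll is essential, since attaching a fully developed CB
population to the stretched ring in one step is a load shock the
quasi-static solver cannot (and should not) absorb; (3) the protocol
phase with linear parameter ramps. Forces are normalised by F₀, the value
at the first sample at/after the intervention time. All randomness is the
seeded per-cell normal draw of Φ_A (s.d. 0.1 µM s⁻¹, negatives redrawn);
identical config + seed reproduces outputs exactly.

## Pharmacological protocols

* **Phenylephrine**: each cell's Φ_A is scaled ×7 linearly over the
  dilution time (50 or 100 s), taking the population mean from 0.6 to
  4.2 µM s⁻¹ and preserving the coefficient of variation.
* **CPA** (SERCA inhibitor): B_SR ramps down; two printed variants are
  shipped (`text`: 400→350 µM s⁻¹ over 2000 s, the default; `table`:
  400→200 over 1000 s) because the source reports both; the θ value for
  CPA is typographically ambiguous in the source (candidates 0.0, 3.0,
  30.0) and must be supplied explicitly.
* **Ryanodine** (RyR blocker): C_Ry ramps 1250→312.5 µM s⁻¹ over 2000 s
  starting at t = 100 s, with store-operated entry enabled (A_S = 0.1)
  and θ = 0.5; baseline Φ_A mean 0.8 µM s⁻¹.

## Collective behaviour and what the tests show

Synchronisation is quantified by the mean pairwise phase-locking value of
the cells' χ phases (peak-interpolated). Coupled oscillator tissue locks
into travelling waves rather than zero-lag states, so a lag-sensitive
global coherence statistic is the wrong readout; the phase-locking value
scores frequency entrainment regardless of fixed lags. On a 28-cell ring
with heterogeneous Φ_A it rises monotonically (≈ 0.08 → 0.13 → 1.0) over
coupling strengths α ∈ {0, 0.1, 1.0} s⁻¹ while the mean χ amplitude
changes by < 20%, and on a 48-cell ring the normalised hook-force
fluctuation under strong coupling exceeds the weakly coupled case —
coordinated cellular forces produce global tone oscillations where
uncoordinated ones average out.

Problem sizes in the test suite are desk-scale by design: coarse rings of
16–240 elements, populations of 28–1000 cells, simulated spans of 1–1000 s
chosen per test so the whole suite runs on one CPU. The synthetic
populations emulate only frequency heterogeneity through Φ_A; they do not
model cell-size dispersion, spatially correlated parameters, myograph
noise or stress relaxation of real tissue, so passing tests validate the
model implementation and its collective mechanisms, not quantitative
agreement with any particular vessel.

## Numerical choices summarised

* RK–Merson tolerances rtol 1e-7 / atol 1e-9; step-size underflow raises
  a stiffness diagnostic.
* Forward Euler for CB/CU with [0,1] and increment guards.
* Newton: relative residual 1e-8, up to 60 iterations, backtracking plus
  Levenberg fallback; element inversion and fibre-exponential overflow
  raise named diagnostics carrying the element index.
* Degenerate inputs (empty hook sets, dangling neighbour indices,
  asymmetric adjacency, non-positive stretches, negative concentrations)
  raise immediately rather than propagating silently.
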