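# vasoring

A multiscale simulator of active arterial-wall mechanics for vascular
physiologists and biomechanics modellers: it reproduces, in silico, the
isometric wire-myograph experiment in which a small arterial ring
(0.7/0.8 mm inner/outer diameter, 2 mm wide) is mounted on two 0.25 mm
steel hooks, preloaded to a resting tension of 1 mN, and challenged with
vasoactive drugs while the hook force is recorded.

Three models are coupled across two scales:

1. **Smooth muscle cell (SMC) Ca²⁺ dynamics** — each cell carries cytosolic
   Ca²⁺ χ (µM), sarcoplasmic-reticulum Ca²⁺ ζ (µM) and membrane potential
   η (V), driven by ten ionic pathways (NSCC, SOCC, VOCC, NCX, SERCA,
   ryanodine-receptor CICR, SR leak, plasma ATPase, Cl⁻ and K_Ca channels):

       dχ/dt = Φ_A + Φ_S + Φ_V + Φ_N − Φ_B + Φ_C + Φ_L − Φ_D + J_Ca
       dζ/dt = Φ_B − Φ_C − Φ_L
       dη/dt = γ (2Φ_V − Φ_N − Φ_Cl − Φ_K) + J_V

   Cells exchange Ca²⁺ and voltage through gap junctions with
   diffusivities α_C, α_V; the network is integrated by an adaptive
   Runge–Kutta–Merson scheme.
2. **Cross-bridge (CB) kinetics** — the four-state actin–myosin cycle
   (n_M, n_Mp, n_AMp, n_AM; n_M eliminated so Σn = 1 is exact), with the
   Ca²⁺-dependent phosphorylation rate τ₁ = θ τ₀ χ²/(χ²+χ₀²), advanced by
   forward Euler.
3. **Contractile units inside a fibre-reinforced hyperelastic FE ring** —
   at each Gauss point a contractile unit converts attached-bridge
   fractions into active stress P_a = μ_a L_fo(u_fs)(n_AMp+n_AM)(λ−1−u_fs)
   via a stick-slip filament-sliding law; the one-eighth-symmetric ring is
   solved quasi-statically with Q1/P0 hexahedra, a volumetric penalty
   Ψ_vol = κ/2 (J̄−1)², the passive energy μ_p/2(Ī₁−3) +
   c_p1/(2c_p2)[exp(c_p2(Ī₄−1)²)−1], and Newton–Raphson iteration.

Pharmacological probes are parameter ramps: phenylephrine (NSCC influx ×7
per cell), CPA (SERCA rate ramp-down) and ryanodine (CICR rate ramp-down
with store-operated entry switched on). See `docs/methods.md` for the full
model statement, assumptions and numerical choices.

## Worked example

Calibrate the passive ring to the 1 mN resting preload and inspect a single
cell's vasomotion:

```python
import vasoring as v

mesh = v.build_ring_mesh(v.RingGeometry(), (2, 24, 5))   # 240 hexahedra
system = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                    v.circumferential_fibre(mesh))
sol, d, force = v.loading_phase(system, mesh.node_sets["hook_contact"],
                                v.ring_model.myograph_bcs(mesh),
                                target_mN=1.0,
                                symmetry_factor=mesh.symmetry_factor)
print(f"hook displacement {d:.3f} mm -> force {force:.4f} mN")
```

prints

```
hook displacement 0.338 mm -> force 0.9998 mN
```

i.e. the secant calibration finds the hook separation at which the passive
ring carries the experimental resting tension (within the 0.5% tolerance).
The same from the shell, plus a single-cell trace:

```bash
$ vasoring single-cell --t-end 100 --phi-a 0.8
chi range [0.3089, 0.9294] uM over the second half; final eta -27.60 mV
```

— sustained vasomotion-like Ca²⁺ oscillation (period ≈ 1.26 s) between
0.31 and 0.93 µM, with the membrane near −28 mV. A full drug run:

```bash
vasoring run --config my_config.yaml --protocol ryanodine --seed 1 --out out/
```

writes the hook-force series (`force.csv`, absolute mN and F/F₀
normalised), per-cell state series (`cells.csv`), VTK snapshots and a run
manifest. `vasoring sweep-coupling --alphas 0,0.1,1.0` reports the
phase-locking order parameter of a heterogeneous cell population at each
gap-junction strength.

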