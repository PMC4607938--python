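# stretchpore

Analysis pipeline for **pore formation in stretched phospholipid/cholesterol
bilayers**: the complete analysis layer of unsteady-stretching rupture
studies of planar DPPC and DPPC + 40 mol% cholesterol bilayers, exercised
end to end on seeded synthetic pseudo-trajectories with known ground truth.

It is written for membrane biophysicists who have (or emulate) stretched
bilayer trajectories and want the standard observables and detection rules
of this kind of study without re-deriving them: stretching-schedule
mathematics, structural observables, trans-bilayer water-chain detection
defining the critical areal strain, and the replicate-level factorial
statistics.

## What it computes

For a square bilayer patch stretched equibiaxially from reference lateral
box length *l*<sub>x0</sub>:

- **areal strain** ε_A = (*l*_x/*l*<sub>x0</sub>)² − 1; unsteady stretching
  (US) grows the box edge at constant speed *c* via per-step affine scaling
  μ = (*l* + *c*Δt)/*l*, with the Berendsen weak-coupling factor
  μ_z = [1 − (Δt/τ_p)β(P₀ − P_z)]^{1/3} in the normal direction;
  quasistatic stretching (QS) holds a fixed area.
- **bilayer thickness** *l*_t: distance between the mean phosphorus planes
  of the two leaflets.
- **chain order parameter** S = (1/N_c) Σᵢ (3 cos²Θᵢ − 1)/2 over the
  N_c = 14 sn-2 chain segment axes (1 = z-aligned, 0 = isotropic,
  −0.5 = in-plane), and the **cholesterol tilt angle** θ_c between the
  C5→C21 ring axis and the bilayer normal.
- **interdigitation**: tail overlap length, and the transition index
  R_Li = (S − S^PD)/(S^DC − S^PD) locating a bilayer between a
  non-interdigitated (≈0) and an interdigitated-gel (≈1) reference at
  matched thickness.
- **critical areal strain** ε_c: the strain at which a chain of water
  molecules first spans the bilayer core (O–O connectivity cutoff 0.35 nm,
  periodic minimum-image distances), plus single/multi-pore classification
  and pore-lining hydrophilicity.
- **statistics**: unbalanced two-way ANOVA (composition × stretching speed,
  Type III), simple main effects, Ryan's step-down multiple comparison, and
  the cube-root reference-area scaling ε_scaled = ε_c (A_sim/A_ref)^{1/3}.

A seeded synthetic-bilayer generator (`stretchpore.synthetic`) produces
pseudo-atomistic frames whose thickness, chain order, tilt, interdigitation
and pore strain are set by construction, so every stage is testable for
exact parameter recovery without running molecular dynamics.

## Worked example

```python
import stretchpore as sp

comp = sp.CompositionSpec(n_dppc=24, n_chol=16, n_water=600, label="chol40")
lz = sp.synthetic.default_box(comp, l_x=4.0)[2]
sched = sp.build_schedule("US", c=1.0, frame_interval=80.0,
                          target_strain=1.7, l_x0=4.0, l_z=lz)
resp = sp.ResponseModel(l_t0=3.6, order_profile="recovery",
                        pore_strain=1.5, n_channels=1)
traj = sp.generate_trajectory(comp, sched, resp, seed=3)

series = sp.compute_series(traj)
report = sp.critical_strain(traj, cutoff=0.35, margin=0.3)
print(report.epsilon_c, report.classification)
# 1.5600000000000005 single
print(sp.scaled_critical_strain(1.43, a_sim_nm2=41.84, a_ref_um2=1000.0))
# 0.004964398046926703
```

The detected ε_c = 1.56 recovers the generator's ground-truth pore strain
1.5 within one frame's strain increment (~0.06 near detection), and the
classification is `single` because one water channel was inserted.  The
last line scales a simulation-box critical strain of 1.43 (the slowest
40 mol% cholesterol condition) from A_sim ≈ 42 nm² to a 1000 μm² cell-scale
membrane: ≈ 5 × 10⁻³, inside the 0.001–0.01 range measured on cells and
vesicles.

The same stages are scriptable from the shell:

```bash
stretchpore run --seed 7 --outdir run_out          # full demo experiment
stretchpore scale --epsilon-c 1.43 --a-sim 41.84 --a-ref 1000
stretchpore generate --speed 1.0 --pore-strain 1.5 --seed 3 -o traj.gro
stretchpore pores traj.gro -o pores.json
```

`run` writes per-replicate observable CSVs and pore reports, a
condition-level summary (n, speed, mean ± SD of ε_c, multi-pore rate), the
ANOVA/post-hoc tables, an R_Li-vs-speed table and a manifest.

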