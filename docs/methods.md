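# Methods

This note documents the models, conventions and numerical choices behind
`stretchpore`, and what its synthetic tests do and do not demonstrate about
real molecular-dynamics data.

## Scope and model of the system

The package analyses planar two-leaflet bilayers of DPPC, optionally with
cholesterol (the study compositions are 128 DPPC + 16,483 waters and
128 DPPC + 86 CHOL + 13,842 waters, ~42 nm² lateral area), in an
orthorhombic box with z as the bilayer normal and positions wrapped into
[0, l_i).  It does **not** run dynamics: no force field, thermostat,
barostat or integrator exists here.  The deformation module implements only
the *kinematics* of stretching; structural responses are either read from
real trajectories (GRO/PDB) or prescribed by the synthetic generator.

Atom-naming convention (required by the analysis and enforced on input):
DPPC carries one phosphorus `P` and sn-2 carbons `C1`..`C14`; cholesterol
carries the ring anchors `C5` (hydroxyl-bearing head end) and `C21` (chain
end); water oxygens are `OW`.

## Stretching schedules

Unsteady stretching (US) scales box and coordinates affinely each step with
the same lateral factor in x and y (equibiaxial stretching).  The per-step
factor is μ = (l + cΔt)/l, i.e. the box edge grows at constant speed c with
l(t) = l_x0 + c·t.  Whether the underlying protocol is linear-in-time or
per-step multiplicative is not decidable from the available description, so
an exponential variant (fixed μ evaluated at l_x0) is provided behind
`growth="exponential"`; linear is the default.  Units: 1 m/s = 1 nm/ns =
10⁻³ nm/ps, project-wide.

The normal direction uses the Berendsen weak-coupling factor
μ_z = [1 − (Δt/τ_p)·β·(P₀ − P_z)]^{1/3} with τ_p = 0.5 ps,
β = 4.5×10⁻⁵ bar⁻¹, P₀ = 1 bar.  Synthetic pipelines have no pressure, so
P_z defaults to P₀ (μ_z = 1, constant l_z) unless a pressure series is
supplied.  Quasistatic stretching (QS) holds the box at a fixed target
strain; its critical strain is therefore only *bracketed* by the largest
pore-free and smallest pore-bearing strains sampled.

## Observables

- **Areal strain**: ε_A = (l_x/l_x0)² − 1; l_x0 comes from trajectory
  metadata (for real data, the equilibrium average; the generator stores it
  explicitly).
- **Leaflets/thickness**: lipids are assigned to leaflets by their anchor z
  (P for DPPC, C5 for CHOL) relative to the mean of all P z.  l_t is the
  distance between the upper and lower mean P planes.  This assumes the
  bilayer is not split across the periodic z boundary; inputs should be
  recentred first (the generator builds frames centred at l_z/2).
- **Chain order parameter**: the molecular axis at carbon i is the vector
  from carbon i−1 to i+1 (ends use their single neighbour) — the standard
  molecular-axis convention, which makes S = 1 exact for straight z-aligned
  chains.  S is averaged over the 14 sn-2 segments and then over molecules;
  the per-molecule spread is reported as the SD.
- **Cholesterol tilt**: θ_c = arccos(|v_z|/‖v‖) for v = r(C21) − r(C5),
  folded to [0°, 90°] so the two leaflet orientations (±z) report the same
  acute angle.
- **Tail overlap length**: L_ov = max(0, ⟨z lower-leaflet C14⟩ −
  ⟨z upper-leaflet C14⟩): the crossing distance of the mean terminal-carbon
  planes, positive iff the leaflets interdigitate.  Chosen as the simplest
  statistic that is monotone in the generator's interdigitation depth,
  which is the property the tests rely on.
- **Transition index**: R_Li = (S − S^PD)/(S^DC − S^PD), where S^DC and
  S^PD are the order parameters of a cholesterol reference run at ε_A = 1.0
  (where the interdigitated-gel transition completes) and of a pure-DPPC
  reference at the *same thickness*.  S at matched thickness is averaged
  over all frames within ±0.08 nm of the target (falling back to the single
  closest frame) to suppress molecule-sampling noise in finite systems;
  ties in the closest-frame search resolve to the earliest frame.  R_Li is
  reported unclipped.

## Pore detection and the critical strain

Waters are nodes of a graph with an edge when the O–O minimum-image
distance is ≤ cutoff (default 0.35 nm, the first hydration shell; the
underlying protocol does not state one, so it is a config key).  The plain
water graph is periodic in x, y and z.

**Spanning** cannot be defined on the fully periodic graph: the upper and
lower bulk slabs of any solvated bilayer are one component through the
z boundary.  Detection therefore recentres the P midplane to l_z/2 and
drops z-periodic edges; a component spans when it contains waters above the
upper and below the lower P plane, with both planes inset by `margin`
(default 0.3 nm) toward the midplane so that detection does not depend on a
chain fully exiting into bulk.  ε_c is the areal strain of the first
spanning frame, scanning in time order; single-frame spanning suffices (no
persistence requirement — persistence is observable in the per-frame
counts).

**Pore counting**: waters of spanning components restricted to the core
slab (|z − midplane| < l_t/2 − margin) are re-clustered with the same
cutoff (xy-periodic); clusters of fewer than 3 waters are ignored as noise
(configurable floor); centres are circular means per axis.  Because
multi-pore events are transient, the single/multi classification takes the
maximum simultaneous count over a 5-frame window from first detection
(configurable).  **Lining hydrophilicity** is the head-group fraction
(default set: DPPC `P`, CHOL `C5`) among non-water atoms within a shell
(default 0.5 nm) of core pore waters.

## Statistics

Critical strains form an unbalanced two-factor design (composition ×
speed).  The default ANOVA is Type III with sum-to-zero contrasts (the
appropriate choice when the interaction is tested first); Type II is a
config alternative.  `anova_from_summary` reconstructs per-cell data with
exactly the given mean/SD/n — sufficient statistics for the ANOVA — so
published summary tables can be analysed directly.  Simple main effects
test one factor within a level of the other against the pooled residual of
the full model.

Ryan's step-down multiple comparison orders the k group means and tests the
pair spanning r ordered means at an adjusted level α′(r), with the
step-down rule that a pair nested inside a non-significant span is never
declared significant.  Two variants are provided:

- `linear` (default): α′(r) = α·r/k with two-sided t p-values on the pooled
  residual variance.  This variant reproduces the qualitative significance
  patterns reported for factorial stretching studies, but its gate tests
  the *selected* extreme pair with an unadjusted t statistic, so its
  familywise error under a complete null is controlled only loosely
  (simulations here give ~0.2–0.3 at nominal 0.05 for k = 4–7).
- `regw`: α′(r) = 1 − (1−α)^{r/k} for r ≤ k−2 (α otherwise) with
  studentized-range p-values (Tukey–Kramer standard errors for unequal n).
  The full-span gate is then an exact range test and the complete-null
  familywise error is held at α (verified by simulation in the test suite).

Both reduce to the ordinary two-sample t test for k = 2.  α = 0.05
throughout; p-values are reported at full double precision.

The cube-root scaling ε_scaled = ε_c·(A_sim/A_ref)^{1/3} maps finite-box
critical strains to cell-scale reference areas (1 μm² = 10⁶ nm²); it
ignores stretching-speed effects and is a first-order comparison device
only.

## The synthetic generator

The generator emulates the *analysis-relevant geometry* of a stretched
bilayer, not its physics:

- DPPC = head bead `P` + 14 colinear sn-2 carbons at 0.125 nm spacing;
  CHOL = rigid 0.9 nm rod `C5`→`C21`.  Lipids sit on a jittered square
  lattice, half per leaflet; P planes are separated by the requested
  thickness (z-jitter SD 0.02 nm); terminal carbons extend the requested
  interdigitation depth past the midplane.
- Chain/rod axes are drawn from a *Gaussian cap*: polar angle
  Θ = |N(0, σ)|, azimuth uniform.  This gives the exact closed form
  E[S] = (1 + 3e^{−2σ²})/4 (since E[cos 2Θ] = e^{−2σ²}), which the
  parameter-recovery tests check against Monte-Carlo and which is inverted
  to drive a target S profile.
- Water fills the two slabs outside the core on a simple-cubic lattice at
  33 beads/nm³, jittered by 10% of the spacing; exact requested counts are
  kept by uniform subsampling of lattice sites.  No solvent structure is
  claimed.
- Trans-bilayer channels are solid cylinders of water beads (axial and
  lateral pitch ≤ 0.25 nm ≤ cutoff, radius 0.2 nm) running slightly past
  both P planes; insertion never moves existing atoms.  Channels closer
  than the bead pitch merge into one detected pore.
- Trajectories follow a schedule; thickness follows a rule (default
  volume-conserving l_t = l_t0/(1+ε_A), l_t0 = 4.0 nm ≈ a DPPC/CHOL
  bilayer); chain axes are resampled per frame from the order profile.
  Profiles: `monotone_decrease` (S = 0.75 − 0.28 ε_A, floor 0.31 — the
  pure-bilayer phenomenology) and `recovery` (a shape-preserving PCHIP
  through control points that dip near ε_A ≈ 0.5, recover, peak at
  ε_A = 1.0 and decay — the interdigitated-gel signature of the
  cholesterol-rich bilayer at slow stretching).  Channels appear at all
  frames with ε_A ≥ the configured pore strain, so the detected ε_c equals
  the configured value up to one frame's strain increment.
- Randomness: a single `numpy` Generator seeded per run; frame k uses the
  substream (seed, k) so any frame is reproducible in isolation, and the
  molecule layout uses a trajectory-level substream so all frames share a
  topology (required for multi-frame formats and physically sensible).

**What passing tests show — and don't.**  Ground-truth recovery on these
frames validates the *estimators and detection rules*: formulas, leaflet
logic, periodic-distance clustering, threshold behaviour, statistical
procedures.  It does not validate force fields, sampling, water structure,
pore energetics or kinetics, nor that real bilayers follow the prescribed
response profiles; on real trajectories the observables are only as good as
the underlying simulation.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down systems (12–400 lipids,
120–1,400 waters, 40–90 frames per trajectory) — large enough that
molecule-sampling noise is controlled (per-frame SE of S ≈ 0.04–0.07 for
24–60 molecules; shape assertions use strain-window means), small enough
that the full suite runs in a couple of minutes on one CPU.  Monte-Carlo
oracles use 10⁶ draws; null calibrations use 200–1,000 replications with
agreement bands of ±3 binomial SE.  Graph construction uses
`scipy.spatial.cKDTree` with per-dimension periodic box sizes; equality
with an O(n²) 27-image union-find oracle is asserted over randomized
frames.  GRO coordinates round-trip at 0.001 nm (file precision), PDB at
0.0001 nm; PDB multi-frame files carry one CRYST1 cell.

## Known limitations

- Leaflet assignment and spanning detection assume an unsplit, roughly
  midplane-centred bilayer; systems wrapped through the z boundary must be
  recentred first.
- The US schedule discretizes strain by frame interval; ε_c is quantized to
  one frame's strain increment (which grows with strain under linear edge
  growth).
- `anova_from_summary` is exact only for the ANOVA family; it cannot
  reconstruct rank-based or robust statistics from summaries.
- The default Ryan variant trades strict familywise-error control for
  agreement with published reporting practice (see above); choose `regw`
  when control matters.
- The generator's response profiles are stylized; the non-monotonic
  `recovery` shape and the thickness rule are conventions for testing, not
  fits to data.
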