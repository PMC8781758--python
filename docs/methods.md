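# Methods

## The mechanical model

A rectangular cortical-bone beam (width *w*, height *h*) sits in a
four-point-bend fixture: outer supports a distance *a* outside each inner
loading point, inner span *b* under constant bending moment. A surface
stress σ on the extreme fiber corresponds to a machine load
*F* = σ·w·h²/(3a) and an inner-span moment *M* = σ·w·h²/6 (the lever arm
cancels). Defaults follow the study protocol this package emulates:
w = h = 6 mm, a = 4 mm, b = 34 mm, fatigue peak 120 MPa, strain images
captured at a 66 MPa hold.

Bone is bimodular — its effective modulus differs in tension and
compression — and fatigue damage grades the modulus through the thickness.
Both effects are captured by a logarithmic functionally-graded law about the
neutral axis (y measured from the axis, positive toward the compression
face):

    E(y) = E0 · [1 − ln(1 + α_C · y / h_ref)],   0 ≤ y ≤ h_C
    E(y) = E0 · [1 − ln(1 − α_T · y / h_ref)],  −h_T ≤ y ≤ 0

E0 is the neutral-axis modulus, assumed constant over fatigue life; h_ref
(default 6 mm, the nominal section height) scales the logarithm argument;
α_C and α_T are the per-instant gradient parameters. **Sign convention:**
positive α means the side *softens* with distance from the axis. The two
branches meet continuously at E0 (ln 1 = 0), and α_C = α_T gives a
mirror-symmetric profile. Admissibility requires the log argument positive
and E > 0, i.e. −h_ref/d < α < (e−1)·h_ref/d for a side of depth d; negative
α (stiffening away from the axis) is allowed.

### From strains to the neutral axis

Plane sections give ε(y) = y/ρ. With measured surface strain magnitudes
ε_C, ε_T the section splits as

    h_C = h·ε_C/(ε_C+ε_T),  h_T = h·ε_T/(ε_C+ε_T),  ρ = h/(ε_C+ε_T),

so a faster-rising compressive strain drags the neutral axis toward the
tension face.

### Balance equations and the inverse problem

Writing the generic side integrals

    J1(α, d) = ∫₀ᵈ [1 − ln(1 + α·y/h_ref)]·y dy,
    J2(α, d) = ∫₀ᵈ [1 − ln(1 + α·y/h_ref)]·y² dy,

zero net axial force and the applied moment require

    J1(α_C, h_C) − J1(α_T, h_T) = 0,
    J2(α_C, h_C) + J2(α_T, h_T) = M·ρ/(w·E0).

Both integrals have closed forms in log1p (validated against adaptive
quadrature to better than 1e−10 relative); below |α·d/h_ref| = 0.01 a
Maclaurin series (14 terms) replaces the closed form to avoid cancellation.

The inverse solve exploits monotonicity: J1 decreases strictly in α, so for
fixed α_C the force balance defines α_T uniquely (inner bracketed root);
along that constraint the moment residual decreases strictly in α_C (outer
root). Both roots use Brent's method at xtol = 1e−14 after a 64-point
admissibility-aware scan for the outer bracket; the solver is deterministic.
Post-conditions: |force residual| < 1e−9·h², |moment residual| < 1e−9·h³.
The forward map (strains from known α's) solves the force balance for h_C —
strictly increasing, hence a unique split — then reads ρ from the moment
balance. Forward∘inverse round trips recover α to ~1e−12 on a 20×20 grid.

### E0 calibration

How E0 is fixed is genuinely open; the default (`homogeneous_initial`)
chooses the homogeneous-beam value that makes the pre-fatigue strain sum
exact with α = 0: E0 = 2σ_meas/(ε_C0+ε_T0) ≈ 23.46 GPa on the default
baselines — physiologically plausible for bovine cortical bone. A fixed
override is config-selectable. Strains are microstrain at every I/O
boundary, dimensionless internally; stresses MPa, lengths mm, moments N·mm.

## Strain-phase fits

The compressive strain shows two linear phases with a kink near 28% of
life. `fit_two_segments` tries every interior observed life fraction as the
breakpoint (the kink sample belongs to both segments), fits each side by
ordinary least squares, and keeps the breakpoint minimizing pooled SSE;
with ~11 observations a continuous profile search adds nothing. r² is
pooled over both segments against the global mean (the convention behind
any single printed r² is ambiguous; pooling is stated explicitly here).
A constant response is reported as a perfect fit (r² = 1) by convention.

## Synthetic trajectories

No raw strain data is publicly deposited, so the generator emulates the
measurements' structure: ε_C(t) piecewise linear with the kink at t = 0.28,
ε_T(t) linear with a 4% total rise, baselines at the measured averages
(2819 / 2807 με), 11 samples with the breakpoint always on the grid, and
additive i.i.d. Gaussian noise (default 20 με, the order of DIC strain
resolution; no measurement uncertainty is published, so this is a stand-in).
The phase rises are likewise unpublished; the defaults — 500 με over the
first phase, 280 με over the second — reproduce the fast-then-slow shape
with a total rise of ~28% of baseline. Same seed, bit-identical output.

What the generator does *not* emulate: inter-specimen variance structure,
drift or spatial correlation in the DIC readings, and any coupling between
noise on ε_C and ε_T. Passing tests therefore demonstrate correctness of
the estimation machinery under the stated noise model, not robustness to
every artifact of real speckle imaging.

Forward fixtures (exact strains computed from prescribed α paths) provide
ground truth for recovery tests; noiseless fixtures satisfy both balances
to 1e−9 scale by construction.

## Finite-element verification

A plane-stress solver (4-node bilinear quadrilaterals, 2×2 Gauss,
thickness w) independently checks the analytical model. The mesh is a
structured grid over outer-span × height with node columns exactly at the
four contact positions (nx must make that possible; ny even so a node row
lies at mid-depth). Element moduli sample the graded profile at centroid
height relative to the *analytically* located axis — the FEM never imposes
the axis; it emerges as the zero line of ε_xx, extracted at mid-span by
linear interpolation between element-centroid samples (centroid-x sampling
avoids the inter-element strain jump of bilinear elements). Supports:
vertical restraint at both outer contacts, horizontal at one; F/2 at each
inner contact as nodal loads (the 2 mm experimental contact radius is not
modeled; mid-span extraction keeps Saint-Venant distance from the loads).
Poisson's ratio defaults to ν = 0.3, a common cortical-bone value; it is
config-exposed.

At the reference mesh (126 elements along the 42 mm span × 24 through the
thickness; element aspect ratio 1) the homogeneous beam reproduces the flexure-formula
surface strain within 0.14% and graded cases agree with the analytical
neutral axis within 0.01% of the section height, shrinking monotonically
under refinement with observed order ≈ 2. These cross-method checks stand
in for a FEM-vs-experiment comparison, which would need the raw strain
fields.

## Problem sizes

The packaged analyses use 11-point trajectories, a 20×20 parameter grid for
round-trip verification, 100 seeded replicates for breakpoint-recovery
statistics, and FEM meshes up to 126×24 (≈6,300 degrees of freedom) with a
three-level refinement study — sizes chosen so the full pipeline solves in
seconds while leaving discretization error far below the quantities
compared.

## Known limitations

- With the measured strain trends (fast-rising compression, slow-rising
  tension) the balance equations force the tension side to stiffen
  modestly relative to E0 over life (+14% at the tension surface in the
  default demo) while the compression side degrades strongly (−39%). A
  reading in which *both* surface moduli degrade is not attainable under
  constant E0 with these balances; relaxing the constant-E0 assumption
  would be required, and is out of scope.
- Constant E0(t) is an assumption, not a measurement; all degradation is
  expressed through the gradient parameters.
- The constitutive law is isotropic along the beam axis only; orthotropy,
  porosity, damage-rate laws predicting cycles-to-failure, and 3-D stress
  states are out of scope.
- Trajectory records that fail to solve are flagged (or skipped on
  request), never silently dropped; per-specimen and averaged-trajectory
  analyses are both possible since any trajectory CSV can be fed through
  the same pipeline.
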