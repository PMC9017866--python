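# Methods

`chainforc` models the magnetic signatures of magnetosome chains — the
fossilizable magnetite nanocrystal chains of magnetotactic bacteria — at
the level of one uniformly magnetized moment per crystal.  This note
documents the model, its numerical choices, the parameters that matter,
and what the synthetic ensembles do and do not represent.

## Energetics

The state of a chain of N crystals is the set of unit moment directions
u_1..u_N.  Its free energy is

    F = Σ_i [ ½ μ₀ Ms² V_i u_i·N_i·u_i                      (shape)
            + K₁V_i (a₁²a₂² + a₂²a₃² + a₃²a₁²) + K₂V_i a₁²a₂²a₃²
            − Ms V_i u_i·B ]                                 (Zeeman)
      + Σ_{i<j} u_i·F_ij·u_j                                 (interaction)

with a the moment in the cubic crystal frame, N_i the demagnetizing
tensor and F_ij the pairwise magnetostatic coupling matrices, computed
once per chain.  Uniform magnetization is assumed throughout; this holds
well for magnetosome sizes up to ~50 nm and avoids intra-crystal
(exchange, vortex) physics entirely.

Material constants (magnetite, room temperature): Ms = 480 kA/m,
K₁ = −1.1·10⁴ J/m³ (easy axes along <111>), K₂ = 0, T = 293 K.  The
spontaneous magnetization is fixed independently by the closed-form
two-crystal barrier (3μ₀m²/4πr³ = 439.9 kT for 50-nm spheres with 5-nm
gaps); the cubic constant is the standard literature value — switching it
off changes the ensemble statistics by well under the stochastic scatter.

* Demagnetizing tensors: triaxial ellipsoids use the classical
  elliptic-integral closed form (Carlson R_D).  Cylinders use the exact
  axial magnetometric factor obtained by reducing the surface-charge
  double integral over the end disks to 1-D integrals of complete
  elliptic integrals (N_z(L/D = 1) = 0.3116); a cubic spline over aspect
  ratio serves repeated evaluation.  Chamfered ends (conical-frustum cut,
  imitating crystal faceting) scale the axial factor by a correction
  interpolated from a table precomputed by surface-charge quadrature on a
  fixed mesh topology, so the quadrature bias cancels in the ratio; the
  change stays below 10 % for realistic geometries.  A slight
  cross-section ellipticity splits the transverse factors in the
  proportion of the equivalent ellipsoid.
* Interaction tensors: spheres couple exactly as point dipoles and
  near-spherical ellipsoids are treated the same way.  Faceted prismatic
  crystals facing each other across a small gap are integrated by
  surface-charge quadrature (triangulated surfaces, centroid rule, with
  optional Richardson extrapolation over mesh levels; the sphere-pair
  oracle converges to the analytic dipole tensor to 1 part in 10⁴).
  Beyond about two crystal extents the point-dipole form is used: the
  remaining multipole correction is sub-percent and decays quadratically
  with separation.

## Chain geometries

Four architectures are generated from parameter distributions: single
strands; native double strands with staggered crystals (each crystal of
one strand faces the gap between two of the other); fold-collapsed double
strands with side-by-side crystals, antiparallel fold topology and
tapering only at the free ends; and rings.  Conventions: center spacing
along a strand is the mean of adjacent axial extents plus the
diameter-normalized gap g times the reference diameter; strands sit one
reference diameter times (1 + g) apart laterally; ring crystals sit on a
circle with chord d(1 + g).  The staggered double-strand convention
(lateral spacing d(1+g), half-spacing axial lag) reproduces the
parallel/antiparallel state-energy splittings of the idealized reference
geometries to 0.1 kT, which pins it among the plausible alternatives.

Default randomization (one documented schema in `ChainConfig` /
`EnsembleSampler`): equant crystals are near-isometric triaxial
ellipsoids, mean diameter 50 nm; prismatic crystals are chamfered
cylinders 60 × 40 nm with chamfer fraction 0.2 and slight random
ellipticity; size coefficient of variation 0.15 (lognormal, exact-moment
parameterization); one <111> axis within a Gaussian 5° of the local chain
axis; gaps lognormal with median 0.1 and log-sd 0.25; tapering 0.2 over
the outer three crystals; crystal count uniform on 10–20 per chain;
strand lag Gaussian (0.5, 0.1); twist uniform 0–15°/crystal; bending a
circular arc with curvature up to 1/(20 chain lengths).  These stand in
for the (unpublished) image-derived distributions of real chains; they
are placeholders in exactly that sense and live in one place so they can
be revised.

## Local-energy-minimum tracking

Hysteresis and FORC protocols are simulated athermally: starting from
positive saturation (a single energy minimum), the state is relaxed at
every field step seeded with the previous minimum.  Barkhausen jumps
occur where the tracked minimum ceases to exist and are logged per branch
when the moment change exceeds 1 % of the chain's saturation moment.

The minimizer is a monotone projected Barzilai–Borwein descent on the
product of unit spheres (jitted), with a torque tolerance of
10⁻⁶ μ₀Ms²V̄ (≈ 5·10⁻³ kT/rad) — small enough to place every switching
field within one field step, large enough that warm-started relaxations
cost tens of iterations.  Monotonicity keeps the iterate inside the
current basin, which is what LEM tracking requires.  A deterministic
transverse kick of 10⁻³ rad precedes each relaxation so that states
parked exactly on unstable equilibria (moment antiparallel to the field)
destabilize at the analytic switching field rather than hanging on a
zero-gradient maximum; the kick is far below the jump-detection
threshold.

The default protocol is ±300 mT; ensembles in the test and acceptance
runs use 3 mT steps and 200 chains per configuration (the desk-scale
setting; 1 mT steps and 10⁵ chains are plain configuration knobs).
Ensemble orientations are drawn with the polar cosine stratified across
the ensemble and random azimuth/roll: the distribution is uniform, but
the orientation-sampling variance — which at 200 chains would alone be
±0.04 in Mrs/Ms — is removed.

A closed-form Stoner–Wohlfarth fast path (`chainforc.sw`) handles
random-orientation uniaxial single-domain reference ensembles with a 1-D
Newton tracker; it reproduces the astroid switching fields of the generic
machinery and makes 10⁴-particle FORC grids cheap.

## FORC processing

The FORC function ρ = −½ ∂²M/∂B_r∂B is estimated by locally weighted
second-order polynomial regression (tricube weights) with a variable
window: half-width 1 cell over the central ridge, growing at rate
λ = 0.08 with distance from it, capped at 4 cells — the variable-
smoothing strategy of the published VARIFORC scheme.  Magnetization
integrals (M_forc, M_cr) use the (B_r, B) measure, fixed by two oracles:
an aligned square-loop population must return its saturation
magnetization as ridge mass (exact by construction of the synthetic
fixture), and the recovered M_cr/Ms and M_forc/Ms of the simulated
single-stranded ensembles then match the reference forward-model values
to about 1 %.

Central-ridge isolation subtracts, per coercivity column, a background
extrapolated from flanking strips on either side of the ridge band
(default half-width max(3 mT, 2.5 cells)).  Two background models are
provided: `sqrt` (default) fits a + c·|B_u|^(−1/2) per flank, capturing
the square-root soft-mode divergence of the reversible continuum that
hugs the ridge in athermal simulations; `linear` interpolates linearly,
which suits thermally smeared measured data.  With the sqrt model the
pipeline recovers the exact synthetic ridge mass to 0.2 % and sits ~2 %
under the delta-ridge mass of the exact athermal Stoner–Wohlfarth
computation (whose orientation-averaged switching jump is ⟨Δm⟩ = 0.584,
obtained by high-resolution 1-D minimum tracking with Gauss quadrature
over orientations).

Coercivity spectra: f_cr integrates the ridge over B_u (calibrated so its
B_c integral equals M_cr); f_dcd is half the derivative of the backfield
remanence curve read off the grid; f_hys comes from the logged jump
events of the lowest branch (exact in simulations) or from an
ascending-branch increment estimator for measured grids (documented
approximation).

## Thermal-activation barriers

Zero-field transitions between remanent states are computed with the
zero-temperature string method (projected gradient descent plus
arc-length reparameterization, endpoints fixed), followed by iterative
re-interpolation of the highest-energy segment, and reported as
β₀ = ΔE/kT.  Idealized reference geometries use identical spheres with
dipolar coupling only (the constant spherical demag term is dropped).

The dipolar energy landscape has several saddle families, and which one a
path optimization converges to is set by the initial path and its
symmetry — so the path families are explicit:

* single strands (N > 4): a reversed domain nucleates at one end and a
  ~3-crystal transition region propagates to the other end; the path is
  free in 3-D (the wall fans azimuthally) with a small deterministic
  symmetric-breaking perturbation, and the barrier is the minimum over a
  few perturbation replicates.  The documented two-domain initializer
  (middle moment forced perpendicular, one domain's couplings weakened by
  1 %) is provided as `two_domain_seed`.
* short strands (N ≤ 4): pinned to the coherent-rotation family, whose
  N = 2 saddle is the closed form 3μ₀m²/4πr³, although symmetric fanning
  has a lower saddle — the reference family for the shortest chains.
* rings: the high-moment state is the *saturation-remanent* onion — two
  opposed-vorticity tangential domains whose walls are canted toward the
  saturating in-plane field — obtained by LEM-tracking the field down
  from saturation (it lies a few to ~20 kT above the fully symmetric
  onion, and its energy is what the reference barrier tables are
  consistent with).  The transition migrates one domain boundary into the
  other while wall moments rotate over the ring axis; this family is
  pinned by projecting the radial component out of the string forces.
  The two migration directions are inequivalent (the field canting breaks
  the symmetry) and both are explored; the cheaper one is reported.
* double strands: one strand reverses via a travelling wall.  In the
  staggered native geometry the wall is locked into the plane containing
  the two strands (the stagger's diagonal couplings penalize azimuthal
  fanning); in the side-by-side fold-collapsed geometry the wall fans
  freely in 3-D.  Both wall entry ends are explored.

Convergence: 64 images; a step cap of 0.05 rad; early termination when
the whole energy profile is stable to 10⁻³ kT over 50 reparameterization
cycles (10⁻⁵ kT during saddle refinement).

The Néel–Arrhenius law τ = τ₀ exp(β₀) (τ₀ configurable in 0.1–1 ns)
converts barriers to lifetimes.  Blocking diameters exploit the exact
cubic scaling of dipolar energies under self-similar rescaling
(diameter-normalized gaps): one barrier evaluation at a reference
diameter anchors β₀(d) = β₀(d_ref)·(d/d_ref)³, which a second independent
path optimization confirms to 1 %.

## What the synthetic ensembles do not capture

No thermal activation during field sweeps: measured central-ridge
vertical offsets (0.3–0.5 mT) and viscous ridges are absent by design,
and the simulated switching fields are the athermal LEM values.  No
bullet/tooth-shaped crystals, no multi-strand bundles beyond two strands,
no maghemitization (spontaneous magnetization is stoichiometric
magnetite's), no mechanical collapse dynamics — the fold-collapsed
geometry is imposed, not simulated.  The parameter distributions are
plausible stand-ins rather than image-derived statistics, so passing
ensemble checks demonstrates the machinery and the geometry-driven
signatures (central ridge fraction, squareness ordering across
architectures), not a quantitative match to any particular culture or
sediment.

## Known numerical limitations

* M_forc carries a small positive residue (a few percent) from
  reversible contributions that do not fully cancel on the truncated
  ±300 mT grid; M_cr/M_forc is correspondingly a few permil to a few
  percent low (quantified on the Stoner–Wohlfarth ensemble, where
  M_cr = M_forc holds analytically).
* The centroid-rule surface quadrature is percent-accurate for facing
  prismatic crystals at the default mesh level; the Richardson-
  extrapolated two-level mode (used in the oracle tests) reaches 10⁻⁴.
* Barrier values depend on the path family as described; the package
  reports the family documented above, and the ring results for some
  crystal counts are sensitive to the migration-direction choice (see
  the discussion of inequivalent directions).
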