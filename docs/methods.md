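# Methods

## The problem

When a long bone fractures, repair proceeds through an external bridging
callus — a functionally graded composite of mineralizing woven bone (hard
callus) and fibrous/cartilaginous interstitial tissue (soft callus).
Image-based virtual mechanical testing estimates the structural rigidity of
the healing limb from a CT scan: each image voxel becomes a finite element
whose Young's modulus is mapped from its calibrated radiodensity, and a
torsion test is simulated on the resulting model. A density–modulus law
calibrated on intact cortical bone works well on intact bones but treats
every low-density voxel in the callus as "soft bone", which systematically
over-predicts the rigidity of osteotomized limbs. `callusfe` implements
the dual-zone remedy — treat sub-threshold tissue as soft callus with its
own modulus — and the optimization machinery that fits the two extra
parameters to physical torsion-test data.

## Material models

Single-zone (bone scaling law):

    E = a * rho^b,   ovine calibration a = 10225 MPa, b = 1.0

with `rho` the phantom-calibrated radiodensity expressed in gHA/cm³. The
coefficient is interpreted as applying to density in gHA/cm³ (equivalently
E[MPa] = 10.225 · rho[mgHA/cm³]): applied literally to mgHA/cm³ values the
same coefficient would give ~10⁷ MPa at cortical densities, four orders of
magnitude above any physiological bone modulus, whereas the gHA/cm³ reading
gives 10–20 GPa at cortical densities (1000–2000 mgHA/cm³), consistent with
ovine cortical bone. The unit convention is explicit in
`MaterialLaw.density_units`.

Dual-zone (piecewise callus law):

    E(rho) = E_sc              if rho <  rho_cut
           = a * rho^b         if rho >= rho_cut

The boundary density takes the bone branch. `rho_cut = 0` degenerates
exactly (bitwise, elementwise) to the single-zone law. Candidate soft-callus
moduli span the literature uncertainty for fibrous/cartilaginous repair
tissue on a logarithmic grid: E_sc ∈ {0.5, 5, 50, 500} MPa. Poisson ratio
is 0.3 for every element. Elements whose bone-branch modulus falls below a
floor of 0.01 MPa (zero-density voxels pulled into a wrapped domain) receive
the floor instead, which is four orders of magnitude below the smallest
candidate E_sc and cannot influence results at reported precision.

## Virtual torsion test

Voxel micro-FE: one 8-node trilinear hexahedron per segmented voxel,
full 2×2×2 Gauss integration (no hourglassing), node coordinates in mm,
moduli in MPa. Boundary conditions follow the physical test protocol: the
distal cross-section is fixed in all DOF; every node of the proximal
cross-section is displaced in-plane by the exact rigid rotation (not the
small-angle linearization — exactness is free) of 1° about the centroidal
long axis, with the axial DOF left unconstrained; all other DOF are free.
The 5 N axial preload of the physical protocol is omitted; it is negligible
for rigidity. Virtual torsional rigidity is

    VTR = M · L / φ   [N·m²/°]

with M the reaction moment about the centroidal axis, L the distance
between the constrained planes (the working gauge length) and φ the twist.
Reactions are evaluated at both constrained planes; their imbalance is
reported (`moment_check_rel`) and is at round-off level for converged
solves. Element strains are evaluated at element centroids; the equivalent
strain is the von Mises (deviatoric) measure sqrt(2/3 · e:e), which equals
γ/√3 in pure shear.

Linear solver: the reduced stiffness system is symmetric positive definite.
Below 2 000 free DOF a sparse LU factorization is used; above it,
Jacobi-preconditioned conjugate gradients with relative tolerance 1e-8.
Benchmarks on this solver's meshes showed 3-D elasticity LU fill-in makes
CG the faster path from a few thousand DOF upward (6 s vs 145 s at ~10⁵
DOF), so the direct path is reserved for very small systems. Both paths
are deterministic for fixed inputs.

Accuracy is controlled by an analytic oracle rather than by matching any
particular commercial mesher: a homogeneous hollow cylinder (ro = 10 mm,
ri = 7 mm, E = 10 GPa, ν = 0.3) has closed-form rigidity G·J·π/180 =
0.8013 N·m²/°, independent of length. The test suite runs the voxelized
cylinder under halving refinement (1.6 → 0.8 → 0.4 mm); the error falls
monotonically (≈14% → 4.8% → 0.3%) and is within 5% at the 0.4 mm
clinical-style voxel pitch. A halving sequence is used because the voxel
staircase makes the geometric error oscillate between arbitrary spacings;
the FE discretization error itself only shrinks under refinement.

## Image pipeline

* Calibration: ordinary least squares through phantom rod readings
  (HU, mgHA/cm³); applying it is an affine map with negative outputs
  clamped to zero (the power law needs non-negative density and air/marrow
  noise can dip below the line).
* Down-sampling: trilinear interpolation at the new voxel centres onto the
  coarser isotropic grid (default 400 µm, a clinical-style resolution).
  Block averaging is not applicable because the emulated native pitch
  (60.7 µm) is not an integer divisor of the target.
* Segmentation: global threshold plus largest-connected-component
  retention — an objective, reproducible surrogate for interactive
  segmentation. The threshold is a required configuration value (default
  150 mgHA/cm³ for the synthetic phantoms, chosen between the soft
  background and the lowest callus densities).
* Wrap: morphological closing with a 1 mm ball followed by removal of
  components smaller than a 0.5 mm ball, mirroring the gap-closing /
  smallest-detail parameters of surface-wrapping tools. It is idempotent.
  The default pipeline does not apply it: closing can pull near-zero-density
  background voxels into the domain, whose bone-law modulus would fall
  below E_sc and void the monotonicity guarantee discussed below.

## Synthetic phantoms

The generator emulates the study inputs that are not publicly depositable:

* Intact bone: hollow cylinder (cortex) at a cortical density mean ± sd
  (Gaussian per-voxel noise, truncated at 0) on a soft background.
* Osteotomized bone: the cortex is interrupted by a transverse gap (3 mm
  noncritical or 17 mm critical defect) at mid-diaphysis, the gap annulus is
  filled at a soft gap density, and a fusiform external callus
  (cosine-tapered radius — the simplest bulge with no free parameters
  beyond max radius and axial extent) bridges the gap. Callus density
  grades linearly from its peak at each callus extremity down to the gap
  value at the fracture line, the simplest profile consistent with callus
  that is most mature away from the fracture.
* Cohorts: per-specimen multiplicative Gaussian jitter on geometry and
  density parameters around a template; three dataset labels with
  dataset 3 carrying the 17 mm defect; all randomness through one seeded
  generator per call.
* Simulated physical tests: the specimen's own FE rigidity under a chosen
  "true" material model defines the slope of a linear torque–angle record
  extending past 12 N·m; multiplicative Gaussian noise with a chosen CV
  perturbs the rigidity as a whole (measurement errors scale with specimen
  stiffness). Physical rigidity GJ is then re-extracted by least-squares
  regression of the 6–10 N·m loading window times gauge length, exactly as
  for real records, closing the loop: with zero noise the recovered GJ
  equals the FE rigidity to round-off.

Default phantom dimensions (24 mm segment, 3.5 mm outer radius, 1 mm
voxels, ~1 000 elements) are deliberately desk-scale: they preserve every
structural feature the method depends on (cortical annulus, gap, graded
bridging callus) while keeping a full optimization sweep to a few hundred
cached FE solves. Because rigidity scales with radius⁴, absolute VTR/GJ
values are of order 10⁻³–10⁻² N·m²/° rather than the ~1 N·m²/° of an adult
ovine tibia; all validation statistics are scale-free or compared within
the synthetic cohort. What the phantoms do not emulate: scanner physics
(beam hardening, partial volume), plates and screws, irregular anatomical
cross-sections, and biological covariance between geometry and density —
so passing tests demonstrate correctness and recoverability of the method,
not clinical performance.

## Optimization

* Split: the operated cohort is divided into Training/Testing groups,
  stratified by dataset label (per-label counts differ by ≤ 1; which group
  receives the odd specimen alternates across labels, so a (7, 18, 8)
  cohort splits 17/16). Deterministic per seed; resampling the seed is the
  cross-validation mechanism.
* Coarse sweep: rho_cut from 0 to 1500 mgHA/cm³ in 100 mgHA/cm³ steps
  (16 levels) at each candidate E_sc; the objective is the RMSE between
  VTR and measured GJ over the Training group. FE failures at grid points
  are recorded on the surface, never silently dropped.
* Refinement: around each E_sc's coarse minimum, every cutoff at 5 mgHA/cm³
  pitch across the full bracket between the two coarse neighbours (interior
  side only at a grid boundary) is evaluated; the bracket-wide sweep
  guarantees the bracketed minimum is found at a bounded cost (≤ 41 points).
  RMSE ties break toward the lower cutoff, i.e. toward the validated
  single-zone limit.
* Caching: solves are memoized per (specimen, E_sc, soft-element set). For
  a fixed specimen the soft set is determined by how many sorted element
  densities fall below the cutoff, so refinement points that move no
  element across the threshold are free. E_sc is optimized only over the
  discrete candidate set; the bone-law coefficients are never refit.
* Evaluation: each optimum is applied to the Testing group and reported
  with RMSE, Pearson r/R²/p (strong: r ≥ 0.8; moderate: r ≥ 0.6), and the
  absolute-agreement verdict RMSE < SD(measured), using the strict
  inequality and the sample (n−1) SD.

A structural guarantee underlies the sweep: replacing an element's modulus
by a smaller one can never increase rigidity (Loewner ordering of stiffness
matrices), so whenever E_sc is at or below the bone-law modulus of every
reassignable element — true for any segmented phantom whose threshold
density maps above E_sc — VTR is non-increasing in rho_cut, and the sweep
crosses the measured rigidity from over- to under-prediction.

## Statistics

RMSE, Pearson correlation (two-sided p from the t distribution),
strong/moderate/weak classification, mean ± sample SD descriptives, and
one-way repeated-measures ANOVA (SS decomposition into conditions,
subjects, error; F = MS_cond/MS_err) with Bonferroni-multiplied paired-t
post-hocs capped at 1. No sphericity correction is applied. Significance
limit p = 0.05. For two conditions, F equals the squared paired-t statistic
(asserted in tests).

## Numerical choices and degenerate inputs

* Segmentation threshold above the maximum density raises rather than
  returning an empty mask; disconnected masks are rejected at meshing
  (the torsion problem would be singular).
* Zero-noise generators are exactly deterministic; density noise is
  truncated at 0 to keep the power law defined.
* The GJ regression requires ≥ 3 samples inside the 6–10 N·m window and a
  strictly increasing angle record.
* `refine_minimum` treats equal-RMSE plateaus (cutoffs that move no element
  across the threshold) by returning the lowest cutoff in the plateau.

## Known limitations

Isotropic linear elasticity only — no anisotropy, viscoelasticity,
poroelasticity, contact, or strength prediction. Hexahedral voxel meshes
only in the solver (tetrahedral files are rejected by the reader with an
explicit error). The phantom geometry is idealized and axisymmetric before
noise. The RM-ANOVA omits sphericity corrections. Scanner artifacts are not
modelled. Screw holes are omitted from the phantoms.
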