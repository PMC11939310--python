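# Methods note

`lumbomech` is a desk-scale, muscle-driven hybrid finite-element /
multibody (FE–MB) simulator of the lumbosacral spine on fully synthetic,
parametric anatomy.  This note records the model structure, the main
assumptions, the parameter choices with units and rationale, the numerical
methods, and the known limitations.  Nothing in the package depends on
patient imaging or external data; every quantity reported by the examples
and the acceptance script is computed at runtime from the generated
anatomy.

## 1. Model structure

**Rigid bodies.** Sacrum and pelvis are static; L1–L5 and a lumped
thoracic segment ("thorax") are dynamic rigid bodies with 6 degrees of
freedom each.  Masses: 2.2 kg per vertebra, 28 kg for the thorax (head,
arms, trunk above T12), with the thoracic centre of mass placed 40 mm
anterior and 150 mm cranial of the T12/L1 junction so that upright gravity
produces a physiological flexion moment.

**FE discs.** Each intervertebral disc (T12/L1 … L5/S1) is a small FE
mesh: a wedge-element nucleus core surrounded by a hexahedral annulus
ring.  Disc nodes are bound to the two adjacent vertebrae by linear-blend
weights varying with height, so the disc follows the relative vertebral
motion affinely and its elastic energy generates the intervertebral
forces.  Materials are Saint Venant–Kirchhoff: nucleus E = 1 MPa,
ν = 0.49 (nearly incompressible fluid-like core); annulus E = 20 MPa,
ν = 0.45.  The annulus modulus is an effective, fibre-smeared value
chosen together with the ligament and facet stiffnesses so that the
passive column supports the upright reference without excessive lordosis
creep; it is stiffer than isolated ground-substance measurements because
it absorbs the fibre contribution.

**Ligaments.** Anterior and posterior longitudinal, interspinous and
intertransverse ligaments are tension-only point-to-point springs with a
C¹-smoothed slack transition (0.5 mm quadratic zone).  Stiffnesses
(N/mm): ALL 90, PLL 15, ISL 10, ITL 8, each bilateral.

**Facet joints.** Compression-only point pairs at the articular landmark
positions, stiffness 700 N/mm, with the same C¹ smoothing.  They resist
extension and shear; they carry no tension.

**Muscles.** Five bilateral groups of straight via-point fascicles:
erector spinae (2 per side, F_max 800 N), multifidus (5 × 150 N), psoas
major (3 × 250 N), quadratus lumborum (2 × 180 N), abdominals (3 ×
420 N).  Tension = e·F_max·a(L) + passive exponential stretch term, with
e ∈ [0, 1] the excitation.  The active factor a(L) = clip(1 + 15·(L/L_ref
− 1), 0.1, 4) is 1 at the reference length and adds short-range stiffness
around it.  Without this gain the activated column has almost no
stiffness about the upright pose: the passive lumbar spine buckles far
below trunk weight, and a constant-force actuator cannot stabilise it.
The slope 15 is a mechanical surrogate for the combined force–length and
reflex stiffness of muscle; it is deliberately stronger than the isolated
force–length curve.

## 2. Synthetic anatomy generator

The generator draws a parametric sagittal spline of vertebral body
frames.  Key parameters (defaults, units):

| parameter | default | why |
|---|---|---|
| L1–S1 lordosis (COBB) | 52° | reference lordosis of the model family |
| disc heights | 17.5 mm (T12/L1: 10 mm, L4/5: 12.15 mm) | lumbar discs; L4/5 is drawn flatter with a 0.10 lordosis share (mild degeneration) so that the 15 mm expandable cage creates a ~1 mm press fit |
| per-level lordosis shares | L1/2 0.13, L2/3 0.18, L3/4 0.24, L4/5 0.10, L5/S1 0.35 | caudally increasing share, degenerate L4/5 |
| vertebral body size | 45 × 35 × 28 mm | desk-scale lumbar body |
| seed / jitter | 0 / 0 | deterministic by default; jitter perturbs landmarks reproducibly |

All left-side structures are generated by mirroring the right side, so
the anatomy is exactly bilaterally symmetric (verified to ~1e-14 mm).
Landmarks for pedicle entry points, screw heads, facets and spinous
processes are placed at fixed offsets in each vertebral frame.  A
tetrahedral FE vertebral body (soft cancellous core to stiff cortical
shell, E spanning 100–12000 MPa, ν = 0.3) can be generated for
stress-probe use; vertebrae are rigid in the assembled model.

**Realism limits.** The anatomy is a geometric caricature: elliptical
body cross-sections, straight muscle paths without wrapping, no
curvature in the coronal plane, lumped thorax, and effective (not
tissue-resolved) material constants.  Absolute forces and pressures are
therefore indicative only; the model is built to reproduce *orderings*
and *ratios* between intact and treated states, not clinical magnitudes.

## 3. FE kernel

Elements: 4-node tetrahedra (1-point quadrature), 8-node hexahedra
(2×2×2), 6-node wedges (3×2), 3-node membrane triangles (plane-stress
StVK) with discrete-hinge bending.  Hyperelastic soft tissue uses a
one-term compressible Ogden law

W = (c/m²) Σᵢ (λ̃ᵢᵐ − 1) + (κ/2)(ln J)²,  λ̃ᵢ = J^(−1/3) λᵢ,

with the first Piola stress computed from the eigen-decomposition of
C = FᵀF; the implementation is verified against central finite
differences of W to 1e-6 relative error.  Element tangents are formed by
element-level finite differences of the internal force (the meshes are
small, so exactness of the consistent tangent matters less than
robustness).  Two static solvers are provided: Newton with line search
(`solve_static`) and an L-BFGS energy minimiser (`minimize_static`) with
an element-inversion barrier for large-strain, contact-laden problems.
Inverted trial states return a large finite energy instead of raising, so
the line search backs off automatically.

## 4. Tracking controller and settling

Per-step excitations solve a bounded linear least-squares problem
(the controller QP): minimise the predicted rotation-tracking error of
the target frames plus λ‖e‖² subject to 0 ≤ e ≤ 1.  Holding a posture,
however, cannot be solved by alternating "solve QP, then settle": the
passive column is above its critical load under trunk gravity, so the
intermediate passive settles diverge.  `SpineModel.track` therefore
solves posture and excitations *simultaneously* as one bounded nonlinear
least squares over (masked body DOFs, symmetric excitation pairs), whose
Gauss–Newton subproblem is exactly the controller QP.  Residual rows:
scaled equilibrium residual (weight 50), per-target angle errors
(degrees, weighted by target share), and √λ·e regularisation.  Sagittal
tasks restrict the DOFs to the sagittal subspace and force left/right
excitation symmetry, which is exact for the mirror-symmetric anatomy and
removes the torsion-generating null space of the QP.

Per-level targets distribute the thoracic rotation by fixed shares
(equal to the lordosis shares).  Targets are ramped in 5° increments.
The *settling phase* ramps gravity in two steps with the controller on,
sweeps the thorax 2° into flexion and extension and returns upright; the
resulting equilibrium *defines* the upright reference posture.  Because
the settled spine relaxes slightly (~0.7°) from the drawn geometry, the
reference builder calibrates the drawn lordosis once against the settled
COBB angle so the settled reference meets the specified 52°.

Statics use a Levenberg–Marquardt settle on the generalized residual
with per-DOF scaling and a step cap (1 mm / 0.01 rad units) to stay on
the nearest equilibrium branch of the near-critical column.

## 5. Instrumentation

**Pedicle screws** are rigid offsets from the vertebral frames (bone
anchorage is not a failure mode studied here).  **Rods** are linear FE
beams (hexahedral mesh, square section matched to the circular second
moment of area, Ti-6Al-4V: E = 110 GPa, ν = 0.30), statically condensed
to two 12-DOF clamp frames.  The clamp coordinates are corotational:
they are measured relative to the caudal anchor vertebra's finite
rotation since lock, so a common rigid motion of the whole construct
produces exactly zero rod strain and locking truly means "unloaded in
the lock configuration" even after large posture changes.  Internal
loads are recovered with the same small-displacement operator (the
linear tangent of the cranial half) by a free-body
cut at the mid-rod node plane: FZ is the axial force (negative =
compression), Mb,sag the sagittal bending moment in an implant frame
rotated 15° about the rod axis (negative = flexion).  A vertebrectomy
null test (instrumented section, bridged vertebra removed, no load,
gravity off → exactly zero rod load) guards the sign and frame
bookkeeping.

**Resections** (nucleotomy, discectomy, facetectomy, laminectomy,
corpectomy, vertebrectomy) deactivate the corresponding structures, are
logged, and error on repetition or absent structures.  The intradiscal
pressure probe refuses a nucleotomised disc explicitly.

**Expandable cage.** A rigid banana-shaped footprint scaled to the disc
radius, inserted after nucleotomy + facetectomy at the design height
minus 2 mm, then expanded to the design height in the passive (prone)
state: gravity off, excitations zero, posterior rods unlocked during
expansion.  Contact against the inclined L4 inferior endplate uses a
per-point conforming gap, penalty stiffness 2000 N/mm per point and a
friction cone μ = 0.5 with elastic return mapping.  With the default
geometry the expansion distracts the segment by ≈1 mm (≈6 % of the mean
lumbar disc height), a press fit carried by the remaining annulus.

## 6. Trunk soft tissue and orthosis

The trunk is an embedding hexahedral grid (default 9×9×10) bounded by an
analytic skin surface: an ellipse (a = 150, b = 112 mm) with a posterior
Gaussian groove (depth 28 mm, width 0.55 rad) representing the lumbar
lordosis hollow.  Elements are tagged posterior muscle / abdominal wall /
abdominal cavity; each region carries a one-term Ogden material whose
(c, m) scale with the regional muscle excitation, e.g. posterior muscle
c: 25→100 kPa, m: 19→23 over e = 0…1; cavity fixed at c = 7 kPa, m = 17;
κ = 40 kPa throughout.  A membrane diaphragm dome closes the cavity
cranially.

The orthosis is a two-layer (2 × 4 mm) wedge-element band extruded from
the skin, E = 3 MPa, ν = 0.49, spanning L1 to the sacrum.  Tightening by
a circumference fraction (≤ 0.08) shrinks the band's rest radius and
re-equilibrates with a frictionless radial contact penalty against the
analytic skin.  The skin pressure map shows posterolateral peaks and
exact lift-off over the posterior groove — an extensible band cannot
push into a concavity.  The FE intra-abdominal pressure (FE-IAP) is the
mean hydrostatic stress of the cavity elements nearest the cavity
centroid after applying the band tractions to the grid (load ramp +
L-BFGS + Newton polish), reported in mmHg (0.133322 kPa/mmHg).  In the
muscle-driven model the pressure acts as a cranial diaphragm force
p·A_diaphragm supporting the thorax, which reduces the posture-holding
muscle-force sum at fixed abdominal tone.

## 7. Protocols and measures

Pure moments are ramped wrenches on the cranial body of a passive
section (flexion/extension resolved in the sagittal DOF subspace).  The
optional follower load is a taut cable through per-vertebra offset
points, optimised (Nelder–Mead, ≤40 evaluations) to minimise induced
bending.  Standard magnitudes: 3.75 Nm, 6.6 Nm, 10 Nm + 200 N follower,
250 N compression.  ROM is the total excursion between the +M and −M
equilibria.  IDP is the mean nucleus hydrostatic stress (MPa, compression
positive); lordosis is the COBB angle between the L1 and S1 superior
endplate frames; muscle sums are per-group and total tensions (N).
Scenario protocols run as phases: (i) passive surgery, (ii) settling —
mandatory, (iii) posture targets, (iv) external loads, (v) sweeps, (vi)
measurement.

## 8. Numerical conventions

- Units: mm, N, N/mm, MPa for bone/disc/implant, kPa for trunk soft
  tissue, Nm for moments, kg for masses; angles in degrees at interfaces.
- Flexion-positive sagittal angles; compression-positive IDP;
  flexion-negative rod bending moment; compression-negative rod FZ.
- Gravity 9.81 m/s², rampable; semi-implicit damped time stepper for the
  dynamic tests; quasi-static LM settle for all equilibria.
- Determinism: all randomness flows from the anatomy seed; Monte-Carlo
  embedding volumes use stratified seeded sampling (~0.7 % error).

## 9. Open design decisions

- Effective annulus/ligament/facet stiffnesses are chosen jointly so the
  upright reference is held with sub-degree drift; they are not
  tissue-calibrated individually.
- The excitation length-gain (15) lumps muscle short-range stiffness and
  reflexes; any value that stabilises the column above its critical load
  reproduces the same orderings.
- Rod loads are read at the mid-rod node plane; off-centre cuts change FZ
  little but shift the bending lever.
- The cage footprint scales with the generated disc, so press-fit
  magnitudes track the anatomy parameters rather than a fixed implant
  catalogue.

## 10. Limitations

- No coronal/axial posture tasks; the controller and masks target
  sagittal, mirror-symmetric tasks.
- No bone–screw compliance, no implant failure criteria.
- Soft-tissue contact between band and skin is frictionless and radial;
  shear transfer through the skin is ignored.
- The trunk grid is coarse (desk scale); FE-IAP magnitudes depend on the
  cavity bulk modulus and grid resolution and should be read as
  relative measures across tightening levels.
- Dynamic stepping is used only for verification tests; all reported
  states are static equilibria.
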