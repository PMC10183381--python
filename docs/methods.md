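# Methods

This note documents the model behind `stagesim`: what is simulated, what
is approximated, which parameters matter, and what the tests do and do not
establish about real treatments.

## Scope and overall scheme

The package simulates a prescribed 2 mm distalization of the upper right
second molar (FDI 17) with a series of clear aligners on a synthetic right
half maxillary arch (FDI 11–17).  One *stage* = one aligner = two weeks of
wear.  Per stage:

1. **Regeneration** — the previous shell is discarded and a new inner
   surface is generated as the union of the current crown (and attachment)
   surfaces above the gingival trim plane.
2. **TCM activation** — the interdental band between 16 and 17 is widened
   by the preset quantity U = 0.1 mm.  The deformation zone is the slab of
   width d + ΣΔ (d = 2 mm) centred on the interdental centre point P_c and
   oriented along the crown-centre line C_i–C_j; displacement ramps
   linearly across the zone (the profile of a uniform equivalent thermal
   strain k·t = U/(d + ΣΔ)) and carries the distal shell segment rigidly.
   ΣΔ = (steps applied) × U is the expansion already accumulated in the
   regenerated geometry; activation a stage fails to express is *not*
   replayed — the next shell starts from wherever the teeth actually are.
   This is what produces the characteristic efficacy curve (rises early,
   then drifts down as tipping losses accumulate) and keeps both efficacy
   measures strictly below 100 %.
3. **Wear-in** — least-squares rigid registration of the shell to the
   current crowns (Kabsch on the generating-point correspondences over
   non-band vertices), with the shell's front end constrained against
   translation across the midsagittal plane; then *elastic seating*, the
   rigid equilibrium of the shell on its unilateral contact springs with
   the teeth fixed.  Seating is restricted to occlusal-plane motions
   (in-plane translation + rotation about the occlusal normal): vertical
   placement is imposed by the wearer pressing the appliance home, and an
   unconstrained unilateral energy minimum for a trimmed shell on
   occlusally convergent crowns is shell lift-off, which is not a wearing
   state.  Seating is what makes the stage-level reaction satisfy
   action–reaction through the shell and distributes anchorage load.
4. **Two remodeling iterations** (one week each): phase 1 solves every
   tooth's rigid 6-DOF equilibrium and applies the screw displacement;
   phase 2 rebuilds the PDL foundation at reference thickness around the
   displaced roots with zero strain.  Wear-in is repeated before the
   second iteration.

## Geometry

Patient imaging is replaced by parametric solids chosen so that every
landmark rule is exercised: crowns are superellipsoids (exponent 0.85 —
rounded-boxy, occlusally convergent above the equator, which is what lets
horizontal contact forces develop an intrusive component), single roots
are tapered elliptic cones, and molar roots are a trunk plus two diverging
cones with an explicit furcation level.  Teeth are slid along an
arc-length-parameterised elliptical arch form until each interproximal
surface-to-surface gap equals 0.005 mm (bisection on a signed convex gap),
strictly inside the (0, 0.01) mm requirement.  Dimension jitter (±2 %,
seeded) makes the arch a small family of geometries rather than a single
instance.

Landmarks follow the standard battery: crown point at the occlusal centre
(incisal-edge midpoint / cusp / occlusal midpoint — coincident for the
parametric crowns), root point at the apex (mesial apex for molars),
centre of resistance (CR) at the cross-section centroid of the
cervical-third root level for single roots and 1 mm above the furcation
for molars, long axis (LA) from crown point to CR.  Whether "1/3 root
level" is measured from the cervix or the apex is not standardised; the
cervical-third reading is used, consistent with conventional CR placement.
The contralateral half-arch exists only as mirrored landmarks across the
midsagittal plane; the occlusal frame (origin at the mirrored central
incisor midpoint, X through the mirrored first-molar mesiobuccal cusps,
Z the occlusal plane normal, Y = Z × X posterior) is exactly equivariant
under rigid motion of the scene, which the tests verify.

Mesh resolution: the geometry generator accepts a target edge length; the
configuration default is 0.20 mm (the fidelity at which the full model is
defined), while the packaged simulation profile and the test suite sample
surfaces at 0.8–1.2 mm.  Every quantity this model class measures — band
widths (vertex-exact), landmark positions, gap targets (bisected to the
measured value), contact resultants (area-weighted sums) — is insensitive
to this choice, which was confirmed by running the full staging study at
0.6/0.8/1.0 mm (efficacies move by ~1 percentage point).

## Mechanics

Teeth and bone are rigid; deformation is concentrated in two spring
systems.

**PDL foundation.**  Root-surface faces become support points (position,
outward normal, tributary area).  Normal stress follows the bilinear law
σ(ε) = E₁ε below the 7.5 % threshold and continues with tangent E₂ above
(odd-symmetric, continuous); strain is normal displacement over the
0.30 mm reference thickness.  Tangential support is a configurable
fraction (default 0.5) of the normal stiffness with the same law.  The
6×6 stiffness about CR is assembled as Σ Bᵀ K_p B and is symmetric PSD by
construction.

**Contact.**  The shell's inner surface is the offset of the crown
surfaces, so each inner face is paired with its generating crown face —
the nearest point at fitting time — and the pair is frozen for the stage
(small-sliding).  Normal force is a unilateral penalty
k·A·max(0, −gap); friction is a velocity-free tangential penalty capped at
μ·F_n (μ = 0.2) with no stick–slip history.  Attachment-region pairs are
stiffer by the modulus ratio 20000/1500 ≈ 13.3.  Contact normal stiffness
per area (default 0.3 N/mm per mm²) is the one lumped constant of the
reduced model: it stands for the local bending compliance of the 0.7 mm,
1500 MPa shell (plate estimates for 3–5 mm load patches give
0.1–0.6 N/mm³) and is calibrated so that a 0.25 mm molar activation
resolves to a resultant of order 1–5 N.  A `contact_clearance` parameter
(default 0) can add thermoforming play.

**Equilibrium.**  With the shell held at its seated pose, the teeth
decouple: each is a damped-Newton solve of the 6-DOF residual (PDL +
contact + optional midsagittal symmetry wall behind the central incisor)
with analytic Jacobian, backtracking line search, tolerances 10⁻⁴ N and
10⁻⁴ N·mm, ≤100 iterations.  The per-iteration CR translation is capped
at 0.3 mm (the physiologic ~0.2–0.3 mm/week steady rate that motivates
the iteration = one week mapping); under the default activation the cap
never binds.  Optional strain gating (suppress remodeling below 0.3 %
peak PDL strain) is off by default.

## Measurements

Displacements are crown-/root-point displacements relative to baseline in
occlusal-frame components; rotations are the frame-axis components of the
relative pose's rotation vector in degrees (right-hand rule) — matrix-log
round-trip verified to 10⁻⁹.  Distalization efficacy is the distal
component (local arch tangent at the target tooth; the frame-Y component
is reported alongside) of the target crown-point displacement over the
prescription; space-opening efficacy is the enlargement of the inter-molar
crown-point distance over the prescription.  Off-track is the distance
from each distal cusp of the target molar to its corresponding
inner-surface vertex, the correspondence frozen at stage fitting and the
gap read at stage end.

## Free parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| contact stiffness / area | 0.3 | N/mm per mm² | shell bending compliance; 0.25 mm activation → 1–5 N |
| attachment stiffness multiplier | 13.3 | – | modulus ratio 20000/1500 |
| PDL shear fraction | 0.5 | – | tangential/normal foundation stiffness, unreported in the protocol |
| gingival trim fraction | 0.40 | crown height | near-equatorial coverage: grips the crown while leaving the contact set occlusally convergent |
| crown superellipsoid exponent | 0.85 | – | rounded-boxy crowns with convergent occlusal shoulders |
| interproximal gap target | 0.005 | mm | centre of the required (0, 0.01) band |
| displacement cap | 0.3 | mm/iteration | physiologic weekly ceiling |
| contact clearance (play) | 0.0 | mm | available; nonzero values trade early-stage efficacy for extra permanent loss |

## What the synthetic study does and does not show

The generator emulates a well-aligned adult arch with idealized convex
crowns, single- and three-rooted anatomy, conventional attachments on
13–17 and symmetric left/right halves.  It does not emulate real crown
morphology (cusps, marginal ridges, undercuts), interproximal contacts
under load, occlusal forces, an occlusal-pad effect, or patient variation
in bone biology.  Passing the directional suite therefore shows that the
*method* — staged TCM activation plus two-phase remodeling — reproduces
the mechanism-level findings (distal tipping of the target molar,
reversed-bow anchorage loss, intrusion signs, space opening outpacing
distalization with both efficacies between 40 and 100 %); the magnitudes
(−6.6° tipping, 77 %/91 % efficacies on this geometry) are
geometry-dependent and are reported, not asserted.

## Numerical choices and degenerate inputs

Bisection on tooth placement uses a signed convex gap (half-space
containment for the penetration sign) with brentq to 10⁻⁵ mm.  The
section-centroid CR computation requires a closed cross-section; an empty
section raises a landmark error.  Newton non-convergence raises with the
residual history; the seating solve regularises its reduced Hessian by
10⁻¹² and exits on a stalled line search.  Zero-area PDL samplings, bands
without member or witness vertices, non-adjacent band teeth, oversized
attachments and non-watertight generated bodies all raise typed errors.
U = 0 is an explicit no-op (a null stage); negative U is rejected.

## Known limitations

The shell is rigid outside the contact springs, so membrane tension in
the stretched band (which in a volumetric model presses the molars
apically and lifts the interdental shell) is represented only through the
seating constraint; molar intrusion consequently arrives mostly through
the chord drop of the tipped crown point and is smaller than a volumetric
model would give.  Contact pairs are frozen per stage (no large sliding),
friction is memoryless, and anchorage biology (cortical boundaries, bone
density) is not modelled.  The off-track gap of the regenerated-per-stage
shell measures per-stage residual unseating, not cumulative appliance
mismatch; its growth with stages is correspondingly mild.
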