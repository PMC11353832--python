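# Methods

This note records the geometric model behind `handlink`, the parameters
that matter, what the synthetic data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Anatomical frames and the deformity measurement

Each bone is treated as a uniform-density solid bounded by its (watertight)
surface mesh.  Its **Z axis** is the eigenvector of the volume inertia
tensor with the smallest moment — the long axis — computed by
divergence-theorem integrals over the triangles (robust to tessellation
density, unlike vertex PCA).  If the two smallest moments agree within 1%
there is no meaningful long axis and the computation refuses (a sphere-like
fragment).  The sign convention is proximal → distal; the distal end is
identified by the condylar landmarks or joint axis when available,
otherwise by the larger extent along the axis.  Non-watertight meshes fall
back to area-weighted surface moments with a warning.

The **predicted rotation axis** of a joint is built from the proximal
bone's head: two circles are fitted to surface points on the radial and
ulnar condyles, and the line through their centers is the axis.  Real MP
and PIP joints are not perfect hinges — flexion includes a translational
component and the axis itself wanders by roughly 2° — but the fixed
concentric-circle approximation is deliberate: it is accurate enough for
osteotomy planning and keeps the whole simulation rigid.

Circle fitting is total-least-squares in two stages: the plane is the
smallest-singular-vector plane of the centered points; in-plane, a Kasa
algebraic fit initializes a Gauss–Newton refinement of the *geometric*
objective Σ(|p−c|−r)² (≤100 iterations, step tolerance 1e-10).  The
geometric stage matters because condylar arcs cover well under half a
circle, where algebraic fits are biased toward small radii.  The tests pin
the refinement against an independent multi-resolution grid-search
minimizer to 1e-6 mm.

The **Y axis** is the rotation-axis direction orthogonalized against Z;
the discarded out-of-transverse-plane tilt is reported as
`y_obliquity_deg` rather than silently dropped.  **X = Y × Z** completes a
right-handed frame; the transverse/sagittal/coronal planes of the bone are
⟂ Z/Y/X.

The **deformity** is measured by projecting the proximal and distal joint
axes of the malunited bone onto its transverse plane and taking the signed
angle (right-handed about +Z, viewed from distal) that carries the
proximal projection onto the distal one.  Positive therefore means
supination of the distal fragment on a right hand; the clinical literature
reports magnitudes only, so the label is attached per side by
`DeformityMeasurement.direction_label`.

### Condylar point selection

The clinical workflow draws the condylar circles by hand in CAD software.
Reproducibility requires an algorithmic stand-in, and the exact slab
placement is a design choice of this package:

* **manual (landmark) mode** — the caller marks the two condyle centers;
  points are taken in a sagittal slab of half-thickness 0.75 mm about each
  landmark (slab normal = landmark separation), restricted to the distal
  25% of the bone, to within 10 mm of the landmark, and to the articular
  arc distal to the landmark plane.  The distal-arc restriction is what
  keeps shaft cortex out of the fit.
* **automatic mode** — slabs are placed at ±¼ of the head width from the
  head midline along the provisional lateral axis (the intermediate
  principal inertia direction), and the arc is limited to within half the
  slab's dorso-palmar extent of the distal tip (≈ one condyle radius, so
  the filter is self-scaling).

On the synthetic bones both modes recover the construction axis to well
under 1° and the condylar radius to <1%.

## Osteotomy planning and reduction

Pure derotations are cut transversely (⟂ Z) at a configurable fraction of
bone length from the proximal end, default 0.25 — proximal-metaphysis
cuts maximize the union surface.  The derotation axis is the bone's Z
through the cut-face centroid; the pivot choice only affects a sub-voxel
translation, not the corrected orientation.  Angular (coronal/sagittal)
corrections are wedge osteotomies hinged *in* the cut plane: a coronal
(radial/ulnar) correction rotates about the bone's X axis, a sagittal
(flexion/extension) correction about Y — rotation about the condylar axis
Y tilts the long axis within the sagittal plane, which is what
flexion/extension deformity is.  The hinge sits on the cortex entry side
(offset configurable).  Open wedge: one cut, fragment rotated, gap left.
Closed wedge: a second cut inclined by the wedge angle about the same
hinge, the sliver removed, fragments apposed (the inclined face maps
exactly onto the transverse face).  Angular corrections should be cut at
the malunion apex; cutting at a different level corrects the orientation
but leaves a small translational jog in the shaft, visible as ~1° of
inertial-axis deviation per 0.1 of level mismatch in the tests.

The reduction rotates the distal fragment *and every bone distal to it*
(with their joint axes) by one rigid transform.  After any wedge
correction the rotation axis is derived again from the reduced mesh —
an angular reduction changes the predicted axis, so measuring rotation in
the stale frame would be wrong; after a pure derotation Z is unchanged
(it is the rotation axis).  The cut-and-rotate machinery caps each cut
loop by ear clipping in the cut plane, so both fragments stay watertight
and their volumes add to the parent volume exactly (linear interpolation
at the plane); nested cut loops (holes in a cross-section) are not
supported, which cortical bone cross-sections do not produce.

## Linkage simulation

Digits are chains metacarpal → proximal → middle → distal phalanx with
revolute joints MP/PIP/DIP about the fitted axes (default limits 0–110°,
0–100°, −10–80°).  Posing composes proximal to distal; each joint's axis
is first carried along by the more proximal rotations, so posing is
associative over disjoint joint sets and exactly reversible.  Two checks
operationalize the visual verification a surgeon performs:

* **scissoring** — exact triangle-pair intersection between adjacent posed
  digits.  The narrow phase tests each triangle edge against the other
  triangle (Möller–Trumbore, both directions, so the result is symmetric)
  under an AABB + KD-tree broad phase.
* **scaphoid alignment** — the distance from the line of the posed distal
  phalanx's inertial axis to the scaphoid tubercle landmark, with the DIP
  extended.  In a normal hand the flexed fingertips aim at the tubercle;
  the default pass threshold is 5 mm (the clinical check is visual, so the
  number is this package's choice).

## The synthetic hand

Bones are implicit solids — a tapered round-cone shaft, two condylar
spheres offset ±spacing/2 along local Y at the distal end, and a flattened
base ellipsoid — polygonized by marching cubes at 0.4 mm, the slice
thickness of the emulated CT protocol (0.2–1.0 mm accepted; the grid must
resolve the condyles).  Malunions are imposed *in the implicit model*: the
field distal to a transverse cut is rigidly transformed (order: coronal
about X, sagittal about Y, transverse about Z, all about the cut centroid)
and the union re-polygonized, so the result is watertight by construction
and the imposed transform is known exactly.  Default shapes: proximal
phalanx L=40, shaft r=4, condyle r=4.5, spacing 7, base r=5.5 mm;
metacarpal/middle/distal phalanges scaled accordingly; digit scale factors
index 1.0, middle 1.08, ring 1.0, small 0.85.  Standard deformity
magnitudes span 7–25°, the range reported for operated rotational
malunions.

A hand places each digit at its anatomical slot in a fan (bases 20 mm
apart, adjacent rays splayed 5°), so a two-digit hand is geometrically a
subset of the four-digit one.  Two calibrations, performed once on the
deformity-free truth kinematics (analytically, no meshes) and frozen:

* **axial obliquity** — each digit is pronated/supinated about its own ray
  so that its flexion plane passes through the scaphoid tubercle (solved
  in closed form; ±13° for the border digits, ~25° for the small finger).
  This is the anatomical mechanism that makes flexed fingertips converge
  even though every joint is a fixed hinge.  The tubercle itself sits on
  the reference (middle) digit's flexed distal axis at mid-carpal height
  (z = −40 mm, proximal to the metacarpal bases).
* **postures** — the convergence posture is MP ≈ 80° (fine-tuned per digit
  by a bounded 1-D search so the distal axis passes through the tubercle),
  PIP 90°, DIP 0°.  The scissoring screening posture backs flexion off to
  MP −20° from that value, PIP 70°, DIP 20°: there the healthy hand keeps
  >1.5 mm clearance between adjacent digits while every deformity in the
  clinically reported 7–25° range still produces contact.  The deep
  convergence posture is for the fingertip-direction check only — aiming
  all fingertips at one point necessarily brings their soft-tissue-free
  bone surfaces within contact range, so it is not used for collision
  screening.

When a bone carries a malunion, every bone distal to it inherits the
malunion transform, exactly as a patient's distal finger follows the
rotated fragment.  Because the rotation axis nearly coincides with the
digit ray, the extended finger looks almost straight; the deformity
reveals itself in flexion — which is the clinical phenomenon.

What the generator does **not** emulate: real condylar asymmetry and
cartilage, cortical/trabecular interior structure, soft tissue (so
inter-digit clearances are bone-to-bone), joint translation and moving
axes, and population shape variation.  Passing tests therefore demonstrate
that the *pipeline* recovers known geometry at CT-like resolution, not
that segmentation noise or anatomical variation are handled; on real data
the landmark-driven mode and the logged circle-fit residuals and axis
obliquity are the quality controls.

## Numerical choices and limitations

* Exact-coordinate vertex welding on STL load (`weld_tol` available for
  noisy exports); deterministic STL output (fixed header, no timestamps).
* Binary STL is float32: round trips are exact to ~4e-6 mm at finger-bone
  coordinates; ASCII output carries 9 significant digits.
* Ear-clipping cap triangulation is O(n²) on the cut-loop size (hundreds
  of vertices here); loops are capped independently, holes unsupported.
* The welded malunion field is only an approximate distance within one
  grid cell of the cut ring, so a zero-angle malunion reproduces the input
  surface to one cell there and to ~0.02 mm elsewhere.
* Intersection tests treat exact coplanar touching as non-intersecting
  (measure-zero configurations); the scissoring scenarios are verified
  against a voxel-overlap oracle on the implicit models.
* Measured recovery accuracy on the synthetic phalanx at 0.4 mm:
  ≤0.02° over 5–25° imposed rotation; cross-talk from 10° of pure
  coronal/sagittal angulation ≤0.001°; reduction residual ≤1e-5°.  These
  are mesh-resolution-limited and degrade gracefully at coarser grids.
* Problem sizes in the test-suite and acceptance runs: single bones at
  0.4 mm (~12k vertices), 4-digit hands (16 bones, ~190k vertices),
  voxel oracles at 0.2 mm (bones) and 0.4 mm (hand overlap volumes).
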