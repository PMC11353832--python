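# handlink

Quantitative measurement and virtual correction of **rotational malunion**
in phalangeal and metacarpal fractures, by rigid **linkage simulation** of
finger flexion.

Malunited finger fractures usually combine deformities in the coronal,
sagittal and transverse planes.  The transverse-plane (rotational)
component is the most troublesome — it causes the fingers to *scissor*
(cross over each other) in flexion — and it is also the hardest to measure:
it is nearly invisible on radiographs and on a single CT of the extended
hand.  `handlink` implements a desk-side version of the surgical-planning
workflow used for corrective osteotomy of such malunions: given per-bone
surface meshes (STL, mm) segmented from CT, it

1. assigns each bone an anatomical frame — **Z** is the long inertial axis
   of the solid bone, **Y** the *predicted rotation axis* of its joint
   (the line through the centers of two circles fitted to the radial and
   ulnar condyles of the bone head), **X = Y × Z**;
2. measures the deformity as the signed angle between the proximal and
   distal joint axes after projecting both onto the bone's transverse
   plane (the plane ⟂ Z);
3. plans a transverse derotation osteotomy (and, when needed, open/closed
   wedge corrections in the coronal or sagittal plane, after which the
   rotation axis is derived again);
4. simulates the reduction by rigidly rotating the distal fragment and all
   bones distal to it;
5. verifies the result with a linkage simulation: every joint is a fixed
   revolute axis, the fingers are flexed, and the software checks that no
   adjacent digits intersect (scissoring) and that each flexed fingertip's
   distal-phalanx axis passes near the scaphoid tubercle.

Clinical CT data cannot ship with the package, so a first-class synthetic
generator (`handlink.synthetic`) builds finger/metacarpal bones as implicit
solids polygonized at the CT slice thickness (0.4 mm), whole multi-digit
hands, and malunions with exactly known imposed rotations — the ground
truth every test is checked against.

## Worked example

Generate a two-digit hand whose index proximal phalanx carries a 12°
rotational malunion, fit the joint axes, and measure the deformity:

```sh
handlink generate --preset hand2 --deformity "index_pp:rot=12" --out demo/
handlink axes --mesh demo/index_mc.stl --landmarks demo/index_mc_landmarks.json \
              --out demo/index_mc_frame.json
handlink axes --mesh demo/index_pp.stl --landmarks demo/index_pp_landmarks.json \
              --out demo/index_pp_frame.json
handlink measure --frame demo/index_pp_frame.json \
                 --proximal demo/index_mc_frame.json --out demo/measurement.json
```

which prints

```
index_mc: joint axis fitted (circle radii 5.48/5.48 mm, obliquity 0.00 deg)
index_pp: joint axis fitted (circle radii 4.48/4.48 mm, obliquity 0.00 deg)
transverse rotation +11.99 deg (supination)
```

The circle radii are the fitted condylar circles (the generator's condyle
radii are 5.5 and 4.5 mm; the fits sit half a voxel inside, as they
should).  The measured +11.99° recovers the imposed 12° malunion; the sign
follows the right-hand rule about the bone's distal-pointing long axis, so
a positive angle on a right hand is supination of the distal fragment.
`handlink plan`, `handlink reduce` and `handlink flex` then plan the
proximal-metaphysis derotation, execute it, and re-flex the corrected hand
(`--check scissoring,scaphoid`) to confirm the scissoring disappears and
the fingertip again aims at the scaphoid tubercle.  The same pipeline is
available as a library; see `docs/methods.md` for the model.

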