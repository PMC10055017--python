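# fluoroplan

X-ray-based implant positioning for proximal humeral plating: from **two
angulated C-arm views** of a locking plate carrying a three-hole radiopaque
marker clip, `fluoroplan` recovers the marker (and hence implant) pose in
each image, reconstructs the humeral head as a sphere **in the marker
frame**, checks the angular validity of the image pair, and outputs
per-screw locking-screw lengths truncated to a target tip–joint distance
(TJD), together with the plate-offset metric used to monitor head-fragment
shifts.

It is written for surgical-navigation researchers and engineers who want a
desk-testable implementation of hole-projection tracking and two-view sphere
reconstruction: a synthetic-scene simulator with exact ground truth stands in
for cadaver or clinical imaging, so every stage of the chain is verifiable to
machine precision.

## The method in brief

With screw seats `s_i` and unit directions `d_i` fixed in the plate frame
(known implant geometry), and the rigid clip-to-plate transform known, every
screw trajectory is known in the marker frame. Per image, the marker pose
`(R, t)` is estimated by nonlinear least squares on the reprojection error of
the six hole-opening centers (each cylindrical hole projects as a lens formed
by its two opening ellipses). Each image's head silhouette circle
back-projects to a tangent cone with apex at the X-ray source; the head
sphere `(c, r)` is fitted to the two cones,

```
angle(c − apex_k, axis_k) ≈ 0,   sin(α_k) · ‖c − apex_k‖ ≈ r   (k = 1, 2),
```

followed by a joint two-view refinement of both poses and the sphere over
all pixel observations. A pair is **valid** only if the angle between the
two viewing directions (measured at the head center) strictly exceeds 15°.
Screw planning intersects each trajectory with the sphere; with exit point
`e_i` the continuous length is `ℓ_i = (e_i − s_i)·d_i − TJD_target`
(default target 5 mm), rounded **down** to the catalog so the achieved TJD
always lands in `[target, target + increment)` — never closer to the joint
than planned.

## Worked example

Simulate a 30° image pair with 0.5 px feature noise and plan screw lengths
against the bundled (synthetic, "philos-like") implant definition:

```bash
fluoroplan simulate --seed 7 --noise 0.5 --out demo
fluoroplan plan --features demo/features_0.json demo/features_1.json --format text
```

```
fluoroplan 0.1.0 screw plan
  rounding: down (rounded DOWN to the catalog unless configured otherwise; down is the joint-perforation-safe direction)
  pair: view angle 30.29 deg (valid)
  head: radius 26.2 mm, center [1.7569, -0.9023, 49.6671] mm, fit residual 0.021 mm
  plate offset: D-V -2.2 mm, C-C -0.4 mm

  screw   length [mm]  TJD [mm]  status
  A1               44       5.5  ok
  A2               44       5.5  ok
  ...
  E9               40       5.1  ok
```

The ground truth of this scene is a head of radius 26.16 mm centered at
(2.17, −1.33, 49.97) mm in the marker frame: at 0.5 px feature noise the
reconstruction lands within half a millimetre, and every suggested length is
the largest catalog value whose achieved TJD still meets the 5 mm target
(hence achieved TJDs between 5 and 7 mm at a 2 mm catalog increment). The
`plate offset` line is the head-center displacement from the central (D7)
screw trajectory along the plate's dorsal–ventral and cranial–caudal axes —
comparing it between a pre- and a post-insertion pair flags head-fragment
displacement. A pair whose view angle does not exceed 15° is refused (CLI
exit code 2).

Other subcommands: `fluoroplan extract` (raster image + operator seed points
→ feature JSON), `fluoroplan validate-pair`, `fluoroplan report`. DICOM
exposures are read with their pixel spacing (a missing spacing tag is a hard
error; all planning is metric).

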