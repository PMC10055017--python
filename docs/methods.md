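# Methods

This note documents the models, estimators and numerical choices behind
`fluoroplan`, and what the synthetic test bed does and does not establish
about real intraoperative imaging.

## Scene model and frames

A mobile C-arm is modeled as a point-source projective camera: an X-ray
focal spot and a flat detector plane with an orthonormal in-plane basis and
a uniform pixel spacing (mm/px). Pixels are 0-based, origin top-left,
`x` along columns and `y` along rows, matching DICOM raster order. All
lengths are millimetres; angles are degrees at the API surface.

The C-arm is untracked, so absolute camera poses are unobservable. The
**marker frame is the world frame**: the three-hole radiopaque clip rigidly
attached to the plate (through a drill sleeve seated in the plate's central
hole) is the only reference, and everything — camera poses, head sphere,
screw trajectories, plate offset — is expressed relative to it. This is
what makes the output "head relative to implant" without any external
tracker. The fixed `clip_to_plate` rigid transform and the full screw
catalog live in a versioned JSON definition file; the bundled
`philos_like.json` is a **synthetic** stand-in with plausible scale (nine
proximal screws on levels A–E fanning ~20°, 2 mm catalog increments from 16
to 60 mm, three tracking holes of radius 2.5 mm and depth 4 mm at
(0,0,0)/(25,0,0)/(0,20,0) mm, central screw D7), because vendor drawings of
clinical plates and markers are proprietary. All algorithms are
geometry-file-relative; nothing is tuned to the fixture.

## Marker pose from hole projections

Each cylindrical hole projects as a lens: the overlap of the two projected
opening circles (exact ellipses under central projection). The pose
estimator matches, per opening, two observation channels against the model:

* the projected opening-circle **center point** (exact central projection),
* the **center of the projected conic** of the opening circle, evaluated in
  closed form from the cone–plane intersection
  (`geometry.project_circle_centers`). The conic center differs from the
  projected center point by O(ρ²/z) ≈ 0.01 px at clinical geometry; using
  the exact conic model keeps the zero-noise estimator bias-free, while the
  two channels, being independently measured, average feature noise.

The 12 model points are fitted over axis-angle rotation + translation by
Levenberg–Marquardt with multi-start initialization: depth from perspective
scale (magnification = SDD/depth applied to the pairwise projected
distances), and 8 canonical orientations (marker facing toward/away from
the beam × four in-plane quarter-turns) to bracket the classic two-fold
circle-pose flip ambiguity. The asymmetric hole triangle makes the global
minimum unique; a genuinely distinct basin whose residual ties the winner
within 0.1 px while differing by more than 1° raises `AmbiguousPose` with
both candidates. Tie candidates are first re-polished to full convergence —
a start that merely stalled en route to the winning basin is not a second
solution.

## Head reconstruction

The silhouette of a sphere is the detector trace of the tangent cone from
the source. From a silhouette **circle** (center, radius in px), the cone is
recovered linearly: boundary pixels back-project to unit directions `d_i`,
and solving `d_i · w = 1` in least squares gives the right-circular axis
`w/‖w‖` and half-angle `arccos(1/‖w‖)` — exact when the backprojected cone
is circular, least-squares otherwise. Cones are mapped into the marker
frame through the inverse estimated poses.

The sphere is first fitted to the two cones (initialization: midpoint of
the common perpendicular of the axes; radius from the mean tangency
relation; residuals per cone are the two off-axis components of the center,
in mm at the center distance, plus the tangency defect
`sin(α)·dist − r` — six equations, four unknowns). A **joint two-view
refinement** then re-optimizes both poses and the sphere over *all* pixel
residuals of both exposures, including the predicted-vs-observed silhouette
circle (center and radius). The two-stage chain is statistically
suboptimal — the silhouette observations carry pose information through the
shared 3D sphere — and the joint step measurably closes that gap; with
exact features the two-stage solution is already the zero-residual optimum
and passes through unchanged. (Only the two views of one pair are bundled;
multi-image adjustment is out of scope.)

### Pair validity

A pair can triangulate the head only with sufficient angular spread. The
view angle is measured between the reference→source directions of the two
exposures; its vertex is the **head-center estimate** when one exists and
the marker origin otherwise (the two differ by up to ~1° at clinical
geometry because the sources are not equidistant from both points). A pair
is valid iff the angle **strictly** exceeds the threshold (default 15°);
`select_best_pair` picks the valid pair with the largest angle,
tie-breaking toward lexicographically earlier image ids.

## Screw planning

Per screw: trajectory in the marker frame, line–sphere intersection, exit
point = the far intersection along the screw direction (the articular-side
crossing), continuous length = seat-to-exit distance minus the target TJD
(default 5 mm). The suggested length is the greatest catalog value not
exceeding the continuous length: rounding **down** is the only direction
consistent with joint-perforation safety, and it guarantees achieved TJD ∈
[target, target + increment). A `nearest` mode exists for sensitivity
analysis and is flagged in the report header. Failure modes are statuses,
not exceptions: `out_of_head` (fewer than two intersections — tangency
counts as a miss) and `no_catalog_fit` (continuous length below the
shortest catalog entry).

The plate offset resolves the head-center rejection from the central screw
trajectory along the plate's dorsal–ventral and cranial–caudal axes
(negative = ventral/caudal). Comparing offsets between a pre- and a
post-insertion pair screens for head-fragment displacement.

## Synthetic scenes: what they emulate, and what not

`make_scene` builds the protocol geometry: two cameras symmetric about the
anteroposterior direction with the requested view angle (default 30°)
measured at the sphere center, source–object 600 mm, source–detector
1000 mm, 0.4 mm detector pixels on a 512×512 field (typical mobile C-arm
scale; the real device geometry is not published). The rig is canted 20°
about the marker x-axis — the operating point at which the cylindrical
holes project as clearly lens-shaped; near-axial viewing degenerates the
lenses and is not how hole-projection tracking is used. Head radius is
drawn U(20, 28) mm (adult humeral head); the center sits medial of the
central plate hole with ±3 mm jitter. Both cameras aim exactly at the
sphere center, as an operator centering the anatomy would; this makes the
emitted silhouette circle exact, so the zero-noise pipeline closes to
machine precision and the circle-vs-ellipse model error appears only with
aiming error (not simulated). All randomness flows from explicit integer
seeds via independent `SeedSequence` substreams.

Feature noise is i.i.d. Gaussian (σ in px) added to every emitted
coordinate, semi-axis and radius at the *feature* level. Real extraction
noise is neither independent across channels nor isotropic, and real images
add intensifier distortion, scatter, bone texture and fracture lines — none
of which are modeled. Passing the synthetic precision studies therefore
bounds the *algorithmic* error chain under the stated noise model; it does
not validate performance on clinical images. The raster path
(`render_image` → `features`) renders anti-aliased feature regions only
(dark head disk, dark opening-ellipse unions with darker lens overlap), not
radiographic physics.

At the stated operating point (100 pairs, 30°, σ = 0.5 px) the measured
precision is ~0.27° SD for marker rotation and ~1.3 mm SD for pooled
continuous screw lengths; a numerical Cramér–Rao evaluation of the full
observation model puts the attainable floor at ~1.28–1.31 mm, i.e. the
pipeline operates at the information limit of these conditions, and the
length spread is dominated by the head-center depth component (lateral pose
error amplified by 1/(2·sin(view/2)) and by the marker-to-head lever arm).

## Raster feature extraction (optional path)

Semi-automatic means seed-point-driven: the operator supplies one tap per
hole and one inside the head; tests supply ground truth ± jitter. Hole
detection flattens the local background with a grayscale closing (removing
hole-sized dark structure), scans Otsu and multi-level-Otsu thresholds of
the attenuation ratio for a hole-sized component near the hint, splits the
subpixel iso-contour at its two turning-angle cusps, fits the constrained
lens model — two *congruent* ellipses (the openings are identical circles
at nearly the same depth), shared shape, two centers — and finally polishes
photometrically against the raw pixels with a soft-edged two-ellipse
attenuation template (free attenuation factor). Head segmentation is a
seeded RANSAC over gradient-magnitude edge points (90th-percentile
threshold inside a 4·r_max window after σ=1.5 Gaussian smoothing; 3-point
minimal sets, ±2 px inlier band, 500 iterations), non-maximum suppression
(5 px center / 5 px radius), and the same style of subpixel photometric
polish per surviving candidate; candidates are returned score-descending
for operator (or headless rank-1) selection. Entry/exit side assignment
from a single raster is ambiguous at sub-pixel magnification differences;
the extractor orders the two centers deterministically and the CLI labels
them by convention.

## Numerical choices

* Algebraic identities (orthonormality, pose round trips): 1e−9;
  projections: 1e−6 px; line–sphere tangency window: discriminant 1e−9.
* LM solves use tight tolerances (1e−12…1e−15) where zero-noise exactness
  is asserted; multi-start phases use library defaults with iteration caps.
* Degenerate inputs: parallel cone axes (<1°) refuse to triangulate;
  tangent line–sphere contact returns a single point but plans as
  `out_of_head`; a source on the detector plane, a zero-radius silhouette,
  or collinear marker holes are construction-time errors.
* Implant-definition loading separates schema errors (missing/extra
  fields) from geometry errors (named invariant violations); rotations are
  re-orthonormalized only when off by more than 1e−12, so load → serialize
  → load is bit-identical.

## Known limitations

No image-intensifier distortion model (flat-panel geometry assumed); no
fracture-fragment motion beyond rigid sphere displacement between renders;
single-pair reconstruction only; the bundled implant geometry is synthetic;
the clinical six-case series bundled in `fluoroplan.clinical` is example
summary data for the offset arithmetic, not raw imaging.
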