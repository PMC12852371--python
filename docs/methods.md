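# Methods

This note records the models, conventions, and numerical choices behind
`atriometry`, in the order the pipeline applies them, together with the
assumptions a user should know before trusting the numbers on real data.

## Coordinate conventions and preprocessing

All geometry is computed in physical patient coordinates (mm), LPS ordering
(+x left, +y posterior, +z superior); grid indices are never used as
distances. NIfTI headers are normalized to this frame by SimpleITK on read.

Masks are resampled to an isotropic grid (default 0.5 mm) with
nearest-neighbor interpolation — labels are categorical, so any averaging
interpolator is wrong by construction. The output grid shares the input
origin and direction and covers the input extent to within one voxel;
resampling an already-conforming grid is an exact identity, which makes the
operation idempotent. Per-structure cleanup keeps the largest 26-connected
component and applies binary closing with a 1-voxel ball; voxels added by
closing never overwrite another structure. The paper-level operations
(component analysis, closing) fix the method; connectivity and radius are
package defaults, chosen as the most permissive component rule (26) and the
smallest closing element.

## Centerlines

A sleeve's centerline is built from geodesic distance rather than
skeletonization: multi-source Dijkstra propagates physical path length from
the LA-adjacent interface voxels through the structure mask
(26-connectivity), voxels are grouped into 1 mm arc-length slabs, and each
slab contributes its medialness-weighted centroid (weight = squared
Euclidean distance to the structure boundary, so thin wall-hugging voxel
layers barely move the vertex). For a tube this puts every vertex on the
cross-section centroid, i.e. the anatomical axis. Thinning-based skeletons
were rejected because they retract from flat end caps by roughly one lumen
radius, which breaks the requirement that the centerline reach the junction.

Two further steps stabilize the proximal end, where the sleeve base meets
the curved chamber wall asymmetrically: the proximal ~7 mm of vertices are
projected onto a total-least-squares line fitted through the first ~10 mm of
slabs, and that line is extended back to the interface centroid's axial
position so the polyline starts at the junction. The ostial region is
thereby modeled as locally straight over ~7 mm — appropriate for PV trunks
and LAA necks, whose curvature radius is much larger than the window, but a
sleeve that genuinely bends sharply within 7 mm of its junction will have
that bend smoothed away. The polyline is moving-average smoothed (window 5)
and resampled at 0.5 mm; the distal anchor is the centroid of the farthest
arc-length slab (the set of geodesically farthest voxels of a capped tube is
the whole end cap, so a single arg-max voxel would sit on the cap rim).

## Ostial planes

The junction point is the centroid of structure voxels 6-adjacent to LA
voxels; if the adjacency splits into several patches the largest is used and
the case is flagged. Candidate planes are centered on centerline points
within ±5 mm of the junction's arc-length projection, stepped at 0.5 mm,
each orthogonal to the local tangent (a centered 2 mm chord).

Each candidate is sampled on an in-plane grid of 0.25 mm pitch within a
30 mm radius, with nearest-neighbor label lookup. The enclosed area is the
8-connected in-plane component of (structure ∪ LA) containing the plane
center (or the nearest labeled sample within 2 mm); this region definition
excludes disconnected cross-cuts of neighboring anatomy. A candidate is
retained only if it intersects voxels of both the structure and the LA;
the check is evaluated on a slab 1.2 voxels thick (plane ± 0.6 h), because
an infinitely thin plane lying exactly on a voxel-face boundary is ambiguous
on a categorical grid.

Among retained candidates the minimal area wins. Sampled areas of a
voxelized lumen oscillate by roughly (perimeter × half-voxel) depending on
where the plane slices the voxel rows, so areas within `√(π·A_min)·h` of the
minimum (h = mean voxel size) are treated as ties and the tie goes to the
smallest |junction offset| — this anchors the plane to the anatomic junction
instead of letting it wander along a uniform vessel, which is the stated
purpose of the narrow search window. The chosen cut is finally shifted half
a voxel proximally, placing it at the proximal face of the winning voxel
layer so that the half-space assignment of voxel centers (boundary voxels
count as distal) is independent of grid obliquity. A topology flag is raised
when the structure's in-plane footprint is not a single 8-connected
component.

The reported ostial size is the equivalent circular diameter `2·√(A/π)`.

## Direction vectors and angles

The flow-oriented direction at an ostium is the direction of the centerline
segment from 5 mm proximal to 5 mm distal of the ostial plane, estimated as
the total-least-squares line through the window's polyline points and
oriented distally. For a straight segment this equals the chord between the
±5 mm points; unlike the two-point chord it is insensitive to voxel-scale
jitter of any single sample, which matters on coarse native grids. When the
centerline starts at the junction the proximal arm clamps there; this is
recorded as a note (expected anatomy), not a QC flag. Inter-ostial angles
are `arccos` of the clamped dot product of the superior and inferior
direction vectors of one side, in [0°, 180°].

## Diameters

AP and ML diameters sweep axial slices, the SI diameter sagittal slices;
each chord is the first-to-last extent of LA samples along a scan line
parallel to the axis (outer-edge/caliper convention: a single voxel has a
one-voxel chord), and the diameter is the maximum across slices. Only the
LA label participates — the ostial exclusion of the sleeves is what keeps a
vein from inflating an ML chord. With mitral-annulus landmarks the frame
changes to: SI = least-squares basal-plane normal oriented toward the LA
centroid, AP = image AP projected into the plane, ML completing the
right-handed frame; the mask is then resampled on a frame-aligned grid at
the voxel pitch before the same sweep. Automatic annulus detection is out of
scope; landmarks are an optional input.

## Volumes

Chamber volume = voxel volume × (LA voxels + sleeve voxels on the proximal
side of their own ostial plane); a sleeve without a plane is excluded
entirely and flagged. LAA volume integrates LAA voxels distal of the LAA
plane. Voxel centers exactly on a plane count as distal. These half-space
rules partition the labeled anatomy exactly: chamber + LAA-distal +
PV-distal equals the total labeled volume identically.

## Agreement statistics

* ICC(A,1): two-way ANOVA mean squares,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, with the
  F-based 95% CI of the absolute-agreement single-measure form. Zero
  between-subject variance raises an error (the coefficient is undefined).
  The implementation is cross-checked against an independent ANOVA oracle
  and against pingouin in the test suite.
* Bland–Altman: differences `a − b`; LOA = bias ± 1.96·SD (sample SD);
  proportional bias from the slope test of differences on pair means.
* Overlap: DSC on voxel counts; surface distances on voxel-center positions
  of the 6-connected boundary layer. Surface-Dice tolerance defaults to
  1.0 mm and must be reported with any SDC value — the metric is
  tolerance-dependent by construction. HD95 is the 95th percentile of the
  pooled symmetric surface distances.
* Paired tests: Shapiro–Wilk at α = 0.05 on the differences selects paired t
  versus Wilcoxon signed-rank (exact where scipy supports it); all-zero
  differences report p = 1 with a flag. Grade tables use chi-square when all
  expected counts are ≥ 5, else Fisher's exact, per grade (grade vs rest),
  plus an overall chi-square.
* Missing pairs are deleted pairwise and counted; nothing is imputed.

## Usability grading

Grades are a pure function of three per-category success booleans filled by
the pipeline: (i) LA volume + diameters, (ii) PV ostial sizes + both
inter-ostial angles, (iii) LAA volume + ostial plane. A = 3 successes,
B = 2, C ≤ 1. These are the pipeline's *self-assessment* (reported as
`auto_grade`); expert usability judgment is a human input the package only
tabulates. A side with one missing vein uses the available vein (flagged)
for the side diameter but fails the angle, hence category (ii).

## The phantom

The generator emulates the anatomy the pipeline assumes: an ellipsoidal LA
(default semi-axes AP/ML/SI = 25/20/30 mm → 62.83 mL, a typical adult LA),
four cylindrical PV sleeves (radius 6 mm, length 30 mm), and a frustum LAA
(8 → 3 mm over 25 mm), voxelized at 0.5 mm isotropic — the resolution the
measurement framework standardizes to — by the voxel-center rule.

Construction details that make the analytic ground truth exact:

* Sleeves start at the plane tangent to the ellipsoid at their attachment
  point and are carved outside the ellipsoid; the LAA label is therefore the
  analytic frustum and the LA the full ellipsoid.
* The thin crescent between the tangent plane and the curved surface under
  a sleeve base is labeled as the vein for PVs (so caliper sweeps on the LA
  label are not widened by collars) and as cavity for the LAA (so the
  frustum-formula ground truth holds for the appendage volume).
* Sleeve axes default to the local surface normal — a tube meets a wall
  perpendicularly — which also makes the attachment tangent plane a
  supporting plane of the convex chamber and anchors the minimal-area search
  at the port. Oblique entry is available explicitly (`axis=`) and is used
  by the waisted-vein and necked-LAA scenarios, whose narrowing sits distal
  of the junction. Ground-truth inter-ostial angles are the exact angles
  between the resolved axes; `angle_pair_directions` solves for attachment
  directions whose normals meet at a requested angle.
* The grid is phase-canonical (voxel centers at half-integer multiples of
  the spacing), so flat caps on integer-mm tangent planes voxelize without a
  ±half-row volume bias.
* Waists/necks have a 0.75 mm flat floor and 3 mm linear ramps, so the
  0.5 mm candidate quantization can actually sample the minimum radius.

`perturb_phantom` emulates the scanner chain on a finished mask: rigid
rotation about the LA centroid and regridding (including anisotropic native
grids such as 0.5 × 0.5 × 0.65 mm) by nearest-neighbor resampling, then
boundary jitter (surface voxels flipped with probability
`0.5·min(1, σ/h̄)`). `generate_phantom` instead applies rotation
analytically — grid positions are rotated into the intrinsic frame before
the solids are evaluated — so rotated phantoms are voxelized exactly.

What the phantom does **not** emulate: real CT intensities, segmentation
errors with anatomical structure (it only jitters boundaries), PV trunks
that branch, appendage lobulation, non-convex atrial remodeling, and motion
artifacts. Passing the phantom suite therefore demonstrates that the
*geometry* is measured correctly on well-formed masks; it does not bound the
error on imperfect segmentations of pathological anatomy.

## Problem sizes and tolerances used in validation

The validation suite runs the full pipeline on ~0.5–1.5 M labeled voxels per
phantom: the six-scenario catalog, a vein-radius sweep (4–10 mm), angle
constructions at 30–120°, a 15° rotated case measured through an annulus
frame, and native-spacing strata {0.4, 0.5, 0.65, 0.8} mm. Observed
recoveries on the default phantom: volumes within ~0.5% of closed form,
diameters exact to the voxel, ostial diameters within ~2%, angles within
~0.4°; rotation changes metrics by ≤1% and strata by ≤1.8%. Statistical
routines are checked against closed forms, exhaustive enumerations (Wilcoxon
sign assignments, hypergeometric tables), and pingouin.

## Known limitations

* The ostial-plane definition assumes the sleeve label reaches the atrium;
  a gap (failed segmentation at the junction) yields an "ostium not found"
  flag rather than a rescue search.
* The locally-straight ostial model (above) biases direction vectors of
  sharply curved necks.
* Chords are extent-based (first-to-last sample); for highly non-convex
  contours a contiguous-run convention would read lower. The extent
  convention matches caliper practice and is the package default.
* The annulus-plane frame depends entirely on user-provided landmarks; with
  none, AP/ML/SI follow the image axes and are not rotation-invariant.
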