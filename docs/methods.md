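# Methods

`skullpatch` designs a patient-specific cranial implant from a CT-like
intensity volume plus three pieces of user input: paired anatomical
landmarks, a selection contour drawn around the defect, and (optionally) a
second contour tracing the defect edge. This note records the model behind
each stage, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Segmentation and surface extraction

Bone is segmented by an intensity window `[lo, hi]` followed by 6-connected
region growing from a seed voxel, which removes disconnected debris. The
0.5-level isosurface of the binary mask is extracted with marching cubes
(the same surface contract as faster extractors such as Flying Edges).
Masks are zero-padded by one voxel first, so foreground touching the grid
boundary still yields a closed surface — every downstream stage requires
closed or single-boundary sheets. Voxel indices are 0-based and the world
position of voxel (i, j, k) is `origin + index * spacing` with no axis
flips.

Marching cubes on a binary field carries a staircase artifact that inflates
surface area by roughly 10% while leaving enclosed volume nearly exact. The
extractor therefore applies 10 iterations of Taubin smoothing
(λ = 0.5, μ = −0.53), which removes the staircase without the shrinkage of
plain Laplacian filtering; `smooth_iterations=0` disables it. Thresholds
and connectivity are configuration, not constants: CT bone windows vary by
scanner and the package makes no Hounsfield assumptions.

## Median plane and mirroring

The mid-sagittal plane is estimated from n ≥ 1 anatomically symmetric
landmark pairs. Its origin is the mean of the pair midpoints; its normal is
the dominant principal direction (largest singular value) of the
*normalized* pair-difference vectors. Normalizing first makes the fit
robust to pairs of very different separations; for a single pair the plane
is the perpendicular bisector. The normal's sign points from the first
pair's first point toward its second — the plane itself is sign-invariant.

The mirror is the Householder reflection

    T p = p − 2 ((p − o) · n) n

for plane origin `o` and unit normal `n`. It is also built as a five-factor
product `A · B · M · B⁻¹ · A⁻¹` where, reading right to left in application
order, `A⁻¹` translates the plane origin to the world origin, `B⁻¹` rotates
the plane normal onto +x (minimal rotation about n × x̂; a fixed 180°
rotation about ŷ when n ≈ −x̂), and `M = diag(−1, 1, 1)` reflects across
x = 0. Note the frame-change factors must *conjugate* the reflection: the
product of the steps written in application order as column-vector matrices
runs right-to-left, so the first step is the rightmost factor. The product
is asserted against the closed form to 1e-9, along with T² = I and
det = −1. A variant that uses a proper 180° rotation about y as the middle
factor is exposed (`rotation_variant=True`) for comparison with
implementations that composed it that way; its composite is a rotation, not
a mirror, and it is never used by the pipeline.

Mirroring a mesh reverses face winding (a reflection is
orientation-reversing), which preserves outward orientation and signed
volume.

## Contour clipping

A closed contour of m ≥ 3 ordered points defines an implicit function. The
prism direction is the normalized mean of the per-node surface normals
(looked up from the mesh being clipped); the contour is projected along
that direction onto the plane through its centroid and must project to a
simple polygon. The implicit value of a query point is the signed 2D
distance from its projection to the polygon boundary: negative strictly
inside, positive outside, zero on the boundary. The zero-level set is thus
the infinite prism through the loop; axial distance is deliberately
ignored, so the loop acts as a selection tool on a curved surface. Signed
*distance* (not just sign) is returned so boundary triangles can be split
exactly by linear interpolation. Non-convex loops are supported through the
even-odd inside test.

`clip_mesh` keeps the sub-mesh with value ≤ tol (default 1e-9), splitting
mixed triangles along the zero level. Vertices closer than 1e-4 mm are
welded afterwards: cut points can land numerically on existing vertices and
would otherwise collapse under float32 STL precision into non-manifold
edges. Because the prism is infinite, clipping a closed skull retains
material on *both* sides; `nearest_only=True` keeps the connected component
furthest along the loop direction (the sheet the loop was drawn on), which
is what the pipeline uses.

## Surface fitting

The clipped patch is a jagged, possibly multi-sheet point set. It is
regularized the way an interactive viewer would: orthographic projection to
integer display cells (`floor(projected mm / pixel_pitch)`), keeping per
cell only the point nearest the viewer. The camera convention is that
`view_direction` points from the surface toward the viewer, so the default
camera for a selection loop (view along the loop direction, up =
`normalize(direction × ẑ)` with x̂ fallback, pitch 1 mm) keeps the outer
sheet and discards the inner sheet and the far side of the skull.

The survivors are Delaunay-triangulated in the projection plane; triangles
whose projected centroid falls outside the projected contour are discarded;
vertices keep their world coordinates, so the fitted sheet interpolates
every retained point. Two topological repairs follow, both removal-only or
vertex-reusing: pinch vertices (two regions meeting at a point) are carved
away and interior holes left by a jagged contour are fan-filled, leaving a
single-boundary disk. Points projecting within 0.5 px of an already-kept
point are dropped before triangulation (`merge_tolerance`) — the same job
as the merge tolerance of interactive Delaunay filters — because cell-based
dedup still admits pairs arbitrarily close across cell borders, whose
sliver triangles destabilize the later offset. Co-circular ties follow the
triangulator's deterministic input-order handling.

The projection fit assumes the patch is a height field over the contour
plane; for strongly non-convex defects this fails by construction, and the
fit emits a coverage warning when retained triangles cover less than 99% of
the contour area rather than silently accepting the result.

## Solidification

The implant is a three-sheet solid: the fitted sheet is the outer surface;
the inner surface is the outer offset inward by the plate thickness along
angle-weighted vertex normals (default 4 mm, a typical cranioplasty plate —
a required clinical parameter, not a derived one); a ruled wall of 2n
triangles closes the rim. Inside the builder the wall connects boundary
vertices index-to-index (the offset preserves connectivity), so the solid
is watertight by construction with no vertex welding; the standalone
`ruled_wall` operation generalizes this to arbitrary loop pairs by
arc-length resampling both loops to equal counts.

Numerical choices in the offset: the normal field is relaxed by 10 rounds
of normalized neighbor averaging before displacing (isosurface-derived
sheets have ill-conditioned raw normals; a smooth field moves sliver
triangles near-rigidly instead of shearing them), and the face-inversion
guard — which rejects thicknesses exceeding the local curvature radius —
ignores faces below 10% of the median face area, since cut-fragment slivers
flip under arbitrarily small perturbations and carry no reliable
orientation. The inner sheet is optionally smoothed (default on) with
boundary-fixed Taubin iterations; the shrink-compensated form is used
rather than plain Laplacian because the plain filter flattens a thin cap's
inner sheet and breaks the thin-shell relation volume ≈ area × thickness.

The final implant re-clips the initial implant's outer sheet with the
defect-edge contour (normals looked up from the skull) and re-solidifies
identically. Re-running with the same contour is a fixed point, and the
final rim is checked to lie within `rim_tolerance` (default 1 mm, mean)
of the edge contour, warning otherwise.

The pipeline additionally applies 5 boundary-fixed Taubin iterations to the
fitted sheet before solidification (`fit_smoothing`); the raw triangulated
sheet is rough, and the smoothed version is what the solid is built from.

## Evaluation

Two agreement measures between implant designs:

* **Overlap rate** — both watertight solids are rasterized on a common
  voxel grid (union bounding box, 2-voxel pad, default 0.5 mm voxels) and
  compared with Dice = 2|A∩B|/(|A|+|B|); Jaccard is available by flag. The
  rasterizer accumulates z-column surface crossings signed by face
  orientation and marks centers with positive winding — exact for
  watertight, consistently wound meshes up to discretization. The grid
  origin is nudged by 2.5e-4 voxel so centers cannot land exactly on mesh
  vertices or edges.
* **Distance field** — for each vertex of one mesh, the exact minimum
  point-to-triangle distance over all triangles of the other (projection
  inside the triangle, else nearest edge), fully vectorized and chunked;
  summarized by mean, max and 95th percentile. Distances are unsigned.

## Synthetic cases

The generator builds a two-layer ellipsoidal shell (default semi-axes
80/100/70 mm, 6 mm wall, 1 mm voxels, intensity 1000 vs 0) on a grid
centered so x = 0 is an exact symmetry plane, with ≥ 4 exactly mirrored
landmark pairs at analytic surface points; a spherical defect (default
25 mm radius) is punched strictly on one side of the midplane. These
defaults were chosen as a realistic adult-cranium scale, clinical CT
resolution, and a large frontoparietal-type defect. The ground truth kept
alongside is the *intact* outer-sheet surface inside the punch sphere
(truth patch) and its ordered boundary (true rim). What the generator does
not emulate: CT noise, beam hardening, sutures, density variation, or real
anatomical asymmetry — a ≤ 1 mm asymmetric surface bump option exercises
the inexact-symmetry path. Passing tests therefore demonstrate geometric
correctness of the pipeline, not robustness to scanner artifacts.

End-to-end on the default case, the final implant is compared with the
thickness-matched solidification of the truth patch; the pipeline achieves
Dice ≈ 0.99 with sub-0.1 mm mean rim error (recomputed, not stored, by
`scripts/acceptance.py` and the test suite).

## Known limitations

* Non-convex defects: the projection-based fit cannot represent overhangs;
  the coverage warning flags it but no geodesic fallback exists.
* The implicit loop is an infinite prism; selection relies on the
  view-dependent component/visibility rules described above.
* Offsetting is vertex-normal based; it reports, but does not repair,
  thickness exceeding the local curvature radius.
* No Boolean fit against the skull, fixation features, or mechanical
  validation — the output is the geometric plate only.
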