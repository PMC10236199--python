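# Methods

This note documents the models, algorithms, defaults and study conditions
behind `morphforge`, and what its tests do and do not demonstrate.

## Problem setting

A baseline finite-element human body model (surfaces + volume mesh with part
IDs and contact pairs) is personalized to a target subject known only
through skin and skeleton surfaces. The deliverable is the same mesh with
moved nodes: connectivity, IDs, parts and contact declarations are
invariants of the whole pipeline, enforced structurally (`FEMesh.with_coords`
is the only mutation path) and asserted in tests.

All coordinates are world millimetres. Images live on axis-aligned grids;
`origin` is the world position of the center of voxel `[0,0,0]` (NIfTI-style
voxel-center convention). Labels are 0 background, 1 flesh, 2 skeleton, with
skeleton overriding flesh where both apply. The "flesh" metric region is
label 1, i.e. the body minus the skeleton.

## Voxelization

Surfaces are rasterized by sampling voxel *centers*: a center is inside if a
+z ray from it crosses the triangulated surface an odd number of times.
Crossings are accumulated per z-column as parity toggles (a crossing at
height z flips every voxel above), giving O(triangles × covered columns)
cost. Ray origins carry a fixed sub-voxel irrational offset
(≈1e-4 voxel) so axis-aligned geometry never produces edge/vertex ties; the
volume bias this introduces is far below the discretization error. There is
no partial-volume weighting — the registration consumes binary labels, so
anti-aliasing would be discarded anyway. Default voxel size is 2 mm for
whole-phantom work (1 mm is appropriate for single components).

The grid covers the union bounding box of all input surfaces plus a padding
margin (default 8–10 mm) with `shape = ceil(extent / voxel)`.

Skin-only registration (to demonstrate why the skeleton matters) is the same
code path with the skeleton masks dropped — a pipeline flag, not a variant
implementation.

## Rigid pre-alignment

`rigid_align` matches foreground centroids (translation mode, the default)
and can additionally align principal second-moment axes ("axes" mode), with
deterministic sign disambiguation (each eigenvector flipped so its
largest-magnitude component is positive, determinant forced to +1; a
principal-axes match is inherently ambiguous up to axis signs). Phantom
ground-truth studies may skip the stage (`rigid_mode="none"`): generated
baseline/subject pairs share one space, and a centroid shift induced by a
one-sided deformation (a belly bulge moves the centroid ~4 mm) would
contaminate the comparison against the closed-form truth.

## Diffeomorphic Demons registration

Fixed image = baseline, moving image = subject; the output field `u` lives
on the fixed grid and maps `x ↦ x + u(x)` into subject space — the single
direction convention used everywhere (morphing uses `u`; image warping for
evaluation uses its numerical inverse).

Per iteration, on each pyramid level (labels cast to float and pre-smoothed
with σ = 0.5 voxel so binary data carries gradients):

1. warp the moving image by the current field (trilinear);
2. classical Demons force with symmetric gradients,
   `δ = −(m∘φ − f) · J / (‖J‖² + (m∘φ − f)²)`, `J = (∇f + ∇(m∘φ))/2`,
   magnitude clamped at 2 voxels;
3. smooth the update with a Gaussian of σ = `smooth_factor` voxels
   (fluid-like regularization; default 2);
4. exponentiate the update by scaling-and-squaring (halve until the max
   step is < 0.5 voxel, then square back) so each step is a
   diffeomorphism, and compose it with the accumulated field;
5. smooth the accumulated field with σ = `field_smooth` voxels
   (diffusion-like; default 1) — this propagates boundary-driven motion
   into object interiors, which matters because label images generate
   forces only at label boundaries.

Convergence: mean step magnitude < 0.01 voxel, or the per-level iteration
cap. Defaults: pyramid shrink {4, 2, 1} with caps {100, 50, 25}. The
per-level warped-foreground DICE is recorded in `field.meta` and is
asserted non-decreasing on phantom runs.

Design choice on regularization placement: applying the σ=2 Gaussian to the
*accumulated field* each iteration instead sets up an equilibrium that caps
local deformation recovery (a 10-voxel belly bulge saturates at ~4.5 voxels
recovered); placing it on the *update* recovers ~7 voxels with equally
smooth, fold-free fields, and a mild fixed field smoothing (σ=1) restores
interior propagation for global motions (translation recovered to 0.1–0.2
voxel, 10 % elongation to ~0.4 voxel). Both smoothing scales are exposed in
`RegistrationConfig`. A `per_label` option registers labels {1, 2} as
separate binary channels with summed forces; the default treats the
composite {0,1,2} image as one intensity channel, which already gives the
skeleton its own matching term at the 1↔2 interface.

Known behaviour, inherited from the heavy smoothing the method deliberately
uses to keep element quality viable: sharp local differences are recovered
only partially (the 20 mm bulge peak converges to ~14 mm), and a
sub-half-voxel boundary offset remains on smooth blobs (warped-sphere DICE
plateaus near 0.98). The accuracy metrics in the acceptance runs include
these effects; they are properties of the regularization trade-off, not of
the iteration budget.

`invert_field` uses the fixed-point iteration `v ← −u(x + v(x))`, reporting
the composition residual `‖u(x+v(x)) + v(x)‖` (mean ~1e-4 voxel on returned
fields; a warning is attached if the requested tolerance is not met — the
field is still returned). Fold-freeness is checked via the determinant of
`∇(x + u)` (central differences), positive at all interior voxels in the
acceptance runs.

## Morphing and pipeline variants

`morph_mesh` applies `x_i = X_i + u(X_i)` with trilinear field sampling.
Nodes outside the grid (fingertip-type overhangs) default to nearest-border
sampling and are counted in `result.meta["outside_nodes"]`, with a warning
above 1 %.

* **Type II** pre-scales the subject image about its foreground centroid
  (nearest-neighbour resampling) before Demons, and composes the *inverse*
  scaling into the final nodal positions:
  `x_i = S⁻¹(X_i + u(X_i))`. The classic use is a 178/160 z-elongation of a
  short subject registered against a tall baseline; the acceptance test
  checks the morphed mesh height lands within one voxel of the subject's
  160 mm.
* **Type III** substitutes the subject's surfaces for named region tags
  with the baseline's (rigidly aligned) surfaces before voxelization.
  Shielded regions then present zero shape difference, so the registration
  leaves them in place (< 0.1 voxel mean head-node displacement on the
  phantom) while unshielded regions follow the subject.

## Evaluation

* `warp_image` is nearest-neighbour only — labels are never blended.
* DICE per label set; both-empty masks raise rather than return 0.
* Hausdorff distances are computed between boundary-voxel center sets
  (mask minus its 6-connected erosion) via exact Euclidean distance
  transforms with world-mm sampling; HD95 is the max of the two directed
  95th percentiles (percentile pooling is a convention choice; it is fixed
  and documented here so reported numbers are reproducible). Verified
  exactly against O(n²) all-pairs computations on small random images.
* `surface_distance_map` gives per-vertex point-to-triangle distances
  (vectorized closest-point-on-triangle classification, KD-tree broad
  phase), not vertex-to-vertex.
* Element quality: hex scaled Jacobian = min over the 8 corners of
  `det(e₁,e₂,e₃)/(‖e₁‖‖e₂‖‖e₃‖)` (1 for a rectangular block, ≤ 0 inverted);
  tets are scored by normalized volume `6√2·V / L_rms³` (1 for the regular
  tet); aspect ratio = longest/shortest edge; minimum edge length feeds the
  explicit-dynamics time-step concern. Elements with a collapsed edge are
  excluded from ratios and reported separately.
* Contact checking: boundary faces of each contact-pair part (faces used by
  exactly one solid, quads triangulated, shells included) are tested
  pairwise for *strict* penetration with a Möller-style interval test after
  a KD-tree broad phase; coplanar or merely touching faces — including the
  stitched flesh/skeleton interface of conformal meshes — do not count.
  The narrow phase is validated against an independent plane-clipping
  oracle and the broad phase against all-pairs enumeration.

## Phantom study conditions

The default phantom is an ellipsoidal body (semi-axes 30 × 25 × 70 mm,
height 140 mm), an ellipsoid skull (11 × 9 × 13 mm, centered at z = 48 mm,
region tag "head") and a spine cylinder (r = 6 mm, half-length 42 mm) — a
desk-scale body analogue whose every closed-form property (volumes, heights,
deformed positions) is available as an oracle. The hex mesh is built from
axis-aligned voxel blocks (default 4 mm) so baseline scaled Jacobian and
aspect ratio are exactly 1.0 and any quality change is attributable to the
morph; flesh is part 1, skeleton part 2, with contact pair (1, 2).
Optional seeded radial skin jitter (default off; 0.5 mm in the acceptance
script) emulates surface-acquisition noise.

Deformations: `uniform_scale`, `axis_scale` (exact inverses),
`belly_bulge` (Gaussian push of amplitude A along a direction, σ = radius/2,
rejected if A ≥ σ√e since it would fold) and `bend` (rotation ramping
linearly over a height band), the latter two inverted by fixed-point
iteration to 1e-9. Each stresses one pipeline variant: axis_scale → Type II,
belly_bulge → high-BMI Type I and Type III shielding.

What the phantoms do *not* emulate: articulated limbs and posture change,
topological skeleton detail (ribs, joints), realistic anthropometric
covariance, open or non-manifold scan surfaces, and production-scale image
sizes (acceptance grids are ~40×45×90 voxels at 2 mm; a whole-body model at
2 mm is ~30× larger). Passing tests therefore demonstrate correctness of
the machinery and realistic behaviour of the registration trade-offs, not
clinical-grade accuracy figures on real body models.

## Numerical choices and degenerate inputs

* Vertex deduplication at 1e-6 mm on STL read; degenerate (repeated-index)
  triangles dropped; winding preserved. Watertightness = every edge borders
  exactly two triangles; failure warns and flags, it does not abort.
* I/O round trips are identities (bit-exact integers, ≤1e-6 relative
  floats); readers never reorder nodes or elements.
* Gaussian filtering uses nearest-edge padding so fields are not damped at
  grid borders; field resampling between pyramid levels is trilinear with
  vector rescaling by the shrink ratio.
* Empty foregrounds, grid mismatches, non-positive scale factors, missing
  shield tags and solver divergence (non-finite field) raise typed errors;
  pipeline stages re-raise with the stage name attached.
* Determinism: phantoms are bit-reproducible per seed; the registration is
  deterministic (no stochastic sampling anywhere).

## Problem sizes in the shipped runs

The test suite and `scripts/acceptance.py` run at 2–2.5 mm voxels on grids
of roughly 40–135 k voxels with ~3.4–35 k-hex meshes; a full acceptance run
takes well under a minute on one CPU. These sizes were chosen as the
smallest at which all phantom deformations are resolved by several voxels;
the algorithms scale to finer grids linearly in voxel count.
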