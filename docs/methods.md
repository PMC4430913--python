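# Methods

This note records the modelling and numerical choices behind `stenoreg`:
what each stage assumes, which knobs matter, what the synthetic phantoms
do and do not emulate, and where the design was genuinely open.

## 2D angiogram chain

**Denoising.** Haar wavelet shrinkage at 3 levels with a hard universal
threshold σ̂·√(2 ln n), σ̂ = MAD/0.6745 of the finest diagonal subband.
The estimator is robust to the vessels themselves (they occupy few
pixels).  On an exactly flat background the MAD is zero and the threshold
degenerates to zero, so nothing is removed; an explicit `threshold`
argument exists for controlled experiments.  Requires both image
dimensions ≥ 8 (three dyadic levels).

**Starlet transform.** The à-trous recursion smooths with a separable
filter whose taps are dilated by 2^(j−1) at level j and defines
w_j = c_{j−1} − c_j, which makes the reconstruction identity
c_0 = c_L + Σ w_j exact to float rounding — this identity is asserted in
the tests and is the transform's main invariant.  The even-length filter
[1,3,3,1]/8 is anchored at offsets {−2,−1,0,+1}; a different anchoring
only shifts the output by at most 2^(L−1) px.  All convolutions use
mirror (symmetric) padding, which avoids edge ramps that mimic vessels.

**Segmentation.** Vessels are dark on bright background, so the image is
inverted before the detail sum over levels {2,3,4,5} (levels {1..5} are
used for sharpening).  The sum is thresholded at k·σ̂ with σ̂ the MAD
scale of the detail sum and k = 2 by default.  Post-processing follows:
components whose thinned skeleton is shorter
than `min_length` (default 30 px; the test phantoms use 15 px at their
smaller image sizes) are dropped and holes are filled.  Raising k never
adds pixels (monotonicity is tested).

**Centrelines and landmarks.** Thinning, then neighbor counts by a 3×3
ones kernel that includes the center (end pixel = 2, branch ≥ 4).  The
raw count also flags pixels *adjacent* to a junction, so a candidate is
kept as a branch point only if its 8-neighborhood ring splits into ≥ 3
arms when the pixel is removed (crossing-number refinement); the hand
oracle for a "+"-cross then gives exactly one branch point.  Detachment
clears skeleton pixels whose distance to a branch point is ≤ their
distance to the background — the tie counts as cleared, otherwise 1-px
skeletons never actually detach on the discrete grid.  Components shorter
than `min_len` (default 10 px; 5 px in the phantom tests) are dropped.

**Artery labeling.** The selected centreline is inflated by r = max
distance-to-background over its pixels and intersected with the
segmentation.  The start/end role of an endpoint is decided by the local
vessel radius: the wider endpoint is the start (ostium side) — real
coronaries taper distally, and the phantom generator reproduces that
taper.  By default every control point lies on the skeleton; for
registration the optional `extend_tips` pushes start/end landmarks along
the local tangent to the mask boundary, because thinning erodes tube tips
by about one radius and biased tip landmarks tilt the affine.

## 3D CTA chain

**HU classification.**  HU = raw·slope + intercept, clipped to
[−1100, +1100].  Region bounds are half-open so they partition:
region 1 HU ≤ −225 (air/lung), region 2 (−225, +30] (soft tissue),
region 3 (+30, +390] (myocardium, uncontrasted arteries), region 4
(+390, +1000] (contrast, aorta, bone).  The lung mask is the complement
of the hole-filled region-1 binary per slice; hole filling absorbs
pulmonary vessels.

**Aorta.**  Region-4 pixels per initial slice, small objects removed, a
Hough circle transform (scikit-image) over the configured radius range;
the best peak above an accumulator threshold (default 0.4) contributes
its disk ∩ filled region-4 to M_Aorta.

**Vesselness.** Hessian entries are Gaussian derivatives scaled by σ²
(γ-normalization), eigenvalues ordered |λ₁| ≤ |λ₂|, score
exp(−R_B²/2φ₁²)·(1 − exp(−s²/2φ₂²)) with R_B = |λ₁|/|λ₂| and
s = √(λ₁²+λ₂²); the map is the maximum over σ ∈ {1,2,3,4}.  Defaults
φ₁ = 0.75, φ₂ = 25.  Two polarity conventions are available: the default
zeroes the score where λ₁ < 0; `bright_vessels` instead zeroes where
λ₂ > 0, the standard convention for bright tubes.  The default condition
suppresses compact bright blobs (both eigenvalues negative), including
artery *cross-sections* in axial slices, so the pipeline tracks on either
the `bright_vessels` vesselness or directly on the region-4 binarization
(`binarize="region4"`, the default for noise-free phantoms, where the
contrast range already isolates the arteries).

**Intersection tracking.** Assumes each artery is a chain of cross-
sections with nonempty overlap between consecutive slices.  From the seed
component the tracker walks top to bottom; when ≥ 2 components of the
next slice overlap the current region, a bifurcation is recorded at the
last united slice and every branch is followed.  The main artery is the
chain that reaches deepest (ties broken by larger cross-section, then
leftmost centroid); terminating branches are discarded unless tracked for
at least `preserve_len` slices (default 15 — the R-PDA/R-PLB rule; their
terminal centroids are added as extra end landmarks).  When no component
overlaps, the region is dilated by `dilate_px` (3) and up to `lookahead`
(3) further slices are searched before declaring the end, which bridges
single-slice dropouts.  A revisited (slice, component) pair raises an
error naming the slice.  LM tracking stops at its first bifurcation; the
two daughter components seed the LAD and LCX (leftmost-in-image = LAD by
default).  In-slice bifurcation detection splits a region by cutting a
disk of the junction's local radius around each skeleton branch point and
reports the non-largest pieces as the distal branches.

## Registration and stenosis transfer

Points act as row vectors, [u v 1]·T.  Rotation is right-handed, applied
x→y→z about the volume centroid; projection is orthographic,
(u,v) = (round(x′), round(y′)), and per-pixel provenance keeps the
viewer-nearest voxel.  Landmark normalization translates the centroid to
the origin and scales the RMS radius to √2; the affine is solved on
normalized pairs (exact inverse at n = 3, least squares above) and
de-normalized as T = N⁻¹·T̃·N′, which makes T map CTA-frame to
angiogram-frame coordinates; warping the angiogram into the CTA frame
therefore samples I_A at [p 1]·T (inverse warping, nearest neighbor), and
marked points travel by T⁻¹.

A transformed stenosis within `tol_px` (2 px) of the CTA artery snaps to
the nearest pixel of the CTA *centreline* — not the mask edge — so the
recovered depth is the lumen's.  Otherwise both channels are thinned, the
two intersection points bracketing the stenosis along the angiogram
centreline are found (geodesic arc length: 1 per axial step, √2 per
diagonal), and the CTA centreline is walked l₁ = l₁′·L/(l₁′+l₂′) from the
first bracket; l₁+l₂ = L holds identically.  Back-projection reads the
provenance map, searching within `snap_radius` (3 px) when the exact
pixel has none.

Correspondence pairing in the phantom pipeline emulates the specialist's
marking: starts pair directly; ends and bifurcations pair within role by
proximity in normalized coordinates.  Explicit index pairs can be
supplied instead.

## The phantom generator

The 2D generator rasterizes tube polylines (a pixel belongs to a tube iff
its center is within the local radius, radii interpolated linearly along
segments) as dark tubes (intensity 60) on a bright background (200), with
optional clipped additive Gaussian noise.  The 3D generator paints a
soft-tissue background, lung ellipsoids (HU −850), a myocardial ellipsoid
(+150), an aortic cylinder (+500) and contrast-filled artery tubes
(+450), encodes HU back to int16 through slope 1 / intercept −1024, and
reports per-label masks, keypoints and the stenosis voxel.  The reference
pipeline geometry is a 128³ volume (spacing 0.75 × 0.5 × 0.5 mm) with a
gently curved main artery ~90 slices long tapering from radius 3.6 to
2.2 voxels, a short diagonal branch, and a focal stenosis at 60% arc
length narrowed to radius 1.2 over ±4 voxels.  The paired angiogram is
the orthographic projection of the tree under an oblique lateral view
(−80°, 10°, 5°) composed with a mild in-plane affine (5° rotation,
scale 1.05, shift (3, −2) px) standing in for the residual mismatch of a
specialist's manual view matching; landmark jitter (Gaussian, px) models
imprecise marking.

What the phantoms deliberately omit: cardiac and respiratory motion,
cone-beam (perspective) projection, beam hardening and scatter, partial
volume effects, neighboring enhancing structures (chambers, veins), and
inter-modality deformation.  Passing phantom tests therefore demonstrates
the correctness of the algorithms under their stated assumptions, not
clinical-grade accuracy.

## Numerical choices and edge cases

- Ambiguous ≥ 3-way splits below the LM raise an error listing the
  candidate regions rather than guessing.
- Empty masks: segmentation of a constant image returns an empty mask
  (not an error); centreline extraction of an empty mask errors.
- Metrics with zero denominators report `None` ("undefined") rather than
  coercing to 0 or 1.
- All randomness flows through seeded `numpy` generators; a fixed seed
  reproduces every output bit for bit.
- Degenerate landmark sets (n < 3, zero spread, collinear sources) raise
  before any solve.

## Known limitations

- Depth recovery relies on the viewer-nearest provenance voxel, so the
  3D error grows as the viewing ray aligns with the artery (the ray's
  chord through the tube scales as 2r/sin θ).  Views should be chosen
  near-perpendicular to the artery of interest, as in clinical practice.
- When the transformed stenosis misses the artery (e.g. under landmark
  jitter at a narrowed segment), the arc-length fallback depends on
  well-placed centreline intersections; with few or one-sided
  intersections its error can reach tens of voxels.  The jittered
  end-to-end experiment therefore reports a median.
- The affine model absorbs view mismatch and scaling but not cardiac
  deformation; a deformable step is out of scope.
- Bifurcation keypoints are recorded where cross-sections separate in
  the slice stack, which trails the anatomical takeoff by a few slices
  for shallow branch angles.
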