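# Methods

This note records how each stage of the pipeline is defined, which knobs
matter, and which behaviours the synthetic test bed does and does not
exercise.  All defaults named here are frozen in code (`PipelineConfig`,
`PhantomParams`, `SnakeParams`, the feature table in
`features.feature_spec()`).

## Coordinate and data conventions

Grids are `(slice, row, col)` with z ascending; spacing is `(z, y, x)` mm.
Bounding boxes are 0-based and half-open, so the box of an inclusive
min/max corner pair adds +1 to the max indices; all crops are plain array
slices and cannot be off by one.  Masks hold strictly {0, 1}; NIfTI is the
canonical container (gzipped, via nibabel), PNG slice stacks are accepted
for fixtures with spacing supplied by the caller (default (1.60, 0.78,
0.78) mm, typical abdominal-CT geometry).

## Registration-based positioning

*Template selection.*  The template is the cohort subject whose liver
convex-hull volume (hull of foreground voxel centres, spacing-scaled;
degenerate clouds are an error) is nearest the cohort mean; ties go to the
lowest subject index.  In single-slice mode the same rule runs on hull
areas.  Hull volume rather than voxel count follows the surface-mesh
formulation of the positioning step; for convex-ish livers the two differ
only by a sub-voxel rind.

*z-correspondence.*  Template and subject slices are matched by
proportional physical z position.  `interpolate_z` resamples a template to
a common slice thickness (default 1.60 mm) with linear intensities and a
0.5-rebinarized label; output slice count is `round(extent/dz)+1`.

*Registration.*  Affine (rotation, anisotropic scale, shear, translation),
parameterized about the image centre, estimated on 2× downsampled,
preprocessed slices.  Coarse stage: FFT cross-correlation for translation,
then a Powell polish of the full parameter vector under a normalized
cross-correlation objective with large direction steps (2 px translation,
5 % scale).  Fine stage: Powell under mean squared difference with steps
divided by 10 and a 4× iteration budget.  The fine stage starts at the
coarse optimum, so its objective can only improve; exhausting the budget
returns the best-so-far transform flagged `converged=False`.  Positioning
runs on window-preprocessed images by default (configurable), and the
pipeline never computes an inverse transform: the template is always the
float image, and its label support is pushed *forward* through `T`.

*Box propagation.*  Transformed label coordinates are boxed with floor/ceil
outward rounding, clipped to the reference frame, then padded by a 5 px
margin (configurable).  Outward rounding means rounding can never clip
liver; the margin absorbs the residual non-affine anatomy difference
between template and subject.

## Preprocessing

Window (default 130–150 gray units, or estimated from a caller-supplied
patch as histogram mode ± half-width-at-half-maximum, floored at 5 units)
→ linear stretch of the surviving band onto [1, out_max=255] (the low edge
maps to 1, not 0, so preserved pixels never collide with the zeroed
background) → 5×5 median with replicated borders.  The patch is an explicit
argument rather than a random crop: randomness in preprocessing would break
run-to-run reproducibility.

## Coarse segmentation

*FCM stage.*  Bezdek alternating updates, c=4, m=2, tolerance 1e-5 on the
largest centre shift, max 300 iterations, centres initialized uniformly in
the data range from a seeded generator; a pixel coinciding with a centre
gets hard membership.  The objective is recorded per iteration and is
non-increasing.  Because the contrast stretch spreads the liver band across
most of [1, 255], the liver routinely occupies several of the four
clusters while the zeroed background forms one genuinely dark cluster; the
candidate tissue is therefore the union of clusters with centre above 40
(preprocessed units), of which the largest 8-connected component is kept,
closed with a radius-3 disk and hole-filled.  Equal-size component ties go
to the lexicographically smallest (row, col) minimum.  This stage is
intentionally permissive: a confounder organ inside the box survives.

*ELM stage.*  126 features per pixel (block table below), z-scored with
training statistics and divided by √d.  That last factor matters: with
uniform [−1, 1] input weights and 126-dimensional z-scored inputs the
projection `w·x` has spread ≈ √(d/3) ≈ 6.5, deep in the sine's aliasing
regime, and training accuracy collapses to ≈ 0.66; with the √d factor the
argument is O(1) and training accuracy is ≈ 0.997.  Hidden width defaults
to 630 sine units; output weights solve `β = H†T` via SVD pseudo-inverse
with relative singular-value cutoff 1e-10 and no ridge term.  Scores are
median-filtered (5×5) and thresholded at 0.5, ties to foreground.
Training pixels are every pixel of every margin-padded true-liver box
(liver = 1, box background = 0), capped at 40 000 rows by a seeded
subsample.

*Fusion.*  Per training slice, stage accuracies `A_F, A_E` (pixel accuracy
inside the training box) give weights `A/(A_F+A_E)`; the final pair
averages the per-slice weights over the top-K slices ranked by
max(A_F, A_E), K = min(100, n).  At inference the *binarized* stage
decisions are fused, median-filtered and thresholded at 0.5: with soft
scores, a pixel rejected by one stage would need the other stage's score to
exceed 1/(2w) ≈ 0.92, which measurably erodes the coarse mask (held-out
Dice 95 vs 99.4 for the binary vote on identical inputs).

## Feature bank (126 dimensions)

gray (1); 1st-order Gaussian derivatives σ∈{1,2,4} × {row,col} (6);
2nd-order ditto (6); local std, windows {3,5,9} (3); bottom-hat, disk radii
{3,5} (2); phase congruency from quadrature Gabor pairs, 4 orientations ×
2 frequencies, DC removed (1); Canny indicator σ=2 (1); Harris response
(1); uniform LBP(8,1) 10-bin histogram over 9×9 (10); Gabor magnitude,
frequencies {0.1,0.2,0.4} c/px × 4 orientations (12); Hessian eigenvalues
σ∈{1,2} (4); window mean+variance {3,5,9} (6); rank entropy, windows {5,9}
(2); co-occurrence contrast/correlation/energy/homogeneity at offsets
{(0,1),(1,0),(1,1),(1,−1)}, 16 levels, 9×9 window (16); Laws 5×5 energies
(25); sum-and-difference statistics, 5 stats × {(0,1),(1,0),(1,1)} ×
offsets {1,2} (30).  The family list is fixed; per-family dimensionality
and scales are this package's convention, fingerprinted so a model refuses
a mismatched bank.  The whole stack is computed on an 8 px edge-replicated
pad and cropped back, keeping library filters free of zero-padding border
artifacts; every block is deterministic and translation-covariant away
from borders (verified to 1 % relative in tests).

## Fine segmentation

Boundary of the coarse mask (largest component, with a warning if there
were several), resampled to 200 points by arc length, evolved under
`E = Σ α|p_{i+1}−p_i|² + β|Δ²p_i|² − w·G(p_i)`, α=0.1, β=0.5, w=1.0,
G = gradient magnitude of the σ=2 smoothed image scaled to [0,1].  The
semi-implicit step `(I + sγK)p⁺ = p + sγw∇G(p)` (γ=0.5) is wrapped in a
backtracking halving of `s` (≤10 tries) so each recorded energy value is
≤ its predecessor; a per-point greedy scheme was rejected because a single
point moving inward on a smooth contour lengthens its chords and the move
is never accepted — the contour cannot contract at all.  Convergence is a
mean drift < 0.1 px accumulated over a 10-iteration window (a slow steady
drift must not read as convergence), or 500 iterations.  Failures
(collapsed contour, empty rasterization) fall back to the coarse mask,
flagged: the snake is an optional refinement and must never lose the
coarse result.  There is no balloon force.

## Tumor stage

Same 126-d bank computed on the *raw* intensity slice (the liver window
zeroes tumor gray values near 112, so windowed features carry no tumor
contrast), restricted to liver-interior pixels; a second ELM (tumor = 1,
other liver = 0, seed offset +1) scores them; 5×5 median; threshold 0.5;
intersection with the liver mask.  Training uses ground-truth livers,
inference the predicted liver — the usual cascade convention.

## Metrics

VOE = 100(1−|A∩B|/|A∪B|); RVD = 100(|B|−|A|)/|A| (signed, asymmetric);
Dice = 200|A∩B|/(|A|+|B|).  Surface voxels are foreground voxels with a
background *face* neighbour (out-of-grid counts as background); distances
are Euclidean between voxel centres with anisotropic spacing applied, and
ASD/RMSD/MSD are the mean / RMS / max over both directed nearest-distance
sets.  All distance values are cross-checked against an O(|S_A||S_B|)
all-pairs oracle in the tests.  Both-empty overlap queries raise rather
than return a sentinel.

## Phantom generator

Emulates exactly the features the pipeline relies on: an elliptic body on
air; a liver as an ellipsoid (semi-axes (62, 90, 72) mm) perturbed by a
smooth random field (10 % of the implicit function, σ≈(4,10,10) voxels)
with N(140, 4) gray values; spherical tumors (radius 14 mm) strictly
inside, N(112, 4); a spleen-like ellipsoid at N(145, 4), inside the liver
window by design; N(0, 2) global noise.  A cohort shares one base anatomy;
each subject applies an in-plane affine (scale ±6 %, rotation ±8°,
translation ±4 mm) drawn from its own child generator, so a zero-range
affine cohort is voxel-identical — this makes the affine the *only*
inter-subject mask variation, which is what the positioning experiment
needs to be interpretable.  Default 3D geometry is 64×128×128 at
(2.5, 1.6, 1.6) mm, sized so a 10-subject cohort averages ≈1700 cm³ of
liver; the fast 2D mode is a single 128×128 slice at 1.6 mm.

What the phantoms do *not* contain: CT physics (beam hardening, partial
volume, HU calibration), respiratory deformation, anatomical organ shapes,
inter-slice pose changes, or texture differences between organs beyond
mean gray level.  Passing the synthetic suite therefore shows the
pipeline's machinery is correct and self-consistent — registration
recovers affine pose, clustering/classification separate the constructed
intensity structure, fusion and refinement behave as designed — not that
clinical-grade accuracy would be reached on patient data, where
boundaries are weaker and texture richer.

## Problem sizes

The test suite and the acceptance script run: metrics oracles on ≤16³
random blob pairs; ELM interpolation at n ≤ 40, L ≤ 80; end-to-end
training on 6 and evaluation on 2 single-slice 128×128 subjects; 3D
positioning on a 6-subject 64×128×128 cohort; cross-validation wiring
3-fold on 6 subjects with a lightened classifier (150 hidden units,
12 000 training pixels).  These sizes keep a full run in a few minutes on
one CPU while still exercising every code path at realistic geometry.

## Known limitations

Slices are processed independently (no 3D regularization across z, matching
the per-slice formulation); the registration model is affine, so strongly
non-affine anatomy is only absorbed by the box margin; FCM sees gray values
only; the fusion weight formula assumes both stages are at least weakly
accurate (a stage with near-zero accuracy still receives positive weight);
and the ELM is unregularized, so feature collinearity is handled solely by
the pseudo-inverse truncation.
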