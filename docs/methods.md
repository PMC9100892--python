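# Methods

## Problem setting and model

A plug seedling's root ball is an approximately cylindrical plug of
substrate whose surface carries part of the root system. The package
measures surface-root phenotypes from four color+depth views taken while
the plant is rotated 90° between shots, and predicts total-root phenotypes
through univariate linear (allometric) models. Quantities and units:

| symbol | meaning                          | unit |
|--------|----------------------------------|------|
| ADTR   | average diameter of total root   | μm   |
| SASR   | surface area of surface root     | cm²  |
| DSR    | encapsulation (root/ball pixels) | %    |
| SATR   | surface area of total root       | cm²  |
| LTR/LTRP | calculated / predicted total-root length | cm |
| VTR    | total-root volume (cylinder model) | cm³ |

All unit conversions live in `rootball.units` (depth mm, areas cm²,
lengths cm, diameters μm).

## Registration

The root ball itself is texture-poor, so registration uses external feature
points: a pseudo-random black/white block pattern behind the plant. Harris
corners are thinned by adaptive non-maximal suppression (suppression radius
= distance to the nearest corner at least 1/0.9 times stronger), described
by bias/gain-normalized 8×8 patches sampled every 5 px from a blurred
neighborhood, matched with a 0.8 ratio test plus symmetric cross-check, and
fed to RANSAC (4-point samples, 2 px reprojection tolerance, 2000
iterations, fixed seed) with a least-squares refit on the inliers.
Consecutive-pair homographies are chained to the reference view. Color is
composited with center-weighted feathering; depth is warped
nearest-neighbor and composited first-valid-wins, because averaging depth
across views would fabricate geometry. The vendor depth-to-color alignment
of a physical sensor is out of scope; `align_depth` is a no-op extension
hook and frames must arrive pre-aligned (the generator guarantees this).

## Preprocessing

Enhancement is `clip(gain·x,0,1)^gamma` per channel (defaults 1.4/0.8).
Background removal consolidates the Sobel edge map: Otsu threshold on the
gradient magnitude (the default; a fixed threshold is configurable), disk
dilation, hole filling, diamond erosion, disk opening, then a
connected-component filter keeping components at least half as large as the
largest one. The alternative reading of the component rule — at least half
the *image* — is available as `component_filter="image-fraction"`, but the
largest-component interpretation is the one that isolates a single
root-ball blob on this kind of image. Structuring-element radii (5/3/3 px)
are specified at 1280 px width and scaled linearly with image width.

Homomorphic filtering works in log space with a periodic (FFT) boundary
model: gain γ_L + (γ_H−γ_L)(1−exp(−D²/2D₀²)) with defaults γ_L=0.5,
γ_H=1.5, D₀=0.05·min(H,W). Periodicity makes the filter commute with
cyclic translation exactly, at the price of wrap-around leakage for
non-periodic illumination fields; on ROI-cropped root-ball images the field
is dominated by low-order components where the attenuation is strongest.

## Vesselness segmentation

Second derivatives are taken from Gaussian-derivative filters multiplied by
σ² (scale-space normalization) so responses are comparable across scales;
kernels are truncated at 6σ because the conventional 4σ cut leaves a ~10⁻³
relative bias in second-derivative responses, which matters once responses
are compared across scales. The 2×2 symmetric eigenproblem is solved in
closed form; eigenvalues are ordered by absolute value. Bright tubes are
assumed (the response is zeroed where λ₂ > 0); a polarity flag inverts the
image for dark roots. R_B is defined as 0 where λ₂ = 0 and the response is
0 there (flat background), avoiding 0/0.

The scale ladder is geometric with 6 scales over σ ∈ [1, 4] px by default.
The upper end matches the half-width of the widest root the pipeline is
expected to meet (~900 μm ≈ 9 px at the working resolution): scales well
beyond the widest tube's half-width cannot win on any real root but do
widen the response halo around thin roots, inflating their apparent area.
β defaults to 0.5. The structureness constant c defaults to "auto" = half
the maximum Frobenius norm per scale (standard practice, adapts to image
contrast); explicit values pass through the config untouched. Binarization
is Otsu on the response restricted to the root-ball mask, followed by
removal of components under 30 px; the mask is always a subset of the
foreground.

## Phenotype measurement

**Calibration.** Depth pixels are back-projected through the pinhole model
(invalid pixels infilled nearest-neighbor first). The per-pixel patch area
is the cross product of the central-difference tangent vectors of the point
grid — the local quadrilateral patch area, exact for planar surfaces. Then
S_pix = S_ROI/ΣPix and L_pix = √S_pix exactly.

**Non-overlapping roots.** `output = mask & ~dilate(median(erode(mask)))`
with equal erosion/dilation disk radii (restoration symmetry) and a 3×3
median. The default radius is 2 px; for a known width range the radius
should be about half the widest expected root plus a margin (5 px for
400–900 μm roots at 0.1 mm/px), so that every single root is destroyed by
the erosion (hence classified non-overlapping) while genuinely overlapping
blobs survive and are excluded.

**Skeleton length and diameter.** Topology-preserving thinning
(`skimage.morphology.skeletonize`), then L = N_skel · 1.2 · L_pix, where the
fixed 1.2 factor averages the unit pixel edge (1) and
diagonal (√2) step lengths. The factor is exact only for an even mix of
step types: a purely axis-aligned run is overestimated by 20% and a purely
diagonal one underestimated by 15%, so the diameter ADTR = SASR_NO/L
carries an orientation-dependent bias of −16.7%…+17.9% in the worst case
and is approximately unbiased for isotropic root orientations (the
length-weighted mean of the per-step correction over uniform orientations
is 1.08·L, a ~+8% length bias). `euclidean_skeleton_length` reports the
chain-length oracle (edge links ×1, diagonal links ×√2) alongside for
comparison.

**Predictions.** LTR = SATR_pred/ADTR deliberately omits the π factor a
cylinder's lateral surface would imply (L = SA/(π·d)): the LTRP model was
fitted against lengths computed in exactly this form, and its slope
(2.9723 ≈ π) absorbs the geometric factor, so "correcting" the formula
would break the fitted model. S_a (the ball's surface soil area)
is taken equal to SSAM, the denominator of the encapsulation ratio.
`fit_model` refits either model by OLS and reports r².

## Synthetic scenes: what they emulate, and what not

The generator draws: a fiducial block pattern (seeded binary cells — corner
density is what matters, no code standard is implemented); a substrate band
with Gaussian texture and bright speckle (perlite-like grains, density
0.02); and n smooth random-walk tubes of per-root constant width with
anti-aliased edges and flat end caps. Flat caps and a per-step turn limit
(max 0.08 rad per 2 px step, minimum bend radius 25 px) keep the drawn area
equal to Σ lᵢwᵢ analytically; candidate roots overlapping existing ones by
more than 2% are redrawn (up to 25 attempts), bounding the union deficit.
Ground truth (total length, projected area, length-weighted mean diameter)
comes from the analytic centerline geometry, never from pixel counts.

Views are horizontal windows of the panorama — rotating a cylinder
translates its unrolled surface — related by stored integer-translation
homographies, with additive Gaussian sensor noise (sd 2 intensity levels)
so RANSAC has something to reject. Depth is the frontal ray/cylinder
intersection (radius 30 mm, camera distance 90 mm, f = 600 px), giving a
0.1 mm pixel pitch at the tangent column; root widths 4–9 px therefore mean
diameters of 400–900 μm, the range relevant for cucurbit rootstock
seedlings about two weeks after emergence. Default panorama 320×832 px,
four views, 25% overlap.

Not emulated: perspective foreshortening within a view (views are crops,
though the estimator handles full projective homographies), shadows and
specular highlights, root color variation, substrate deformation, and the
depth sensor's noise/occlusion artifacts. Passing tests therefore show the
algorithm chain is correct and well-conditioned under controlled
conditions, not that the accuracy figures transfer to a particular camera.

## Study conditions for the recovery experiments

The diameter-recovery experiment uses 20 scenes whose per-scene width
ranges step from (4,5) to (8,9) px — mean diameters ≈ 430–890 μm — with
fixed seeds, the default method parameters, and non-overlap erosion radius
5 px. Observed median |relative ADTR error| is ≈ 11%, dominated by the
skeleton-length factor and the vesselness mask's boundary halo. The
regression-recovery experiment uses n = 200 pairs, noise sd 1, uniform x
over [5, 40]. Scene sizes were chosen so a full pipeline run takes about a
second on one CPU core.

## Numerical choices and degenerate inputs

* Homographies are normalized so H[2,2] = 1; singular or badly scaled
  matrices are rejected.
* Ties in the multi-scale maximum keep the smallest winning scale.
* Otsu on a degenerate (single-valued) response keeps nothing below it;
  an all-zero vesselness map yields an empty mask with a warning.
* Empty masks: skeleton length 0; the diameter is reported as undefined
  (error) rather than 0/0.
* The report re-checks VTR = π(ADTR/2)²·LTRP at 10⁻⁹ relative tolerance on
  assembly and on deserialization-for-validation paths.
* Pixel coordinates are 0-based (row, col); homographies act on
  (x=col, y=row, 1).

## Known limitations

* The fixed skeleton-length factor (1.2) is a compromise; anisotropic
  root orientation biases ADTR by up to ±18%.
* The vesselness halo makes SASR run ~10–25% above the drawn tube area on
  synthetic scenes; DSR inherits this scale.
* Calibration assumes the pinhole model and locally smooth depth; strongly
  slanted or noisy depth inflates S_ROI.
* The allometric coefficients were fitted for pumpkin rootstock plug
  seedlings at one growth stage; other species or stages need refitting
  (`fit_model`).
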