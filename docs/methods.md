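# Methods

## Optical model

The eye is reduced to a single refractive surface with first focal length
`f1` (default 17.0 mm in air; vitreous index 1.336 and axial length
23.87 mm are carried as informational constants). For an emmetropic eye the
retina coincides with the second focal plane, the eye–camera system behaves
like a telescope, and the magnification is `f0 / f1`. Axial ametropia of
`D` diopters displaces the retina by

    Δd = −f1² D / (1 + f1 D)      (f1 in metres inside the product)

so a myopic eye (negative `D`) has `Δd > 0` and magnification
`f0 / (f1 + Δd)`. The relative magnification bias is defined as `Δd / f1`
(1 mm ↔ 5.9% at `f1 = 17 mm`); the alternative `Δd/(f1+Δd)` differs only in
second order but does not reproduce that reference figure, which is why the
first form is used. Treating the retina as a sphere of radius `f1 + Δd`,
a camera of field of view `α` images a retinal arc `L_ROI = α (f1 + Δd)`.
All lengths are millimetres internally; pitches are reported in µm; `α` is
stored in radians.

The units of the diopter product are the one genuinely open convention:
`f1·D` is evaluated with `f1` in metres (diopters are inverse metres), and
the inverse relation `D = −Δd / (f1 (f1 + Δd))` round-trips to 1e-9 over
±10 D, which the test suite asserts.

## ROI detection

1. Threshold the red channel (brightest, most transmissive plane) at one
   third of its mean gray value, computed over the whole frame.
2. Keep the largest 8-connected bright component (area ties broken by the
   smallest top-left bounding-box corner). A circularity guard
   `4πA/P² ≥ 0.3` rejects frames whose brightest blob is not remotely
   disk-like (noise, blank frames); a disk scores ~1 and even a heavily
   cropped disk stays above 0.7.
3. Canny on the binary component (not the raw image, so retinal texture
   contributes no edges), hysteresis thresholds at 0.1/0.3 of the peak edge
   magnitude; edge pixels within 2 px of the frame border are discarded so
   the straight cut lines of a cropped circle cannot vote.
4. Circular Hough transform over radii `[0.25, 0.75]·max(H, W)`. The
   schedule is two-stage — a coarse pass on a 2×-downsampled edge map
   narrows the radius window, then a full-resolution step-1 pass casts the
   definitive vote — followed by an algebraic (Kasa) circle fit to the edge
   pixels within ±2 px of the winning circle, giving sub-pixel diameters.
   Vote ties prefer the larger radius, then the center nearest the frame
   center. Circles below a normalized vote fraction of 0.15 raise
   "ROI not found". Centers are searched in-frame, which suffices for
   macula-centered photographs: arcs surviving a crop still vote for the
   true center and radius.

Coordinates are 0-based `(x, y) = (column, row)` at pixel centers
throughout.

## Disc measurement

The disc diameter is deliberately the **farthest-pair** (circumscribed
circle) diameter of the edge-point set — the maximum pairwise Euclidean
distance, center at that pair's midpoint. This is not the minimum enclosing
circle; it reads the maximum extent of the irregular disc shape, which for
the vertically elongated disc is the vertical diameter, the axis the
anatomical prior describes. The search is exhaustive over all pairs
(restricted to convex-hull vertices beyond 2000 points, which cannot change
the result), with ties broken by the lexicographically smallest index pair.

Locating is a pluggable strategy so an external detector can be substituted;
the default classical locator takes the centroid of the brightest connected
region of the median-smoothed mean of the red and green planes, restricted
to the ROI minus a 5% frame margin, and requires at least 15 gray levels of
contrast over the median background ("disc not found" otherwise). The
locator works at 2× downsampling: the chain only needs the center inside
the disc (~10 px accuracy).

Edge extraction resamples the smoothed image to polar coordinates about the
located center (360 angular samples, 1 px radial step, bilinear) and runs
Canny there, where the closed contour becomes a single-valued curve r(θ).
Per angular column the edge pixel with the strongest gradient magnitude
wins; ties go to the smallest radius; columns without a response are
skipped, and fewer than 50% responding columns raises "edge too weak". The
polar raster extends to 3× the expected disc radius (default expectation:
ROI diameter / 13, from the ~6.4 ROI–disc ratio), but is capped at 90% of
the distance from the disc center to the ROI boundary so the much stronger
ROI rim cannot masquerade as the disc edge.

## Calibration statistics

The offline ratio is the **mean of per-image ratios**; the ratio of mean
diameters is computed alongside for transparency, as the two differ under
per-image magnification variation. All standard deviations are population
(1/n) deviations, including the cohort ROI spread `U_lROI` and ratio spread
`U_r`. Abnormal images are excluded before pooling: failed ROI or disc
detections always, and — when per-image diopters are supplied — eyes with
|D| > 6 D (configurable; serious axial ametropia breaks the stable-Δd
assumption). Online, a single image has no spread of its own, so the
offline cohort's `U_lROI` is reused in the uncertainty propagation.

Uncertainty follows first-order propagation for a product/quotient:
relative variances of `r`, `L_disc` and `l_ROI` add in quadrature. The ISO
reference arithmetic `P = 1700/N` (100 mm target at 1000 mm, 17 mm focal
length) and the bias columns `ΔP = P_disc − P_ISO`,
`ΔP′ = 100·ΔP/P_ISO` are provided for comparison against target-photography
measurements; no physical target is involved.

## Disc-diameter prior

DerSimonian–Laird random-effects pooling: fixed-effect weights `1/se²`,
Cochran's `Q`, moment estimator `τ² = max(0, (Q − df)/C)` with
`C = Σw − Σw²/Σw`, random-effects weights `1/(se² + τ²)`, pooled SE
`(Σw*)^(−1/2)`, 95% normal CI. The bundled seven-study table pools to
1.921 ± 0.026 mm with substantial heterogeneity (τ² ≈ 0.0043) — the
random-effects choice matters, since the fixed-effect estimate would be
dominated by the single n = 3918 study. The implementation is cross-checked
in the tests against `statsmodels.stats.meta_analysis.combine_effects`.
Area-only studies are converted by the equivalent-circle diameter
`2·sqrt(area/π)`. Standardized residuals `(x − pooled)/sqrt(se² + τ²)` are
reported for information only.

## Synthetic cohorts

The generator emulates exactly the statistical structure the method
assumes, at desk scale:

- **Camera profiles** mirror four real camera classes at 1/5 linear scale
  (e.g. the Canon-like profile: 595×397 frame, ROI 360.478 ± 0.103 px, true
  pitch 34.485 µm = 5× the corresponding ISO reference). Two profiles have
  ROIs taller than their frames, reproducing the cropped-circle case. The
  scale keeps a 100-image cohort's full detection run near a minute while
  leaving discs 45–70 px wide, large enough for ~1% edge accuracy.
- **Per-image truths**: ROI diameter ~ N(profile mean, profile std); disc
  diameter in mm ~ N(1.921, 0.19) truncated at ±3.5 σ; diopter ~
  N(−0.559, 3.522) truncated at ±10 D. The disc is projected to pixels
  through the profile's true pitch scaled by `(f1 + Δd)/f1`, drawn as a
  vertical-major ellipse (axis ratio 0.9) at 0.6 ROI radii to a randomly
  chosen nasal side with small vertical jitter.
- **Rendering**: dark background, radially shaded reddish ROI with an
  anti-aliased rim, brighter yellowish disc with a soft (1.2 px) edge, four
  dark vessel arcades leaving the disc, additive Gaussian noise (σ = 3 gray
  levels), all deterministic per seed. An optional quadratic radial lens
  distortion exists but defaults to off, since no distortion magnitude is
  specified anywhere and the calibration treats distortion only through the
  ratio's camera dependence.
- `expected_ratio` integrates the generator's own distributions
  (`E[r] = E[l_ROI]·pitch·E[(f1+Δd)/f1]·E[1/L]/1000`) on a dense grid; it
  is the analytic oracle that cohort statistics are tested against.

What passing synthetic tests shows: the detection chain and the statistical
estimator are unbiased to within a few tenths of a percent under the
modelled geometry, noise and population spread, and the end-to-end pitch
recovery error stays within 5% at 100-image cohorts. What it does not
show: robustness to real retinal texture, illumination gradients,
pathology, media opacity, or uncorrected lens distortion — none of which
the renderer attempts.

## Problem sizes and numerical choices

The test suite runs cohort statistics at n = 2000 (measurement level,
closed-form oracle, 3-SE band) and the full rendered pipeline at 5 seeds ×
100 images (5% recovery band); the farthest-pair fit is checked against an
O(N²) brute-force oracle on 100 random 50-point clouds; the per-unit disc
chain accuracy check uses 30 rendered frames. These sizes were chosen so the
whole suite completes in a few minutes on one core while keeping every
statistical band at 3 SE or wider of its own sampling noise.

Degenerate inputs raise typed errors rather than returning sentinels: blank
red channel, empty masks, no qualifying Hough circle, contrast-free disc
search, flat polar rasters (gradient below 1e-3 on the 8-bit scale), and
sub-2-point farthest-pair input. The published calibration table carries
its own last-digit rounding in the bias columns (the authors evidently
carried unrounded intermediates); the acceptance tests therefore hold
pitches and uncertainties to 3 exact decimals but the bias columns to
0.0015 µm / 0.01 percentage points, and the published meta-analysis
relative weights — whose inputs are 3-decimal standard errors — to 0.05
percentage points.

## Known limitations

- The classical brightest-region locator assumes the disc is the brightest
  smoothed region inside the ROI; bright pathology (exudates, atrophy) can
  defeat it on real images. The strategy interface exists so a learned
  detector can be plugged in.
- The farthest-pair diameter is sensitive to single outlier edge points by
  construction; the polar per-column selection limits but does not remove
  this.
- Lens distortion is not estimated; the ratio absorbs it only on average,
  per camera, which is the method's core approximation.
- The diopter compensation `P′ = P (f1+Δd)/f1` assumes purely axial
  ametropia; refractive (corneal/lens) ametropia violates it.
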