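# Methods

## Image model and quantification pipeline

An en-face OCTA angiogram is treated as an 8-bit grayscale grid with a known
physical scale (default 304 × 304 px over 3 × 3 mm, fovea-centered). The
pipeline is deterministic for a fixed input and configuration:

1. **Multi-pass vessel extraction.** Global histogram equalization maps
   intensity *v* to `h(v) = round(255 * cdf(v) / MN)` with `cdf(v)` the count
   of pixels ≤ *v* and `MN` the number of pixels equalized; the result is
   thresholded at ≥ 185 (inclusive; vessels carry the high flow signal).
   Pass *k* re-equalizes only pixels not yet classified in passes 1..k−1,
   so each pass re-stretches the residual dynamic range and reveals fainter
   structure; the final mask is the union, which makes masks nested in the
   number of passes by construction. Three passes are the default. A
   consequence of rank-based equalization is that every pass converts
   roughly the brightest ~27% of its residual into "vessel"; the scheme
   works because genuinely avascular tissue is the darkest structure in the
   image and is claimed last, if at all. Degenerate inputs (constant images,
   or a pass-1 vessel fraction outside 5–95%) are rejected by a quality
   guard, the software analogue of discarding low-signal or artifacted
   scans.

2. **Zhang–Suen thinning.** The union mask is thinned to one-pixel
   centerlines by the original two-subiteration boundary-deletion scheme,
   iterated to a fixed point. It is implemented in-package (vectorized over
   the image) because the widely used library variant is a lookup-table
   approximation that differs at line ends. Known limitation inherited from
   the original algorithm: on dense, speckle-like masks a small fraction of
   pixels (< 0.5% in practice) deadlocks in locally thick configurations
   (the 2 × 2-block case); this has no measurable effect on the perfusion
   map.

3. **Perfusion map.** The binary skeleton is convolved with a normalized
   L × L Gaussian kernel, L = 35 and σ = 0.3·((L−1)·0.5 − 1) + 0.8 = 5.6 px,
   with the scale factor α chosen so the weights sum to 1 (so total map mass
   equals the skeleton pixel count up to border losses). Borders are
   zero-padded: the analysis regions sit ≥ 0.7 mm from the border at default
   geometry, so the padding policy cannot affect parafoveal measurements,
   and the attenuated border band never seeds a void (its minimum, at
   corners, is ~25% of the interior level, above the 10% seed threshold).

4. **Flow-void and FAZ detection.** Void detection is seeded hysteresis
   thresholding on the perfusion map. Pixels below `void_threshold_frac`
   (default 0.10) of the map maximum *seed* a void; each seeded component is
   grown through 4-connected pixels below half the *plateau*, the median map
   value over clearly perfused pixels (≥ 0.5 × max) inside the analysis
   disc. The two levels play different roles: the low seed threshold decides
   *existence* (a dense healthy network never dips that low, so lesion-free
   images yield no voids), while the half-plateau growth decides the
   *boundary*. The half-height level is where a Gaussian-blurred step
   recovers the true edge position; a single low threshold would instead
   erode every void boundary by ≈ σ·z(1−f) ≈ 5 px and underestimate a
   0.25-mm² lesion by ~30%. Residual boundary bias is the curvature term
   σ²/(2r), under 5% for lesions ≥ 0.1 mm². Components smaller than 10 px
   are discarded as noise. The component containing the region center is
   the physiologically avascular FAZ: it is reported as its own area and
   excluded from the parafoveal flow-void total, which sums the remaining
   void pixels inside the 0.5–1.5 mm annulus times scale². Vessel/skeleton
   components use 8-connectivity and void components 4-connectivity, the
   standard complementary pairing. Because the boundary level is
   re-estimated per image, areas measured for the same lesion in different
   scenes can shift by a sub-pixel ring (~1–2% of area), which is the
   tolerance used when checking additivity of disjoint lesions.

   Monotonicity properties: raising `void_threshold_frac` can only add
   seeds, hence only add surviving components; growing a lesion lowers more
   map values below both levels. Both are verified in the test suite.

5. **Vessel density** is the percentage of region pixels covered by the
   vessel mask (a pixel belongs to a circle/annulus when its center does).
   Note that on real device data this metric is computed by the
   manufacturer's software from its own vessel segmentation; the mask-based
   figure here is an independent re-implementation of the definition, not a
   reproduction of the device's numbers, and multi-pass equalization
   deliberately over-segments faint signal (see step 1), so absolute
   densities are comparable only within a configuration.

### Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `threshold` | 185 | intensity | fixed binarization cut on equalized images; pinned for reproducibility |
| `passes` | 3 | — | trunk vessels, capillaries, residual faint signal |
| `block_size` (L) | 35 | px | kernel support; σ = 5.6 px ≈ 0.055 mm follows from L |
| `void_threshold_frac` | 0.10 | fraction of map max | seed level; calibrated once so lesion-free dense networks yield < 0.01 mm² of void |
| `min_component_px` | 10 | px | suppresses single-pixel noise components |
| region radii | 0.5 / 1.5 | mm | 1-mm foveal circle, 1-mm-wide parafoveal annulus |
| quality bounds | 5–95 | % pass-1 vessel fraction | rejects empty/saturated scans |

## Blood-pressure features

The 1-year window is `(enrollment − 365 d, enrollment)`, both ends
exclusive; the enrollment-day reading is stored separately and never enters
the aggregates (a documented choice — the source tables list "at
enrollment" and "in 1 year" as distinct rows). Within-patient SD uses the
sample (n−1) denominator, standard in the visit-to-visit variability
literature. "High" SBP is strictly > 140 mmHg, so a reading of exactly 140
is not high. A single in-window reading has no defined SD and is reported
as 0 with an insufficiency flag rather than dropped, so downstream tables
keep their row count; the ≥ 3-measurement eligibility filter makes this
unreachable in normal runs.

## Statistical procedures

All p-values are two-tailed and no multiple-testing correction is applied
across the 27-cell correlation grid — a faithful-reproduction choice, not a
recommendation. The `auto` t-test variant mirrors SPSS: Levene's test
(mean-centered) at α = 0.05 on raw data, or an F ratio on the two variances
when only summary triples are available. The chi-squared test is Pearson's
without continuity correction, df = 1. Partial correlation residualizes
both variables on an intercept plus the covariates by least squares and
correlates the residuals, p from t with df = n − 2 − k; rank-deficient
covariate sets raise an error naming the offending columns; missing
covariates are handled by complete-case deletion per analysis with the
dropped count recorded. Sex and diabetes enter as 0/1 codes; there are no
interaction terms.

## Synthetic data: what it emulates and what it does not

**Images.** The SVP morphology draws branching arteriole/venule trees
entering from the border (recursive jittered segments with decreasing
caliber) cross-linked by a random short-segment capillary mesh at ~15%
pixel coverage; the DVP morphology draws converging capillary vortices. A
central avascular disc realizes the FAZ target (default 0.31 mm², the
healthy-eye scale), and each lesion removes all vessels inside its disc.
Intensities are layered so that avascular tissue (28 ± 7) is darkest,
perfused inter-capillary speckle (70 ± 12) intermediate, capillaries
(118 ± 15) faint — deliberately inside the speckle's upper tail so that
only later equalization passes capture them all — and trunks (230 ± 10)
bright, with 4-intensity additive noise and 8-bit quantization. Ground
truth is exact rasterized bookkeeping: pixel counts × scale², with the
center-connected avascular component booked as FAZ (also when a lesion
merges with it) and per-lesion annulus-intersected areas recorded.

Passing tests on these images show the pipeline recovers areas of smooth,
fully nonperfused discs against a statistically homogeneous capillary bed.
Real angiograms add projection artifacts, motion lines, signal-strength
gradients, and partially perfused (rather than empty) voids; none of these
are modeled, so accuracy figures from the synthetic suite are upper bounds
on real-data performance.

**Cohorts.** Default sizes 256 cases / 70 controls. Per CKD patient, the
visit count is a rounded normal (mean 8.7, SD 6.1) clipped at 3 — the
latent mean is re-centered numerically so the *realized* mean matches 8.7
despite the clipping — with visits on distinct random days in the year
before enrollment plus an enrollment-day reading. SBP visits are
Normal(μᵢ, σᵢ) with patient-level μᵢ ~ N(135, 16) and σᵢ ~ N(14, 6.6)
floored at 2 mmHg (DBP analogously), rounded to integer mmHg and
constrained below the paired SBP. Outcomes follow a linear effect model:
flow-void area loads on the realized within-patient SD of SBP with a
planted partial correlation (default 0.244), SVP density loads negatively
on realized maximum SBP (default −0.186), and DVP density carries no BP
effect, mirroring the null layer. Effect sizes are calibrated from the
realized feature spread: β = ρ·√(var_avail)/sd(x_res) and noise SD
√((1−ρ²)·var_avail), where var_avail is the outcome's target variance
minus the small age/diabetes covariate contributions — this makes the
planted partial correlation exact in expectation while keeping the total
outcome SD at its configured value. Outcomes are *not* floored at zero:
the linear-Gaussian model is kept exact (a ~10% negative tail on flow-void
draws is accepted as a model idealization) so that correlation-recovery
checks are unbiased. Controls receive outcome distributions at the
configured control magnitudes and no BP series.

## Numerical choices and degenerate inputs

- Rounding in the equalization LUT is `np.rint` (half-to-even); with 8-bit
  data this differs from half-up only at exact .5 boundaries.
- The Gaussian kernel is built as α·(g ⊗ g) from its 1-D profile, so the
  separable convolution reproduces the stored weights exactly; the map of a
  single skeleton pixel equals the kernel to machine precision.
- An all-zero perfusion map (empty skeleton) marks the whole image as void;
  in practice the quality guard rejects such inputs earlier.
- A paired t test with zero-variance differences reports p = 1 for a zero
  shift and p = 0 otherwise; a two-summary t test with both SDs zero and
  equal means reports statistic 0, p = 1.
- Eye selection takes the higher quality score and breaks exact ties toward
  the right eye; the tie-break is a documented convention, not a data
  property.
- Patient counts are conserved: enrolled = analyzed + excluded, every
  exclusion carrying a machine-readable reason code.

## Problem sizes used in the validation suite

Lesion recovery runs 20 seeded images spanning 0.05–0.6 mm² (the clinically
observed range); partial-correlation calibration uses 1,000 null replicates
at n = 100, k = 5 and 200 planted-effect cohorts at n = 256; the BP feature
round trip covers 1,000 generated patients. These sizes give Monte-Carlo
error comfortably below the tolerances they are checked against.
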