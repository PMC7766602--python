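# Methods

## The measurement problem

Short-term cutaneous edema — fluid entering the interstitial space and the
viable epidermis, e.g. under venous occlusion, after histamine-induced
vasodilation, or during high-volume infusion therapy — alters optical
microscopy of the skin in three measurable ways: nailfold capillaroscopy
(NVC) frames lose contrast ("foggy" capillaries), capillary lumina dilate,
and the dermal papillae seen in reflectance confocal (CLSM) cross-sections
become hyporefractive. `capedema` implements one estimator for each effect,
plus the nonparametric statistics to compare conditions and a phantom
generator that closes the validation loop.

## Sharpness score

The score of a frame `I` is the mean absolute amplitude of its
difference-of-Gaussians band-pass:

    S(I) = mean | G_{σ_low} * I − G_{σ_high} * I |

with defaults σ_low = 0.5 px, σ_high = 8 px. The narrow-minus-wide
convention makes the DoG a high-pass; the absolute value makes the sign
convention irrelevant to the score. The band passes objects a few pixels
wide with crisp borders — first-row capillaries at NVC magnifications —
so epidermal water accumulation, which acts as a low-pass on the optical
image, lowers `S` monotonically.

Numerical choices:

* Gaussian kernels are sampled, normalized and truncated at 4σ; boundaries
  are handled by reflection. Reflection preserves constant rasters exactly,
  so `S` of a featureless frame is zero to round-off (the implementation and
  tests bound it by 1e−12; exact zero is not achievable in floating point
  because the two normalized kernels each carry an independent rounding of
  unity mass).
* Only the *narrow* kernel support constrains the admissible frame size:
  repeated reflection defines the wide blur on frames smaller than its
  nominal support, and the separable implementation agrees with dense
  explicit convolution to < 1e−10 there (verified against an independent
  oracle in the tests). Frames smaller than the narrow-kernel support are
  rejected.
* `S` is linear in intensity (`S(aI) = aS(I)`), so cross-image comparisons
  require a declared common scale. Loading never rescales silently;
  `normalize_unit` divides by the nominal full scale of the source bit
  depth (255 / 65535; floats by their max) as an explicit step, and the
  batch pipeline applies it by default. All published comparisons are
  relative (ratios, before/after), so the absolute unit is arbitrary.

### Relative sharpness and time courses

`relative_sharpness` divides a series by its mean pre-event (or
explicit-window) baseline, mapping baseline points to ≈1 and a drop by a
factor f to ≈1/f. `fit_timecourse` fits a cubic least-squares smoothing
spline to `(t, S)` points and reports the fitted-curve minimum over the
span, the RMSE, and the first time after the minimum at which the fit
re-attains 90% (configurable) of the pre-event baseline.

The smoothing factor `s` (the residual-sum bound of the classical
smoothing-spline formulation) is, when not supplied, chosen by 5-fold
cross-validation over a log grid spanning near-interpolation to
near-regression. scipy's smoothing spline does not expose the effective
degrees of freedom that a classical GCV denominator needs, and k-fold CV is
the nearest well-defined stand-in; for simulated series whose noise level σ
is known, the discrepancy principle `s = n σ²` is the better choice and is
what the validation suite uses (CV slightly over-smooths step-like series,
which delays the fitted minimum by up to ~2 samples). Flat or degenerate
series are fitted and flagged (`flat=True`, minimum reported at the span
start) rather than rejected, since short clinical series are common.

## Vessel size

Within an ROI drawn around one capillary cross-section, the lumen is
segmented by (1) Gaussian smoothing with `smooth_sigma` (default 15 px),
(2) thresholding at `threshold_frac` (default 0.20) of the *smoothed* ROI
maximum, (3) keeping the largest 8-connected sub-threshold component.
Vessel size is `√area` of that component, convertible to μm via the pixel
pitch. The threshold is relative, so the mask is invariant under
multiplicative intensity rescaling (detector gain, laser power).

Two deliberate choices:

* **Smoothed vs raw maximum.** The threshold references the smoothed
  maximum, making the operation self-contained and robust to isolated hot
  pixels; for well-behaved ROIs the two references differ negligibly.
* **Bandwidth vs lumen radius.** Smoothing shifts the detected boundary
  inward by ≈ `Φ⁻¹(1 − threshold_frac) · σ ≈ 0.84 σ` pixels (threshold
  crossing of a smoothed step edge at the 20% level), so `smooth_sigma`
  must be small relative to the lumen radius. The default of 15 px suits
  full-resolution CLSM where lumina span ≥ 100 px; phantom-scale analyses
  (radii 10–30 px) use σ = 0.5–2 px, and a physical `smooth_um` alternative
  converts through the pitch. Note that the boundary bias largely cancels
  in before/after *percent change* of medians, which is how the quantity
  is used.
* **Largest component.** An ROI contains one capillary; stray dark corners
  must not inflate the area. Ties are broken deterministically by smallest
  centroid row then column and recorded in `component_policy_used`.

`vessel_size_change` reports `100 · (median_after − median_before) /
median_before` on `√area` sizes — medians, not means, because capillary
size distributions are skewed and the literature quantity is a median
change.

## Papilla brightness

With user-supplied (or phantom ground-truth) masks for the papilla, the
melanin-bright ring at the dermal–epidermal junction, and the dark lumen:

    B = 100 · mean(papilla) / (mean(ring) − mean(lumen))

Referencing to the ring–lumen contrast removes detector gain and local
illumination (B is exactly invariant under `I → aI`, and covariant in the
documented way under offsets); the ×100 factor puts values in a convenient
range (tens). A ring mean at or below the lumen mean signals segmentation
failure or saturation and raises an error rather than returning a
meaningless ratio. No automatic papilla detector is provided: real masks
are drawn manually, and inventing a detector would change what the number
means. Sampling-variance considerations put the number of 500 × 500 μm²
frames needed per subject at ~10–12; smaller groups are flagged, not
rejected.

## Group statistics

All condition comparisons use rank statistics, treating capillaries as
independent observations (a simplification — capillaries within a subject
are correlated; a mixed-model treatment is out of scope and the caveat
carries over to any real-data use):

* **Kruskal–Wallis** H with midrank tie correction; p from the χ²(k−1)
  reference, except for total n ≤ 10 where the exact permutation
  distribution is enumerated over all assignments of the pooled ranks to
  the observed group sizes (the χ² approximation is poor there). If all
  pooled values are identical the comparison is degenerate: H = 0, p = 1.
* **Pairwise follow-up**: two-sided Mann–Whitney U per pair with Bonferroni
  adjustment `p_adj = min(1, m·p)`; Dunn's rank z-test is available as an
  option. Stars at 0.05 / 0.01 / 0.001 / 0.0001.
* **Box summaries**: type-7 (linear-interpolation) quartiles, whiskers at
  the most extreme data inside 1.5×IQR fences, the rest listed as outliers.

## Phantoms

The generators define the study conditions for all validation:

* **Hairpin capillary** (default 256² frame): a dark U-shaped tube
  (two limbs joined by a semicircular apex, width 12 px, contrast 0.5 on
  background 0.9) rendered with 4× supersampling and box down-sampling so
  sub-pixel edge placement keeps the blur series monotone; then Gaussian
  blur and seeded additive Gaussian noise, clipped to [0, 1]. The hairpin
  shape matches nailfold morphology and presents edges at many
  orientations. The standard blur series is σ = 0.5, 3.8, 7.2, 11, 14, 17.
* **Papilla cross-section** (default 201² frame): concentric lumen disk
  (r = 20 px), papilla annulus (to 45 px), melanin ring (to 60 px),
  intensities (0.05, 0.40, 0.95, 0.55). Zones are assigned by pixel-centre
  distance — no anti-aliasing — so the ground-truth masks coincide exactly
  with the intensity regions and formula-level checks hold to machine
  precision. Optional boundary roughness perturbs the lumen contour with
  zero-mean angular Fourier modes (k = 2–6) of given RMS amplitude; modes
  k = 0/1 are excluded because they would rescale or translate the area,
  so roughness leaves the enclosed area unchanged to first order.
* **Effect datasets**: paired before/after phantoms for
  occlusion dilation (lumen radius × 1.10 by default, per-subject radii
  spread ±15%, 1 px RMS boundary roughness per frame),
  histamine hyporefractivity (papilla intensity × 0.80, 12 pairs, noise
  σ = 0.02 ≙ 5% of the papilla mean), and histamine blur (blur σ from 0.5
  to a post-event value). Magnitudes default to the effect sizes the
  metrics are expected to resolve (≈10% dilation, 20% brightness drop,
  severalfold sharpness drop); they are generator inputs, not claims.
  Every dataset carries a manifest from which each metric's true value is
  computable analytically.
* **Time course**: baseline 1.0 until the event, then an instantaneous
  drop by `drop_factor` (default 2) and exponential recovery with
  `recovery_tau` (default 10 time units), sampled at 60 unit-spaced points
  (15 pre-event), noise σ = 0.03.

What the phantoms do **not** emulate: speckle and depth-dependent CLSM
noise, erythrocyte motion and flow artifacts in NVC video, multiple
capillary rows, uneven illumination, and real papilla shapes. Passing the
closed-loop suite therefore shows the estimators are correct and unbiased
under the stated image model, not that they are robust to every clinical
artifact; the manual-ROI workflow mirrors real use, where an operator
excludes artifacts by construction.

## Validation suite and problem sizes

`run_validation` (CLI: `capedema validate`) checks, per seed: strict blur
monotonicity plus a ≥4× sharpness collapse across the standard series;
the zero/linearity properties; disk-size recovery within 5% over radii
10–30 px; the brightness closed form (25.0) and gain invariance;
hyporefractivity recovery within ±3 points of −20% with Bonferroni
significance (12 pairs); occlusion recovery within ±3 points of +10%
(20 pairs); time-course minimum within 2 samples of the event and ≥90%
baseline recovery by 4τ; and a type-I-error simulation for the
Kruskal–Wallis stage (3 × 20 null groups, 1000 replicates, rejection rate
inside the exact binomial 99% interval). These problem sizes keep the full
suite around a few seconds on one core while leaving each check
well-powered; the report is byte-identical across reruns with the same
seed, and any failure exits nonzero. `scripts/acceptance.py` recomputes
the same quantities from scratch and writes them as JSON.

## Known limitations

* Pixel pitch is never inferred; it must be supplied per acquisition.
* The sharpness score is a relative quantity; absolute values are not
  comparable across optics or normalization conventions.
* Vessel segmentation assumes one dark lumen per ROI and a threshold level
  that separates lumen from papilla; heavily saturated or inverted frames
  are rejected rather than guessed at.
* Statistical tests assume exchangeable, independent observations within
  groups; repeated measures on the same subject violate this.
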