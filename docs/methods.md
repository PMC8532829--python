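# Methods

## The measurement model

A half-carcass photographed against a dark background is modeled as a
two-class intensity image: muscle pixels and subcutaneous-fat pixels, fat
brighter than muscle. The measurement chain is

1. **Outlining.** The carcass mask is the largest 4-connected component of
   pixels with gray > 20 (the generator guarantees background gray 0), with
   interior holes filled. Real protocols outline the carcass manually or
   semi-automatically; the automated surrogate here is exact on clean
   silhouettes and is validated pixel-exactly against the generator's
   ground-truth masks on noise-free images.
2. **Mean gray level** ḡ: arithmetic mean of gray over the carcass mask,
   fat and muscle pixels both included.
3. **Fat segmentation.** Fat = carcass pixels with gray strictly greater
   than the threshold T; **carcass fat area** = 100·|fat|/|carcass| %.
   The default T = 106 is the midpoint of the 100–112 range of per-carcass
   optimum thresholds from the calibration study; standardizing on one value
   trades a little per-image accuracy for method comparability.
4. **Optimum-threshold search** (diagnostic, not part of the standardized
   measurement): scan T ∈ [0, 255], minimize misclassified carcass pixels
   against a reference mask, and return the midpoint (rounded down) of the
   minimizing plateau. For perfectly separated constant-intensity classes
   this is the class midpoint. The criterion is a declared choice — the
   calibration study does not state how its per-carcass optima were judged.

Color inputs are converted with ITU-R BT.601 luma (0.299R + 0.587G +
0.114B, rounded half-up); the generator emits grayscale PNGs, so this path
is only exercised on external color images.

## The synthetic cohort generator

Published evidence for the calibration cohort is four group summaries
(SEUROP fatness scores 3, 4, 5, 6; n = 9, 6, 28, 7) with mean ± se of hot
carcass weight (360/358/363/347 kg), cutting fat (4.2/6.4/9.2/12.8 %) and
carcass fat area (25.0/31.5/41.7/48.4 %). The generator treats these as the
data-generating truth:

- per-animal SD = se·√n (summaries report standard errors of group means);
- HCW ~ Normal truncated to > 0; true fat fraction f ~ Normal truncated to
  [0, 100] (resampling);
- cutting fat follows the within-group linear model
  `CF = μCF + β(f − μFA) + ε`, β = ρ·sdCF/sdFA, ε ~ N(0, sdCF·√(1−ρ²)),
  truncated to ≥ 0, so each group keeps its published mean and SD and a
  within-group fat↔cutting-fat correlation ρ. **ρ is a free calibration
  knob** — no within-group covariance is published. The default ρ = 0.6
  places the cohort-level R² of the fat-area regression in the
  mid-0.6s-to-low-0.7s band of the calibration study.

Images: a star-convex smoothed-blob silhouette covering ≈ 45 % of a
192×144 frame (single 4-connected region, enforced); fat patches are the
top-f% of carcass pixels ranked by a Gaussian-smoothed (σ = 8 px) random
field, so the mask ratio equals f up to pixel rounding; intensities are
muscle ~ N(56, 12²), fat ~ N(145, 12²), both shifted by a per-image
brightness jitter ~ U(−6, 6), clipped to [0, 255] and quantized. The class
means come from fitting ḡ = a + b·f through the published end points
(f = 25.0, ḡ = 78) and (f = 48.4, ḡ = 99) and extrapolating to f = 0 and
f = 100 — a generator calibration, not a measured tissue property. It
reproduces the whole published gray-level row: 56 + 0.89·f gives 78.0,
84.0, 93.1, 99.1 at the four group fat areas. The ±6 jitter spreads
per-image optimum thresholds over roughly a dozen gray levels, emulating
the reported 100–112 spread of fat/muscle color across animals.

The frame size (192×144) is the package's own choice: a 50-image cohort
renders in about a second while pixel-rounding of the fat fraction stays
far below 0.5 percentage points (~12 000 carcass pixels per image).

All randomness flows from explicit seeds; one run seed fans out to
per-stage and per-animal sub-seeds via `numpy` `SeedSequence` splitting, so
stages re-run independently and byte-identically.

### What the generator does *not* emulate

Ribs, hooks, stamps, drip, uneven illumination, camera vignetting,
breed-specific anatomy, conformation differences, or any spatial
correlation between fat cover and anatomical site. Passing tests therefore
show that the measurement chain and statistics are correct **given** the
two-class intensity model and the published group structure — they are not
evidence that threshold 106 or the fitted models transfer to real
carcasses.

## Statistics

- **OLS** (via statsmodels behind `ols_fit`): R² = 1 − SSE/SST;
  RMSE = √(SSE/(n−p)) with p including the intercept — the regression
  standard error in response units, the convention used throughout;
  two-sided t-tests per coefficient. Rank-deficient designs error, naming
  the collinear terms.
- **ANOVA + Tukey HSD**: standard between/within decomposition;
  all-pairs comparisons with Tukey–Kramer standard errors
  √(MSE/2·(1/nᵢ+1/nⱼ)) referred to the studentized range; compact letter
  display by insert-and-absorb, letters ordered so the lowest mean gets
  "a". Zero within-group variance errors ("degenerate MSE").
- **Candidate features**: each base variable under each requested transform
  (identity, square, log₁₀, ln), plus products of 2..k distinct transformed
  factors (k = interaction order, default 3; the transform-rich variants
  use 4). Aliased duplicates collapse by canonical name. log₁₀(x) and ln(x)
  are exactly collinear by design; selection simply skips candidates that
  would make the design singular.
- **Stepwise**: bidirectional — forward add of the smallest-p candidate if
  p < α_enter, then backward drop of any retained term with p ≥ α_remove,
  until stable; α_enter = α_remove = 0.05 (the retention rule is published;
  the search direction and entry level are declared choices). No hierarchy
  is enforced: an interaction may enter without its main effects. Ties
  break by the deterministic enumeration order of the candidate list.
- The SEUROP score enters the simple score model as a numeric 1–15
  covariate; it is excluded from the stepwise multiple models, which use
  only mean gray, carcass weight and fat area.

## Problem sizes and numerical choices

Replicate studies use 500 cohorts for moment calibration and parameter
recovery and 200 (tests) / 100 (acceptance script, analysis driver)
measured cohorts for the model-ordering study; at these sizes the
Monte-Carlo standard errors are a few thousandths of an R² unit, small
enough to resolve the fat-area-vs-gray ordering. Recovery checks compare
at 3 Monte-Carlo SEs; 95 % CI coverage is required to land in [93 %, 97 %]
(binomial SE ≈ 1 % at 500 replicates). Degenerate inputs error loudly
rather than guess: empty masks, empty cohorts, groups of size < 2, logs of
non-positive values, constant predictors. The one silent degenerate case is
an empty *reference* fat mask in the optimum-threshold search, which
returns 255 (nothing labeled fat) with a warning, matching the
"no fat anywhere" reading.

## Known limitations

- The stepwise oracle equivalence (all-subsets agreement) is verified on
  small, well-separated problems; bidirectional stepwise is not guaranteed
  to find the best subset in adversarial designs.
- The compact letter display is the classic insert-and-absorb construction;
  with many groups it can require more letters than groups have meaningful
  orderings, though with four groups it is exact.
- Measured fat area is computed over the *extracted* mask, which at default
  noise can differ from the ground-truth silhouette by a handful of
  boundary pixels; the observed effect is ≲ 0.05 percentage points.
- Cutting fat includes kidney/pelvic and intermuscular fat that no surface
  image can see; the generator encodes this as within-group noise (1−ρ²),
  which is an assumption, not a measurement.
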