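# Methods

`photosense` audits the *operational* robustness of a fixed image
classifier: how much of the variance of its predicted probability is
attributable to plausible photometric acquisition variability, and what
that variability does to the thresholded decision.  The classifier is
treated as a black box `Y = f(X)` where `Y` is a probability (melanoma in
the dermoscopy setting) and `X` is the vector of five photometric
perturbation factors applied to a given image.  Nothing about training,
architecture or features enters the analysis.

## Uncertainty model

Each image is perturbed by five independent factors, each uniform on a
fixed interval:

| factor     | default bounds | meaning                                        |
|------------|----------------|------------------------------------------------|
| brightness | [0.5, 1.5]     | multiplicative rescale toward/away from black   |
| contrast   | [0.8, 1.2]     | rescale around the mean luma                    |
| sharpness  | [0.8, 1.2]     | rescale against a 3×3-smoothed copy             |
| saturation | [0.5, 1.5]     | rescale against the per-pixel grayscale         |
| hue        | [−0.1, 0.1]    | normalized circular shift of the 8-bit hue      |

Independence is a modeling choice that makes the variance decomposition
well defined; in real acquisition some correlation between factors is
expected, so the indices are first-order risk indicators and may
understate compound effects.  Dependence-aware indices are out of scope.

## Perturbation semantics (normative)

All stages operate on uint8 RGB with rounding half away from zero and
clipping to [0, 255] after every stage, in the fixed order resize →
brightness → contrast → sharpness → saturation → hue.  The stages do not
commute on quantized data (a test demonstrates this on a gradient image),
so the order is part of the contract.

* **Resize** — point-sampled bilinear interpolation with half-pixel
  alignment to 128×128.  This convention makes a same-size resize a byte
  identity and an exact 2× downscale a per-block mean, both of which are
  pinned by tests.  (Convolution-style resamplers weight a wider support
  and satisfy neither property exactly.)
* **Enhancements** — `out = round_clip((1−α)·degenerate + α·original)`
  with the degenerate image being all-black (brightness), the uniform
  image at the rounded mean of the per-pixel integer luma
  `round((299R + 587G + 114B)/1000)` (contrast), that luma image
  replicated to three channels (saturation), or a copy smoothed by the
  kernel `[[1,1,1],[1,5,1],[1,1,1]]/13` with the border ring copied
  unchanged (sharpness).  α = 1 is a byte-exact identity for every kind,
  so the nominal sample (1, 1, 1, 1, 0) reproduces the resized original
  exactly.
* **Hue shift** — convert to 8-bit HSV (hexcone; H, S, V each quantized to
  [0, 255], V exactly the channel maximum), shift
  `H ← (H + round(ΔH·255)) mod 256`, leave S and V untouched, convert
  back.  The integer shift is its own inverse mod 256; the RGB round trip
  is within 1 unit per channel on dermoscopy-like images (measured on the
  synthetic fixture; highly saturated synthetic noise can reach a few
  units because the hue channel quantizes 360° into 256 steps).  The 8-bit
  wheel has a harmless alias at H = 255 ≡ 0.

These formulas are the package's normative definition of the perturbation;
they are implemented directly in numpy so results do not depend on any
imaging toolkit's internals.

## Sensitivity estimation

A Saltelli design with base sample `N` over `D = 5` factors yields
`N(D+2)` evaluation rows (A, B, then AB_1…AB_D; the serialization order is
part of the design contract).  Points come from a single 2D-dimensional
Owen-scrambled Sobol' sequence (scipy's generator); the seed fixes the
scrambling, so identical (bounds, N, seed) give a bitwise identical
design.  The configuration default seed is 2021 and default `N` is 256
(1792 evaluations per image).  Whether the upstream sequence was scrambled
or offset differently is unknowable from its description, so exact numeric
reproduction of any particular historical sample set is not claimed —
only the design algebra and the estimators.

Estimators: Saltelli-2010 for `S1_i` (`mean[y_B (y_ABi − y_A)] / V`) and
Jansen for `ST_i` (`mean[(y_A − y_ABi)²] / 2V`), with `V` the population
variance of the pooled A and B responses.  Raw estimates are reported
(slightly negative values are honest estimator noise) with a clipped
[0, 1] view alongside.  Responses with `V < 1e−12` — on the probability
scale this means the predictor is flat — set a `degenerate` flag and
report zero indices instead of dividing by noise.

Verification is dual-route: a double-loop Monte-Carlo oracle estimates the
same conditional-variance definitions by literal conditional sampling
(outer 2000 × inner 500 by default, with the within-cell bias correction
for the first-order term), and a registry of analytic functions (Ishigami,
Sobol' g-function, additive linear) carries closed-form indices.  At
N = 4096 the Saltelli estimates recover the closed forms to within 0.02
(S1) / 0.03 (ST), and the two estimation routes agree within combined
Monte-Carlo tolerance.

## Aggregation

Indices are computed per image and aggregated by the unweighted arithmetic
mean with the sample SD (n−1) and a normal-approximation 95% CI half-width
`1.96·SD/√M`.  One design is shared across all images of a run, so
cross-image dispersion reflects the images, not resampling noise.
Degenerate images are excluded from means and counted
(`n_input = n_used + n_degenerate`).  Stratified tables (diagnosis class,
sex, age, localization) use the same arithmetic per group; empty groups
are omitted with a warning.

Ranking stability under dataset reduction: stratified subsamples without
replacement at fractions 0.1–0.8, 20 replicates per fraction by default,
reporting the share of replicates reproducing the full-data total-order
ranking and the mean Kendall tau against it.

## Decision metrics

With threshold `t` (default 0.5; ties labelled positive by the `p ≥ t`
rule): flip rate is the fraction of perturbed predictions whose label
differs from the baseline label, where the baseline is the prediction on
the nominal perturbation of the resized image (byte-identical to the
resized original); the dataset flip rate pools all image × perturbation
pairs.  Gini dispersion is the impurity `2p̂(1−p̂)` of the perturbed
labels — twice the Bernoulli variance, in [0, 0.5].  The Brier score is
computed on the baseline (unperturbed) probabilities against the true
labels; a perturbed-response variant is available via the function
arguments.  OAT sweeps sample one factor linearly in 5 steps across its
bounds with the others at nominal values.

## Surrogate Shapley attribution

A random-forest regressor (scikit-learn defaults, seeded, 80/20 split for
held-out R²) is fitted per image to the (factor sample → probability)
table.  Shapley values are then computed **exactly** on the surrogate by
enumerating all 2⁵ = 32 coalitions with the interventional value function
(coalition coordinates from the explained point, the rest from background
rows).  Exact enumeration is model-agnostic — it does not rely on any
tree-internal algorithm — and satisfies efficiency, symmetry and the dummy
axiom to numerical tolerance, which the tests verify together with
agreement against an independent permutation-sampling estimator.  The
background is a seeded subsample of the response table itself (capped at
200 rows); explained rows are a seeded subsample (default 64; 32 in the
battery runs) since mean |φ| stabilizes quickly.  Attributions are
aggregated as the cross-image mean |φ| per factor and compared with the
total-order ranking by Kendall tau.

## Synthetic data and probe predictors

The generator renders dermoscopy-like images: a skin-tone background with
a random illumination ramp, one soft-edged elliptical pigmented blob with
radial darkening (hue ≈ 0.055 on the normalized wheel, i.e. the
red-orange arc), low-frequency mottling, and occasional dark hair strokes.
Melanoma-labelled lesions get darker cores and stronger variegation.
Metadata is sampled from the standard archive vocabularies.  Defaults: 8
images, 128 px, melanoma fraction 0.3, seed 2021.  The generator emulates
the *photometric statistics* relevant to the audit (value, saturation,
hue, edge-energy distributions of lesion photographs); it does not emulate
diagnostic morphology, camera noise models or optics, so passing tests
demonstrate that the audit machinery measures what it claims on images
with realistic photometric structure — not that any real classifier is
robust.

Probe predictors close the loop: each computes one scalar statistic
matched to a factor — mean value channel (brightness), coefficient of
variation of the value channel (contrast), mean saturation (saturation),
saturation-weighted circular mean hue offset from a reference (hue), mean
absolute luma Laplacian (sharpness) — mapped through a logistic
`σ(gain·(statistic − center))`.  The contrast statistic is a coefficient
of variation rather than a raw SD because a brightness rescale moves the
value-channel SD and mean together: normalizing by the mean cancels the
brightness effect (up to clipping) and leaves the statistic dominated by
the contrast stretch, which is what a contrast probe must isolate.  Gains
and centers default to values calibrated once against the generator's
nominal statistic ranges so that sweeps stay on the responsive part of the
logistic.  Under the default bounds each of the brightness, contrast,
saturation and hue probes is dominated by its designed factor
(total-order index ranked first, both by the variance decomposition and
by surrogate Shapley).  The sharpness probe cannot dominate brightness —
edge energy scales with brightness over a wider interval than the
sharpness factor's own ±20% — so the designed expectation, verified by
test, is only that sharpness outranks the structure-preserving factors
(hue, saturation).

## Problem sizes used by the test battery

The battery runs at deliberately desk-scale sizes chosen to keep the
statistical margins comfortable: analytic recovery at N = 4096; the
end-to-end probe runs on 8 synthetic 128-px images at N = 128 (1024×7 =
7168 evaluations per probe); the brute-force oracle at 2000×500; Shapley
with 32 explained rows over a 100-row background.  All stochastic tests
fix their seeds.

## Known limitations

* No dependence-aware or second-order indices; no emulator-based
  estimation.
* Bit-exactness is guaranteed for this package's normative perturbation
  formulas, not for any other toolkit's implementation of "brightness" or
  "hue shift".
* The per-response level carries no confidence intervals; uncertainty is
  quantified across images, not within a single Saltelli estimate.
* The Brier score is only as meaningful as the labels supplied; for the
  synthetic generator the labels are synthetic constructs.
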