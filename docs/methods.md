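# Methods

## The model

`dermgfr` implements a non-invasive chronic-kidney-disease (CKD) assessment
chain that replaces the two-valued race multiplier of creatinine-based eGFR
equations with a continuous, per-subject value derived from forearm skin
texture. The underlying physiology: CKD alters skin hydration, collagen
remodelling and muscle breakdown, which manifests as denser and deeper
wrinkle lines; those lines are measurable as second-order image texture.

The chain, in the order the pipeline runs:

1. **Enhancement.** The grayscale image f (intensities in [0, 1]) is
   contrast-enhanced as `f + WTH(f) − BTH(f)`, where WTH/BTH are the white
   and black top-hats with a disk structuring element (default radius 3 px,
   on the order of a wrinkle line width at ~21 × 36 µm per pixel). This
   amplifies fine bright and dark structure — the wrinkle lines — against
   the smooth skin background. The morphological operator behind the
   published pipeline is not specified in detail; this additive top-hat
   scheme is a standard choice and the radius is config-exposed.
2. **Directional gradient.** gx = ∂f/∂x, gy = ∂f/∂y by central differences
   (one-sided at borders; rows are y, columns x, 0-based). The direction is
   θ = atan2(gy, gx), defined as 0 where the magnitude vanishes. The scalar
   image handed to texture analysis is the gradient magnitude rescaled to
   [0, 1] by its maximum; θ or the enhanced image itself can be selected
   instead (config `texture_source`).
3. **Co-occurrence texture.** The image is uniformly quantized to L = 8
   grey levels and a grey-level co-occurrence matrix (GLCM) accumulated at
   distance 1 over the four orientations {0°, 45°, 90°, 135°}, symmetric,
   then normalized. Accumulating over orientations suppresses the
   dependence on hand pose. From the GLCM we take four Haralick statistics
   as the texture random variables (RVs) — contrast Σ(i−j)²p(i,j)/(L−1)²
   (normalized so all four RVs share a [0, 1] scale), correlation,
   energy Σp², homogeneity Σp/(1+(i−j)²) — plus entropy −Σp log₂p for
   reporting. Correlation is undefined on constant images and is then
   reported as 0 with a warning.
4. **Skin parameter.** The four RVs act as the constants of a
   four-parameter logistic curve evaluated at the subject's age x:
   Sp = d + (a − d)/(1 + (x/c)^b), with a = contrast (minimum asymptote),
   b = energy (hill slope), c = correlation (inflection point, clamped to
   [10⁻³, 1] since the form needs c > 0), d = homogeneity (maximum
   asymptote). Sp is bounded between a and d and runs from a at x → 0
   to d as x grows.
5. **GFR and staging.** Reference equations are MDRD
   (175 · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³, × 0.742 female, × 1.212 black) and CKD-EPI
   (141 · min(Scr/k, 1)^α · max(Scr/k, 1)⁻¹·²⁰⁹ · 0.993^age, × 1.018
   female, × 1.159 black; k = 0.7/0.9, α = −0.329/−0.411 female/male). The
   texture-based equation substitutes Sp for the race factor:
   GFR = 175 · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · Sp, with no sex multiplier (an
   optional female-factor flag exists for sensitivity analysis, default
   off). Stages: ≥90 → 1, 60–89 → 2, 30–59 → 3, 15–29 → 4, <15 → 5.
6. **Ensemble statistics.** Each CKD level is treated as a random process
   whose realizations are subjects' RV vectors. Per subject we take the
   mean of the four RVs; per level, the mean ± sample SD (n−1) over
   subjects and the percent deviation (mean₁ − mean_L)/mean₁ × 100 from
   the level-1 baseline.
7. **Classification.** Two feed-forward networks with one hidden layer of
   five logistic-sigmoid units and a linear five-unit output, decoded as
   one-hot (argmax + 1, ties to the lower level). Network 1: age, gender
   (1 = male, 2 = female), height, weight, serum creatinine. Network 2:
   age, gender, height, weight, Sp, mean-of-RVs, and entropy as the
   seventh input — the published description names only six inputs for
   seven neurons, so the seventh is config-selectable; entropy was chosen
   as the only remaining per-image texture scalar. Evaluation collapses to
   binary confusion (positive = any CKD level 2–5, negative = normal),
   reported as percentages of the test set.

## Training procedure and numerical choices

The training algorithm is not part of the published method and is fixed
here as full-batch gradient descent on the mean squared error of the linear
outputs against one-hot targets, Xavier-uniform initialization from a
seeded generator, 10 000 epochs at rate 0.5 (all config-exposed). The rate
and epoch count were set so the 45-record fit actually converges; at much
smaller rates the loss is still far from a stationary point after 5 000
epochs.

Inputs are z-scored by training-set statistics — raw heights (~160) and
creatinine (~1–10) differ by two orders of magnitude and would saturate
the sigmoids. Serum creatinine is additionally log-transformed first
(default, switchable): across CKD stages Scr spans roughly 0.5–25 mg/dl
and is heavily right-skewed, and GFR is a power law in it, so without the
log the end-stage tail dominates the z-scale and the clinically decisive
normal-vs-mild boundary collapses into a tiny interval.

Degenerate inputs: constant images yield correlation 0 (warned); c ≤ 0 is
clamped to 10⁻³ (warned); zero-variance input columns get unit scale in
the z-scorer; decoding ties warn and resolve to the lower level.

## The synthetic cohort

No images or records from the study are deposited, so the package ships a
generator that emulates the study conditions and makes every stage
testable:

- **Composition:** 75 subjects — 11 normal (level 1) and 16 per CKD level
  2–5; ages truncated-normal, mean 43.46, SD 17.86, range [14, 75]; gender
  Bernoulli(½); heights/weights from adult normals by gender.
- **Creatinine:** a target GFR is drawn uniformly inside the subject's
  stage band (level 1 capped at 130, level 5 floored at 2 ml/min/1.73 m²)
  and inverted through the MDRD male form,
  Scr = (175 · age⁻⁰·²⁰³ / GFR)^(1/1.154). Construction therefore
  guarantees that re-staging the MDRD estimate recovers the assigned
  level — the label/feature consistency the classifier tests require.
- **Images:** a smooth low-frequency background (Gaussian-filtered noise,
  scale 16 px, amplitude 0.12 around 0.7) stands in for illumination and
  tone; wrinkles are dark anti-aliased straight segments with
  Poisson-distributed count (floored at 2 — normal skin also shows lines)
  and level-dependent expected count {24, 56, 96, 144, 200} and depth
  {0.22 … 0.54} on a 256 × 256 patch; sensor noise (SD 0.005) and a
  Gaussian optical blur (σ = 1 px, the camera PSF) finish the render. The
  blur matters: without it the sensor noise dominates the gradient image
  of line-free skin and normal skin would not have the smoothest texture.
- **Patch size:** 256 × 256 rather than a smaller patch because the study
  computed features on full 5-megapixel frames; on 128 px patches the
  per-level feature SD (~5% of the mean) is far wider than the narrow
  published per-level spreads, and at 256 px the level-1 vs level-2
  separation (gap ≈ 5 pooled SDs) is comparable to the published table.
  Line counts scale with patch area (density held fixed).

With these defaults the per-level mean of the RV means decreases strictly
from level 1 to level 5 in 10/10 generator seeds, and the two networks
reach ~91% (with creatinine) and ~97% (texture only) mean binary test
accuracy over ten 45/30 train/test splits (5 normals in each test set) —
the creatinine-free network on par with the creatinine one.

What the generator does **not** model, hence what passing tests do not
show about real data: skin tone and melanin, curved or branching wrinkle
geometry, illumination artefacts, comorbidity structure, any correlation
between demographics and stage (ages are independent of level here), or
the real joint distribution of texture with kidney function — the
stage-conditioned line statistics are stated assumptions, not estimates.
Synthetic classification accuracies are statements about this generative
model only.

## Known limitations

- The mapping (contrast, energy, correlation, homogeneity) → (a, b, c, d)
  follows the published assignment; it treats per-image statistics as
  curve constants, so Sp inherits any instability in correlation on
  near-degenerate textures (hence the clamp).
- The published deviation table lists one value (level 3, 7.329%) that is
  inconsistent with its own printed means, which give 17.33%; the package
  reproduces the three self-consistent values and does not target that one.
- Whether the study applied the 0.742 female factor inside the
  texture-based equation is not stated; the default is the literal
  equation without it.
- GLCM distance, angles, level count and normalization are unstated in the
  source; the defaults here (d = 1, four angles, L = 8, symmetric) are all
  config-exposed.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on ten
75-subject cohorts (750 images at 256 × 256) for the ensemble and
classifier checks, 200 random ≤8 × 8 images against the brute-force GLCM
oracle, 100 random networks against the loop-based forward oracle, and
10⁴ random inputs for the four-parameter-model bounds; unit tests use
64 × 64 patches with line counts scaled to that area.
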