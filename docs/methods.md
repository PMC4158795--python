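# Methods

This note records the model as implemented, the choices made where the design
was genuinely open, what the synthetic data does and does not emulate, and
the known limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Statistical model

Bandpass responses are modeled as generalized Gaussian,
`p(x; α, β) ∝ exp(−(|x|/α)^β)`, with a shared shape `β` and class-dependent
scales: `α₁` under the target hypothesis, `α₀` under the background ("natural
images") hypothesis. `β = 0.5` is the default everywhere, the value
characteristic of natural imagery; it is configurable (`RunConfig.shape`) but
never estimated from data (out of scope by design).

Scales are estimated by MAP with a conjugate Gamma prior,
`α^β = (Σ|x_j|^β + ν)/(n + ηβ)`, with `η = 1`, `ν = 10⁻³`. Two properties
matter downstream:

* The estimator converges to `E|X|^β = α^β/β`, not `α^β`. We keep the
  estimator verbatim and store the estimated quantity (the "scale power")
  directly; since *every* consumer uses the same estimator, the ratio
  `α₁/α₀` — hence the rectifier threshold `T` — is unaffected, and the gain
  `γ` is consistently expressed in the same units. All formulas consume
  `α^β`, never `α`, which also avoids raising small numbers to power `1/β = 2`.
* "Prior disabled" means `η = ν = 0` (the plain sample mean of `|x|^β`).
  This is the condition under which the Jensen relation between the
  neural-network and algorithmic paths (below) is exact.

The discriminant unit computes `g(x) = γ|x|^β − T` with
`γ = 1/α₀^β − 1/α₁^β` and `T = log(α₁/α₀)`. We fix this one sign convention
throughout (the literature is inconsistent between the LLR form and the
rectifier form; only this choice makes them identical). `|0|^β` evaluates to
0 exactly; the network is feedforward, so no derivative at 0 is ever needed.

## Three forward implementations

* **forward_nn**: `ψ(x) = ⌊γ|x|^β − T⌋₊` pointwise, then average pooling.
* **forward_bio**: differential divisive normalization
  (`|x|^β/α₀^β − |x|^β/α₁^β − T`), sigmoid to a posterior, then
  `ξ(p) = log(p/(1−p))` for `p ≥ ½` (0 otherwise), then additive pooling.
  Because `ξ∘σ = ⌊·⌋₊` exactly, this equals forward_nn; a variant of ξ that
  carries a ½ factor (supported via `xi_variant="paper"`) halves the output
  globally, which is immaterial to ranking and classification. The canonical
  (no-½) form is the default so the equivalence is exact.
* **forward_algorithmic**: per neighborhood, MAP-estimate the local scale
  power and evaluate `γ·α̂₁^β(l) − T` (the local KL divergence between the
  neighborhood's response distribution and the background model). Not
  rectified per sample; with the prior disabled it equals the neighborhood
  mean of `g`, so by Jensen's inequality it never exceeds forward_nn.

Numerically, the bio/nn identity holds to machine precision for the moderate
LLR ranges that arise in practice (the sigmoid→logit round trip loses
precision only for |g| ≳ 30).

The rank consistency between the nn and algorithmic paths is measured, on
trained detectors applied to synthetic scenes, as the Spearman correlation
computed per channel over complex units where at least one path reports
positive saliency; the minimum across channels is reported. Each channel is
a separate detector with its own affine output scale, so ranks pooled across
channels are not commensurate; and units silenced by the dead zone (nn
exactly 0) versus the algorithmic path's negative values agree that a
stimulus is not salient, but their rank ties carry no information and would
dilute the coefficient arbitrarily.

## Pooling and grids

Layer-1 simple units are dense (every pixel, every pyramid level); complex
units average over a 5×5 spatial window spanning 2 adjacent scales and
subsample 3×3 spatially (stride 1 in scale). Cross-scale pooling maps
coarser-scale coordinates by the map-shape ratio (nearest pixel, no value
resampling) and weighs each scale equally — the pooled value is the mean of
the per-scale clipped-window means, and all three forward paths share this
weighting so their relations hold at map borders too. Window statistics at
borders use in-bounds samples only. Ties in max pooling resolve to the value
(first-index order when indices are needed). Boxes and grids are 0-based,
half-open; one convention everywhere.

## The two-layer network

* **Front end**: four 11×11 Gabor kernels, orientations {0, π/4, π/2, 3π/4},
  aspect 0.3, envelope width 4.5 px, wavelength 5.6 px, each zero-mean and
  unit-norm (the source of these filters normalizes; we follow it and flag
  the choice in config). Optionally 63 8×8 DCT kernels (the separable cosine
  basis minus DC) extend the channel pool; per-class channel selection keeps
  the `k` channels of largest whole-field pooled saliency (default 4,
  index tie-break).
* **Pyramid**: 10 levels, subsampling factors `2^(i/4)`, anti-aliased
  bilinear resizing; levels smaller than the kernel are not built (the level
  count adapts downward for small images).
* **Layer-1 training**: per class, the scale powers are fitted to the Gabor
  responses pooled over *all* locations, scales, and training images of the
  class (capped at 10⁶ samples per channel with a seeded subsample), against
  the pooled background-image responses.
* **Templates**: layer-2 filters are patches sampled uniformly at random
  from the layer-1 saliency output of the class — size n ∈ {4, 8, 12, 16},
  spanning all layer-1 channels, normalized to zero mean and unit norm
  jointly over channels; degenerate (near-zero-norm) patches are redrawn.
  Each template owns a pooling neighborhood: a square covering
  S ∈ {10, 20, 30}% of the map area, spanning d ∈ {3, 5, 7} scales, centered
  at the template's sampling origin. One complex unit per template, centered
  at that origin, so the feature dimension equals the template count.
* **Layer-2 responses**: the layer-1 output is contrast normalized (below),
  correlated with the template at every feasible scale, rectified by the
  template's own fitted `ψ`, and averaged over the pooling neighborhood.
  Training samples for the template's GGD model are the correlation
  responses inside its neighborhood over all class images (target) and all
  background images (null). The class saliency map sums rectified template
  responses over the template's own scale span (the scales its statistics
  were fitted on) and resamples to the input resolution.
* **Classifier**: linear SVM (primal, C = 1, one-vs-rest). Features are
  standardized to the training mean/sd before the margin fit — template
  gains span orders of magnitude, so raw features have no common scale; the
  standardization parameters are part of the trained model. The likelihood-
  unit (LU/PU/CPU) baseline layer receives the same treatment so unit-type
  comparisons are like-for-like.

### Contrast normalization

Layer inputs are divisively normalized by the cross-channel magnitude sum in
a window the size of the template, plus a **semisaturation constant** — the
class's mean layer-1 saliency at training time, stored with the model. A pure
ratio (semisaturation 0, ε-guarded) is scale invariant but renormalizes
near-silent regions (noise floors) to full range, which on synthetic scenes
destroyed the layer-2 signal entirely; anchoring the denominator at the
trained operating point, as in standard divisive-normalization models of
cortical gain control, suppresses regions far below typical energy instead.
Border windows use the in-bounds mean scaled to the full window count, so
clipped windows are not artificially under-normalized (without this, a
scene-independent border artifact dominates the layer-2 maps).

## Synthetic data

The generator emulates strongly textured scenes with embedded targets:
backgrounds mix two oriented sinusoidal gratings (default 30° and 120°,
jittered) plus white noise, under a smooth contrast-modulation field that
emulates the non-uniform contrast of natural textures; targets are oriented
grating patches (blended so zero contrast is exactly invisible), bright
polygon silhouettes, or *blank* regions (feature absence). Target boxes are
centered with ±12 px jitter: layer-2 pooling neighborhoods are
location-specific, which presumes class images share coarse layout, as
photographic object datasets do. Defaults: 96×96 scenes, 32×32 targets,
noise σ = 0.05, contrast 1.0.

GGD sampling uses the exact Gamma construction
(`|X|^β ~ Gamma(1/β, α^β)` with a random sign), which gives the closed-form
moment `E|X|^β = α^β/β` used as the estimator oracle.

What passing tests on these scenes do **not** show: performance on natural
images. The scenes are periodic, wall-to-wall texture; their bandpass
statistics are far less heavy-tailed than natural imagery after
normalization, which matters for layer 2 (below).

## Study protocols and problem sizes

The validation battery (`hdsn.experiments`, also driven by
`scripts/acceptance.py`) uses sizes chosen to run in minutes on one CPU:
100 random stacks for the equivalence checks, 10⁵ draws for the Monte-Carlo
estimator and expected-saliency checks (errors measured against the scale of
the closed-form expression, which is a difference of terms and can itself
sit near zero), 50 scenes / 20 training images per class for localization,
40 templates for the absence task (the reference per-class count), and a
3-class recognition split of 20 train / 20 test per class with 10 templates
per class. Detection studies report one box per scene, since every scene
contains exactly one target; average precision uses all-point interpolation
and greedy highest-score-first matching at IoU ≥ 0.5.

## Known limitations

* **Layer-2 discriminant units on bounded statistics.** After contrast
  normalization, template-correlation magnitudes on the synthetic textures
  have a narrow, bounded distribution (max/mean ≈ 1.1) rather than the
  heavy-tailed GGD the units assume. Under `β = 0.5`, the parametric-ReLU
  dead-zone boundary sits at about *twice* the mean response whenever
  `α₁ ≈ α₀`, i.e. above the maximum attainable response — so informative
  layer-2 units can carry discrimination in their pooled statistics (used by
  recognition features) yet be pointwise silent. Consequently the two-layer
  saliency map does not improve on the single-layer map for the blank-target
  (absence) task on these textures: the single-layer detector is already at
  ceiling and the two-layer map is near-silent. This is a statement about
  synthetic periodic texture, where the GGD shape assumption fails at
  layer 2; the absence task needs dense texture to be well-posed, and dense
  periodic texture is exactly what removes the heavy tails. Re-estimating
  `β` per layer would recalibrate the dead zone but is deliberately out of
  scope.
* The biological path's exactness degrades for |LLR| ≳ 30 (sigmoid
  saturation); irrelevant at trained operating points.
* The box-filter size and detection score threshold have no principled
  defaults (config parameters; the studies use the known target size).
* Training assumes class images fit in memory; sampling caps bound the
  estimator inputs, not the image count.
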