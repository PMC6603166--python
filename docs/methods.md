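# Methods

## Model

Style transfer treats an image transformation as an optimization over the
target image's pixels. A fixed convolutional network Φ maps an image x to
activations Φ^l(x) at named layers. Three representations are compared:

* **Content** C(x) = Φ^{l_c}(x) at one deep layer, `Conv4_2` by default —
  deep enough to be insensitive to texture, shallow enough to pin cell-scale
  geometry.
* **Style** S^i(x) = G(Φ^{l_i}(x)) for i = 1…5, the Gram matrices
  G_jk = Σ_p F_j(p) F_k(p) at `ReLU1_1`, `ReLU2_1`, `ReLU3_1`, `ReLU4_1`,
  `ReLU5_1`. The Gram discards spatial position, which is exactly why a
  style source from a *different* tissue location (and patient) is usable.
* The target is initialized as a copy of the content image and updated by
  L-BFGS-B to minimize

  L(x) = D_c(C(content), C(x)) + α Σ_i w^i D_s(S^i(style), S^i(x)),

  α = 100, w^i = 0.2, pixels box-constrained to [0, 1], 1,600 iterations in
  production. The network weights never change; gradients flow to pixels
  only, through hand-written backward passes for the 3×3 zero-padded
  convolutions, ReLUs, and 2× average poolings.

## Distance normalization

Only α and w^i are fixed externally; the algebraic normalization of the two
distances is a package convention, recorded in
`TransferConfig.distance_form`:

* `normalized` (default): D_c = mean(ΔF²) and D_s = ‖ΔG‖² / (4 C² M²)
  (C channels, M spatial positions). Both terms are then *intensive* —
  per-element quantities independent of image resolution and feature width —
  so a single α keeps the same content/style balance across working
  resolutions and across backbones. With a summed content term the balance
  degrades sharply with size: the content gradient grows with the element
  count and pins the deep features, stalling style descent.
* `classic`: D_c = ½‖ΔF‖² (summed) with the same style normalization — the
  textbook formulation, kept selectable.
* `mse`: plain mean squared error for both terms.

Gram matrices themselves are kept unnormalized; all scaling lives in D_s.

## Optimizer

scipy's L-BFGS-B with history size 100, strong-Wolfe line search capped at
20 evaluations per step, `ftol`/`gtol` set near machine precision so the
iteration budget, not an early tolerance, terminates production runs.
"Iterations" counts optimizer steps (line-search evaluations may be more).
The box bounds implement pixel clamping natively, preserving the monotone
non-increase of accepted iterates; the loss trace records the initial point
plus one record per accepted step (capped at `n_iterations` records). A
non-finite loss aborts with the iteration index and term values — there is
no silent recovery.

Content-copy initialization makes the first content term exactly 0 and the
whole pipeline deterministic up to floating-point reduction order; noise
initialization is available behind a seed. The style image is bilinearly
resized to the content image's working resolution before its Grams are
captured, since Gram statistics are resolution-sensitive and a shared scale
is the simplest defensible choice.

## Backbones

The production extractor is the 19-layer VGG topology (2-2-4-4-4 conv
blocks), built from a user-supplied `.npz` of named convolution weights;
a missing or incomplete archive is an explicit error, never a fallback to
random weights. Preprocessing (per-channel mean/std) is part of
`BackboneSpec`, with the standard ImageNet statistics for the pretrained
path and identity for the test path.

The test extractor is a seeded random network with the same naming scheme:
five blocks (one conv each, except block 4 with two, so `Conv4_2` exists),
ReLU after every conv, 2× average pooling between blocks, channel widths
8-12-16-16-16, He-initialized weights and zero biases. After drawing
weights, each convolution is rescaled so the mean rectified activation of
its filters is ≈ 1 on seeded reference noise — the activation-normalization
convention classically applied to style-transfer networks. Without it the
feature magnitude drifts exponentially with depth and the per-layer Gram
terms become wildly unbalanced. Zero biases keep the zero-input → zero
-activation property, a useful linearity probe. Convolutions use zero
padding ("same"), which makes Gram statistics border-sensitive at small
sizes; tests that check translation covariance therefore compare interior
crops only.

## Color coding and cropping

Evaluation presentations: gray = unweighted channel mean (deliberately not
luma weights — the transform mirrors plain channel averaging); green/red =
gray value placed in the kept channel with the other two exactly zero;
intact = unchanged. Group assignment is a seeded shuffle followed by
round-robin split, giving 25/25/25/25 at 100 images. Center-cropping takes
the window of side `round(fraction · dim)` with any off-by-one slack on the
bottom/right; the default fraction 0.5 focuses raters on a manageable number
of structures and is a config field, as neither the crop size nor whether
the style image was cropped is externally fixed.

## Rater-score model and statistics

A rating event is (rater, image, color group, added 0–6, removed 0–6) with
(rater, image) unique. Scores above 3 mark positive impact, below 3
negative, 3 none. Statistics:

* 7-bin histograms per axis; 7×7 intensity map of (added, removed) pairs;
  modal cell with ties broken toward larger added then larger removed and
  flagged.
* One-way chi-square against uniformity, Σ(O−E)²/E with E = N/k and
  df = k−1; for the "improved vs. not" question the two-bin split
  (> 3 vs. ≤ 3) per axis is used — the minimal reading of a one-way test on
  that claim.
* Paired t-test on d = added − removed with the rating event as the pairing
  unit (per-image-mean pairing is a caller option: aggregate first). sd uses
  the n−1 denominator; zero-variance differences raise a degenerate-test
  error rather than returning an infinite statistic. All p-values are
  two-sided.
* Per-image categories from the mean over raters on each axis: improved
  (> 3), degraded (< 3), neutral (= 3). The seven categories partition the
  images; a mixed improved/degraded pair is filed under the degraded axis
  (`degraded_added_only` / `degraded_removed_only`), since a degradation is
  the clinically salient event. A mean of exactly 3 is neutral and belongs
  to neither improvement nor degradation.

## Synthetic data

The generators emulate the *structure* of the pipeline's real inputs, not
their optics:

* Pseudo-CLE: dark background (level 0.10) with Gaussian noise (sd 0.04),
  25 bright elliptical cell bodies with darker cores (fluorescein pools
  extracellularly), and artifacts — bright blurred disks and horizontal
  streaks — covering ≈ 10% of the field by default; grayscale first, then
  replicated to three channels like real CLE. 256×256 default, 64×64 in
  tests.
* Pseudo-H&E: eosin-pink stroma with low-frequency texture and 80 purple
  elliptical nuclei; the gamut guarantees mean(R) > mean(G).
* Rating tables: 5 raters × 100 images. Each image gets a planted category
  (default partition 84/6/5/2/2/1/0 across
  improved_both/improved_removed_only/improved_added_only/
  degraded_removed_only/degraded_added_only/degraded_both/neutral) and a
  color group; each rater's score on an improved axis is the group's modal
  anchor (gray (5,4), green (5,5), red (5,4), intact (5,4)) plus rounded
  Gaussian noise (sd 0.7 — raters typically within one level of consensus),
  clipped to the axis's status range (improved 4–6, degraded 0–2, neutral
  exactly 3). Clipping makes per-image means respect the planted category
  exactly, so category recovery is deterministic, while modal-cell recovery
  is statistical but extremely robust at 500 records.

Every generator is a pure function of (params, seed) and emits a
ground-truth manifest (cell centers, artifact masks, planted categories) so
recovery tests have an exact oracle.

What the synthetic data does **not** emulate: real confocal optics, tissue
morphology, stain variability, or human rating behavior. Passing tests
demonstrate that the algorithmic machinery is correct and that planted
signals are recovered — not that stylized real CLE images gain diagnostic
quality; that claim requires human raters on real data.

## Problem sizes

Tests and the acceptance script run the optimization at 64×64 with the
seeded test backbone and 20–50 iterations, rating analyses at 5 × 100
ratings, and oracle checks at ≤ 6 channels × 16 positions — desk-scale
settings at which every check completes in seconds while exercising the
full code paths used at production scale (native-resolution images, 1,600
iterations, pretrained VGG-19).

## Known limitations

* The pretrained path needs an externally supplied weights archive; no
  checked-in weights exist, so its integration behavior beyond registry and
  error contracts is untested here.
* L-BFGS over pixels is CPU-bound numpy; production-size images (≥ 512²)
  at 1,600 iterations take minutes to hours. The implementation favors
  correctness and testability over speed.
* The chi-square binning for the improvement claim and the t-test pairing
  unit are documented conventions; other readings of "one-way chi square"
  (e.g. pooled axes) are possible and configurable by the caller.
* With `distance_form="classic"` the α = 100 balance is resolution-
  dependent; choose α per resolution if that form is selected.
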