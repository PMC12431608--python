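# Methods

## Model

The framework classifies queries in an N-way K-shot episode by fusing two
independent per-episode classifiers.

**Second-order image branch.** A feature map `h × w × d` is reshaped into
observation vectors and summarized by its double-centered pairwise
Euclidean distance matrix (the BDC matrix). Double-centering removes the
additive row/column structure of the distance matrix, so what remains
encodes the *dependence* among observations — a covariance-like statistic.
Class prototypes are element-wise means of support BDC matrices
(double-centering is linear, so the mean is itself double-centered), and
queries are scored by the Frobenius inner product `tr(AᵀP)`. Plain, not
squared, Euclidean distances are used.

The observation axis is configurable. By default the *channels* are the
observations (each channel described by its `h·w` spatial profile), giving
a `d × d` BDC matrix whose centering sums run over `d` — the construction
used by deep BDC pooling layers, and the one that keeps the normalization
in the centering formula dimensionally consistent. The alternative
(`axis="spatial"`, an `(h·w) × (h·w)` matrix over spatial positions) is
implemented and tested but not the default.

**Probability conversion.** Trace similarities scale with the matrix size
and the squared feature magnitude, so feeding them to a softmax directly
saturates it. Similarities are z-scored across the episode's classes and
passed through a temperature-scaled softmax (default temperature 1.0).
Both steps are strictly increasing, so the predicted class — the raw
argmax — is unchanged; ties resolve deterministically to the lowest class
index. When all similarities are equal the z-score is undefined and the
output is the uniform distribution.

**Text branch.** Class descriptions are joined with `", "` — nothing else
is inserted or appended, so any trailing period is carried by the last
description. The compound prompt is encoded by a pluggable text encoder;
the paired image encoder embeds query images into the same space. Both
embeddings are L2-normalized inside the module, which makes the branch
invariant to positive rescaling of encoder outputs. Cosine similarities
are divided by a temperature (default 0.01, i.e. the familiar
logit-scale-100 convention of contrastively trained vision–language
models) before the softmax. The library schema permits any number ≥ 1 of
descriptions per class, though five is the intended use.

**Fusion.** Support-set cross-entropy is the mean (not sum) of
`−ln p(true class)` over support items, with probabilities floored at
1e-12, so K does not rescale the losses. Raw weights `1/(L + ε)` use
`ε = 1e-8`; normalization makes them convex; smoothing with `β = 0.5`
(default) interpolates halfway toward the equal split. `β = 0` leaves the
dynamic weights untouched and `β = 1` reproduces fixed equal-weight fusion
bit-for-bit. When only one modality is present the weights degenerate to
(1, 0) or (0, 1) and smoothing is bypassed.

In 1-shot episodes the image branch's support loss is degenerate — each
support item is its own prototype, so its loss is near zero and the image
weight is biased upward. The default computes the loss exactly as stated;
an opt-in leave-one-out mode (`FusionConfig(loo_support_loss=True)`)
removes each support item from its own prototype for K ≥ 2, where the bias
can actually be corrected.

The confidence-based fusion arm (raw weight = mean top-1 probability on
the support set, then normalized) is an *interpretation* of
confidence-weighted dynamic fusion, provided only as an ablation
comparison; its published definition is not specified precisely enough to
reproduce.

Activation-map fusion min-max normalizes each map to [0, 1] and takes the
weighted sum. A constant map normalizes to all zeros (avoiding 0/0)
rather than all ones, on the view that a featureless map carries no
localization evidence.

## Episodic protocol

Classes are split 3:1:1 into train/val/test with no class overlap;
remainders after integer division go to train. Classes with fewer than 3
images (1-shot) or 7 images (5-shot) are excluded *before* the split.
Episodes draw N classes and K + q items per class without replacement;
q defaults to 2 (q = 1 is allowed but warned against, since single-query
episodes give unreliable accuracy estimates). Items are sorted
lexicographically before every seeded draw so determinism survives
filesystem enumeration order. Aggregation reports the mean per-episode
query accuracy, its standard deviation, and a normal-approximation 95%
confidence half-width. The ablation harness replays one materialized
episode stream under each fusion strategy, so arms differ only in the
strategy.

File names follow `Phylum_Family_Genus species` (first two underscores
delimit; the species part may contain spaces or further underscores; a
trailing `__<k>` duplicate index is ignored). The binomial species field
must contain a space.

## Synthetic fixtures

The generators emulate the statistical structure each stage assumes, not
plant imagery:

* **Embedding episodes.** Class means sit at the vertices of a regular
  simplex, so a single `separation` parameter is the exact distance
  between every pair of means (feasible for `n_way ≤ dim + 1`); items add
  isotropic Gaussian noise (`noise_sd`). Two independent noise draws
  stand in for the two backbones that see each image: the metric-branch
  vector and the encoder-side vector (`clip_noise_sd`, defaulting to
  `noise_sd`). The synthetic text encoder maps each class's compound
  prompt to `fidelity·mean + (1 − fidelity)·u` (u a random unit vector),
  renormalized — a continuous dial from a perfect text branch to pure
  noise.
* **Feature-map episodes.** Each class gets a channel covariance
  `I + s·GGᵀ/d` with G random; items are zero-mean spatial observations
  with that covariance. First-order (mean) pooling is uninformative by
  construction; only second-order statistics separate classes. At
  `s = 0` no classifier can beat chance; at `s = 5` BDC nearest-prototype
  5-way 5-shot accuracy is well above 60% in simulation.
* **Complementary streams** flip a fair coin per episode between an
  image-strong condition (separation 6, metric noise 1, encoder noise 4,
  fidelity 0) and a text-strong condition (metric noise 4, encoder noise
  1, fidelity 1). The weak branch is *confidently wrong* — a random but
  consistent text direction, or overlapping visual clusters — which is
  exactly the regime where fixed averaging fails and support-loss
  weighting helps.
* **Fidelity-response streams** fix a mid-difficulty regime (5-way 5-shot,
  separation 1.5, metric noise 1.0, encoder noise 0.8) chosen so neither
  branch's support loss saturates at 0 or ln N; there the text branch's
  fusion weight responds smoothly to `text_fidelity`.
* **Image sets** are a fixed geometric pattern (concentric rings by
  default) with per-image channel-intensity offsets and translations
  proportional to a jitter amplitude; amplitude 0 gives pixel-identical
  images.

What passing these fixtures does *not* show: robustness to real
photographic nuisance (backgrounds, occlusion, lighting), to non-Gaussian
embedding geometry, or to the calibration behavior of actual pretrained
encoders. The fixtures validate the algebra, the protocol and the
*mechanism* of adaptive fusion, not field performance.

## Variability statistics

Feature dissimilarities (Euclidean, cosine) use a pluggable embedder,
defaulting to flattened resized grayscale pixels so no pretrained network
is needed; "avg cosine" is reported as cosine *dissimilarity*
(1 − similarity) so that, like every other normalized statistic, higher
means more variable. SSIM and PSNR are computed on grayscale images
resized to a common side (default 128); PSNR of identical images is
capped at 100 dB. Per-image variance uses the resized grayscale pixels;
color standard deviation is the per-image standard deviation of channel
means on the original channels. Pairwise statistics run over all
unordered pairs up to a cap (default 200 per class, seeded subsample
beyond). Dataset vectors are unweighted means over classes;
normalization is min-max across datasets with SSIM/PSNR inverted and
constant columns mapped to 0.5; the overall score is the mean of the six
normalized entries and ranking is descending with ties broken by name.

## Numerical choices and problem sizes

Double-centering is validated to 1e-8 absolute (relative to the matrix
scale); oracle agreement of the BDC pipeline is tested at 1e-10.
Simulation-based checks use 100–2000 episodes per condition — enough that
binomial noise on a mean accuracy is a few tenths of a percentage point —
and every random draw flows through a seeded generator spawned from one
root seed; there is no global random state.

## Known limitations

* No feature extractor or vision–language encoder is bundled; real-data
  evaluation requires precomputed feature maps/embeddings (`.npy`) or
  user-supplied encoder callables.
* The confidence-based fusion arm is an interpretation (see above).
* The episodic *training* of a backbone is out of scope; evaluation is
  inference-time only.
* Dataset-level variability metrics average per-class vectors, weighting
  small and large classes equally; pooling all within-class pairs instead
  would weight by class size.
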