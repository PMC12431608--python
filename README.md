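# bdcc

Few-shot fine-grained plant classification with second-order
Brownian-distance-covariance (BDC) pooling, class-aware structured text
prompts, and per-task adaptive fusion of the two modalities.

Fine-grained plant recognition from a handful of labeled images is hard:
intra-class variability is large (season, organ, viewpoint) while
inter-class differences are subtle, and rare species contribute only a few
photographs each. This package implements an episodic N-way K-shot
framework that attacks the problem from two sides and fuses them:

* **Image metric branch.** A backbone feature map of shape `h × w × d` is
  pooled into a second-order representation: with observation vectors
  `x_1, …, x_m` (channels by default, so `m = d`), the pairwise Euclidean
  distance matrix `Â_kl = ‖x_k − x_l‖` is double-centered,

  `A_kl = Â_kl − (1/m) Σ_i Â_il − (1/m) Σ_j Â_kj + (1/m²) Σ_ij Â_ij`,

  giving the BDC matrix `A`. A class prototype `P_c` is the element-wise
  mean of its support samples' BDC matrices, and a query is scored by the
  trace similarity `ρ(A_query, P_c) = tr(A_queryᵀ P_c)`.
* **Text branch.** Each class carries five short structured descriptions
  stored in a JSON prompt library; they are concatenated with English
  commas into one compound sentence, encoded by a pluggable paired
  vision–language encoder, and queries are classified zero-shot by
  temperature-scaled softmax over cosine similarities.
* **Adaptive fusion.** Per episode, both branches predict the support set;
  with cross-entropy losses `L_img`, `L_txt`, raw weights `w = 1/(L + ε)`
  are normalized to `α_img + α_txt = 1` and smoothed toward the equal
  split, `α_final = (1 − β)·α + β·0.5` (default `β = 0.5`). Query
  probabilities are fused as `P = α_img P_img + α_txt P_txt`. Unimodal
  fallback, a fixed 0.5/0.5 arm and a confidence-based arm are included
  for ablations.

Also included: the six intra-class variability statistics (mean pairwise
Euclidean/cosine feature dissimilarity, image variance, SSIM, PSNR, color
standard deviation), their cross-dataset normalization with direction
correction, and an overall dissimilarity ranking for comparing datasets.

Because no public dataset or pretrained encoder is bundled, the package
ships seeded synthetic generators (`bdcc.synthetic`) that emulate every
input the pipeline needs: Gaussian embedding clusters with controllable
separation and text-encoder fidelity, feature maps whose class identity
lives only in channel covariance, jittered image sets, and templated
prompt libraries.

## Worked example

Evaluate the full pipeline on 200 synthetic "complementary" episodes —
5-way 5-shot tasks where a random half of the episodes have informative
visual features and a useless text encoder, and the other half the
reverse:

```
$ bdcc simulate --mode complementary --episodes 200 --seed 3 --k-shot 5
{
  "episodes": 200,
  "mean_accuracy": 0.9795000000000001,
  "ci95": 0.006706318778420017,
  "std": 0.04838860698999467
}

$ bdcc simulate --mode complementary --episodes 200 --seed 3 --k-shot 5 --fusion fixed
{
  "episodes": 200,
  "mean_accuracy": 0.59,
  "ci95": 0.056948747124014716,
  "std": 0.41090658440274186
}
```

Support-loss-driven smoothed fusion reaches 98% mean accuracy because each
episode leans on whichever modality its support set shows to be reliable;
naive equal-weight fusion is dragged to 59% by the confidently wrong weak
branch. `--fusion {fixed,confidence,support_loss,support_loss_smoothed}`
selects the strategy; `mean_accuracy` is the mean over per-episode query
accuracies and `ci95` its normal-approximation 95% half-width.

With no class signal at all the classifier sits at chance, as it should:

```
$ bdcc simulate --mode nosignal --episodes 100 --seed 2
{
  "episodes": 100,
  "mean_accuracy": 0.199,
  ...
}
```

Other entry points: `bdcc eval` runs the episodic protocol on a
class-structured image directory with precomputed `.npy` feature maps and
embeddings; `bdcc metrics DIR1 DIR2 ...` ranks image datasets by
intra-class variability; `bdcc prompt build/validate` works with prompt
libraries. The Python API mirrors the CLI (see `bdcc.episodes.evaluate`,
`bdcc.variability.dataset_variability_report`).

## Layout

```
src/bdcc/bdc.py          second-order pooling and trace-similarity classification
src/bdcc/prompts.py      prompt libraries and the zero-shot text branch
src/bdcc/fusion.py       support-loss weighting, smoothing, fused prediction
src/bdcc/episodes.py     dataset index, 3:1:1 class splits, episode sampling, evaluation
src/bdcc/branches.py     adapters from feature/embedding providers to branches
src/bdcc/variability.py  intra-class variability statistics and dataset ranking
src/bdcc/synthetic.py    seeded fixture generators
src/bdcc/cli.py          `bdcc` command-line interface
docs/methods.md          modeling assumptions, parameter choices, limitations
```
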