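# Methods

## Model

The classifier is a pre-norm Vision Transformer. An `H × W × C` image
(`H = W`, divisible by the patch side `P`) is cut into `N = HW/P²`
non-overlapping patches in row-major order; each flattened patch is
mapped by a learned linear layer to dimension `D`, a learned position
vector is added per grid position, and a learned `[CLS]` token is
prepended. Each of the `depth` encoder blocks applies layer norm,
multi-head self-attention (`heads` heads of width `D/heads`), a residual
connection, then layer norm, a GELU feed-forward of width `4D`, and a
second residual. A final layer norm feeds the `[CLS]` row into a linear
head with one logit per class.

### Adaptive token sampling

When a token schedule is configured, a sampling step sits between the
attention sub-layer and the feed-forward of every block (the position the
attention-output equations describe). The per-head attention matrices
are averaged and the significance of patch token `j` is the CLS-row
attention weight `A₁ⱼ` times the Euclidean norm of the token's
concatenated value row, normalized over all patch tokens; with one head
this is exactly the single-head score. The `[CLS]` token is excluded
from scoring and always kept.

Sampling inverts the score CDF: a variate `u` maps to the smallest patch
index `i` with `CDF_i ≥ u` (the generalized inverse — a step CDF has no
literal inverse to round, so we use the standard inverse-transform
convention). In *stochastic* mode the `K` variates are i.i.d. `U[0,1]`
draws from a per-model seeded generator; in *deterministic* mode they are
the midpoint quantiles `(i − 0.5)/K`, which makes evaluation and the
consistency branches reproducible. Duplicates are removed, so the
realized count `K′` is at most the budget `K`, and a budget `K ≥ N`
keeps every patch. Selection is a discrete gather: gradients flow
through the kept rows, not through the scores. A live `patch_map`
records which original grid positions survive each block; it backs the
top-token overlay (`visualize-tokens`) and the mask-overlap measurements.

If every score numerator is zero (possible with zero value rows) the
sampler falls back to uniform scores rather than failing, so training
survives pathological batches; the functional API raises a
`DegenerateScoresError` by default so callers can choose.

## Losses

* **Supervised**: one-vs-all binary cross-entropy with logits against
  one-hot targets, averaged over all elements, computed in the stable
  `max(x,0) − xy + log(1+e^{−|x|})` form. For two classes this is
  ordinary BCE; predictions are argmax over per-class sigmoids.
* **Pseudo-label MSE**: for unlabeled `x` and its augmented version `z`,
  the squared distance between probability vectors `‖F(x) − F(z)‖²`
  averaged over the batch. `F(x)` is detached (stop-gradient): the clean
  prediction acts as a fixed label, the standard consistency-training
  choice that prevents the trivial collapse of both branches.
* **Earth Mover's**: between the final-block token sequences of `x` and
  `z` ("final block" because late tokens are the ones closest to the
  classification head). For equal-length sequences the loss is the
  exact minimum over permutations of the summed squared-Euclidean costs,
  computed by optimal assignment on the pairwise cost matrix
  (`scipy.optimize.linear_sum_assignment`), which provably equals the
  permutation minimum; we divide by the sequence length so the magnitude
  is length-invariant. Consistency passes run in deterministic sampling
  mode so the two sequences almost always have equal length; when
  deduplication still yields different counts, the loss falls back to a
  rectangular partial matching (every token of the shorter sequence
  matched to a distinct token of the longer, normalized by the matched
  count).

The objective is the unweighted sum `L = L_CE + L_MSE + L_EM`
(configurable weights default to 1). Each step draws one labeled and one
equal-sized unlabeled batch (the unlabeled loader cycles); both branches
run through the same parameter set, and one Adam step is taken on `L`.
An empty unlabeled set degrades to supervised-only training with a
logged warning.

## Data protocol

Splits are class-stratified 7:1:2 train/val/test, then the training part
is split 8:2 into labeled/unlabeled; the hidden labels are retained only
for audit. Sizes use largest-remainder apportionment, which keeps every
split within one sample per class of its exact share (so 780 balanced
samples give 546/78/156, and the 546 give 436 labeled / 110 unlabeled).

Augmentations (all seeded): random crop to 87.5% of the side followed by
bilinear resize, horizontal and vertical flips, contrast scaling about
the image mean by `U[0.7, 1.3]`, and brightness jitter `U[−0.1, 0.1]` on
[0,1] intensities. One transform is drawn uniformly per unlabeled image.

Reference full-scale hyperparameters (the defaults of `TrainConfig` and
the config file): Adam with learning rate 2e-5, eps 1e-8, batch 64, 300
epochs, 256×256 inputs, 16-pixel patches (a 16×16 grid of 256 tokens),
six blocks with token schedule 256/128/64/32/16/8. Width `D = 128`,
4 heads and FFN ratio 4 are package choices — the reference setting
does not pin them.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
the appearance of real scans:

* **Ultrasound-like mode** (grayscale, three imbalanced classes,
  default 487/210/133): smoothed speckle background (base ≈ 0.35,
  noise level 0.08); "benign" adds a bright smooth ellipse (+0.30–0.45),
  "malignant" a dark spiculated blob (−0.20–0.32) whose radius is
  modulated by random harmonics, "normal" is background only. Lesion
  radii default to between 1/8 and 1/4 of the image side — large enough
  to cover several 16-pixel patches, small enough not to fill the frame —
  and centers stay one patch-width from the border so lesions always
  straddle patch boundaries.
* **Histopathology-like mode** (RGB, two imbalanced classes, default
  2480/5429): an irregular tissue region over an eosin-pink background;
  the class is carried by the region's texture frequency and
  chromaticity.

Every sample carries a binary mask of the informative region (empty for
"normal"), which is what token-localization checks score against. A
tiny profile (e.g. 60/30/20 at 64×64) is used throughout the test suite
so the whole suite runs in minutes. Generation is deterministic given
the seed.

What passing on this data does *not* show: robustness to the acquisition
artifacts, scale variation, annotation noise and subtle morphology of
real ultrasound or histopathology. The synthetic classes are nearly
linearly separable from intensity statistics (by design ≥ 80% for a
histogram classifier, but below 100%), so absolute accuracies here say
nothing about clinical performance — only the *relative* behavior of the
training variants is meaningful.

## Numerics and engineering

The model, its gradients and Adam are implemented on a small
reverse-mode autodiff engine over float64 numpy arrays (no deep-learning
framework is used). All primitive gradients are verified against central
finite differences in the test suite. Attention softmax subtracts the
row maximum; sigmoid clips at ±500; layer norm uses eps 1e-5;
initialization is N(0, 0.02²) with zero biases, seeded. Sampling
randomness comes from one generator per model instance, so runs are
reproducible given (seed, call order). Checkpoints are single `.npz`
files with a JSON config header.

## Desk-scale benchmark

`atsvit.benchmark` scales the study down to one CPU: 64×64 grayscale
images, 16-pixel patches (16 tokens), `D = 64`, three blocks with
schedule 16/8/4, two classes (125 benign / 125 malignant), 200 train /
50 test, Adam at 3e-4 with batch 16 for 30 epochs. The full-scale
learning rate (2e-5) is tuned for 300-epoch training and does not move
in this regime, so the benchmark uses a correspondingly larger step.
The final-epoch model is evaluated — the 200/50 protocol has no separate
validation set (train() still performs validation-F1 checkpoint
selection whenever a validation set is supplied). Five paired seeds
compare consistency training (160 labeled + 40 hidden) against
supervised-only training on the same 160 labeled images.

## Known limitations

* **Late-block attention does not localize at this scale.** After
  training the tiny model, the *first* block's significance scores
  concentrate strongly on lesion patches (on/off-lesion score ratios in
  the hundreds), confirming the scoring mechanism; but the CLS token
  absorbs the class signal in that first block, later blocks feel no
  pressure to re-attend to the lesion, and their scores stay near
  uniform. The last-block retained set is therefore close to random
  (mask overlap ≈ 0.3 on average, not a majority), and training longer
  does not change this. Emergent late-block saliency of the kind seen in
  deep, long-trained transformers should not be expected from a
  three-block model trained from scratch on an easily separable task.
* Per-image (not batched) forward passes: simple and exact for ragged
  token counts, at the cost of Python overhead; fine at desk scale.
* The consistency comparison is directional: with five seeds the paired
  F1 difference is small relative to seed noise, so only the ordering —
  not its magnitude — is informative.
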