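# Methods

## Problem and scope

The package grades individual grain kernels into three quality classes —
good, moldy, broken — from RGB photographs of kernels spread on a light
tray. Two sub-problems are solved separately: (i) isolating single-kernel
crops from a multi-kernel image, and (ii) classifying each crop. Because
no public corpus exists for this task, a synthetic generator with exact
ground truth stands in for photographic data everywhere the package
measures itself.

## Synthetic kernel model

A kernel is an anti-aliased ellipse (semi-axes `axes`, orientation
`angle`) rendered by 4×4 supersampling onto a light background
(intensity 235). Appearance follows the class definition:

* **good** — smooth convex ellipse, yellowish base colour
  (210, 172, 84) ± 6 per channel, multiplicative radial shading
  (1 → 0.82 towards the rim);
* **moldy** — the same outline with `blemish_count` (default 4–7)
  Gaussian-profile dark blotches (strength 0.7, radius 0.16–0.26 of the
  minor axis), lowering mean interior intensity;
* **broken** — a circular bite of radius `notch_fraction × major axis`,
  centred slightly inside the outline (depth factor 0.45·notch), cutting
  a concavity into the shape and lowering solidity (area / convex-hull
  area).

Additive Gaussian sensor noise (σ = 4 gray levels) is applied last so
thresholding is non-trivial. The declared centre always equals the
rendered mask's centroid (a second render pass corrects the shift a bite
introduces), so centroid recovery can be scored to sub-pixel accuracy.
Class statistics are enforced by test: over 100 kernels per class,
solidity(broken) < solidity(good) and intensity(moldy) < intensity(good),
each by more than 3 pooled standard deviations, and a linear model on
(mean intensity, solidity) separates the classes with ≥ 90% accuracy —
the floor any useful classifier must beat.

Per-item seeds derive from a master seed via a splitmix64-style mixer
(`fixtures.derive_seed`), so datasets are bit-reproducible and
parallel-safe. Trays place kernels by rejection sampling with a ≥ 2 px
mask gap; placement failure raises a capacity error.

What the generator does **not** emulate: touching or overlapping
kernels, specular highlights, shadows, camera distortion, husk debris,
and natural texture. Passing tests therefore demonstrate the pipeline's
correctness and the architecture's trainability on controlled data, not
field performance on photographs.

## Kernel isolation

Grayscale uses Rec.601 weights. Denoising is a Gaussian filter
(default σ = 1 px, kernel truncated at 3σ). Binarisation defaults to Otsu
with automatic polarity (the minority side of the threshold is taken as
foreground, since kernels occupy less than half a tray); a fixed
threshold is available. Contours come from connected-component labelling
with centroids from first image moments; components below a minimum area
(default 0.1% of the image) are treated as specks. Each kernel is cropped
by its minimum-area rotated rectangle (shapely's rotating-calipers
implementation), rectified to axis-aligned by bilinear resampling with
2 px padding. Crops are returned row-major by centroid.

## Augmentation, balancing, split

Six operators: random rotation (±180°, edge-padded bilinear), brightness
scaling (0.7–1.3), salt-and-pepper (per-pixel probability 0.02 by
default, half salt half pepper), additive Gaussian noise (σ = 10),
Gaussian blur (σ ∈ 0.5–1.5), and exact 180° rotation (array reversal, an
involution). Every operator is a pure function of (image, config, seed).
`balance_and_expand` retains all originals and adds augmented copies of
uniformly sampled source images until each class reaches the target
count, recording (source index, op, seed) so any synthetic image replays
exactly. The train/test split is stratified per class, performed once per
seed (4:1 by default), with per-class counts within one item of the
requested fraction.

## Classifier

The backbone is a Swin-T hierarchy truncated after three stages: patch
size 4, embedding 96, window 7, depths (2, 2, 4), heads (3, 6, 12),
MLP ratio 4, shifted windows with attention masking on alternate blocks,
relative position bias, and patch merging between stages. For 224-px
input the stage outputs are 56×56×96, 28×28×192 and 14×14×384. A
learnable absolute position embedding (σ = 0.1 init) is added after patch
embedding: the classifier's pooled features are spatial averages, and
concavity of a centred kernel is only expressible after pooling if token
features carry positional information; the option can be disabled
(`use_abs_pos_embed=False`).

Each stage output passes a pooling head — LayerNorm → Linear(Cx→384) →
GELU → global average pool — giving three 1×1×384 vectors, concatenated
into the fusion tensor F4 (1×3×384). The convolution block takes the mean
of the three pooled vectors (option `conv_input="f3"` uses stage 3
alone), reduces 384→128, replicates the vector over a 14×14 grid (all
interpolations of a 1×1 source coincide with replication), applies two
3×3 depthwise-separable convolutions (depthwise + pointwise, GELU after
each half; channels 128→256→256), global-average-pools, expands 256→1152
and reshapes to F5 (1×3×384). No normalisation layer is used inside this
block: its input is a single vector per sample, so batch statistics are
nearly degenerate across a batch — a batch-coupled norm there amplified
batch noise during training and made inference depend on batch
composition, while a per-position LayerNorm erased the per-sample
magnitude signal. F6 = F4 + F5. The feature-attention layer computes one
scalar logit per stage slot with a shared Linear(384→1), softmax-normalises
over the three slots (weights are non-negative and sum to 1), and rescales
each slot; a per-channel variant exists behind a flag, default off. The
classifier flattens F7 (3·384 = 1152) into a linear layer and softmax.

Ablation variants share all code: `baseline` (backbone + stage-3 pool
head + linear head), `tf` (+ fusion and convolution block), `tf_fa`
(+ feature attention, the default). An untruncated 4-stage Swin-T with a
plain pooled head (`build_swin_baseline`) serves as the parameter-count
reference: 9.6 M vs 27.8 M parameters.

## Numerical substrate

The model runs on a reverse-mode autodiff engine over numpy float32
arrays (`grainqc.nn`), implementing exactly the operations the
architecture needs (broadcast arithmetic, batched matmul, reshapes/rolls,
softmax, exact-erf GELU, LayerNorm, a 3×3 depthwise convolution, gather
for position-bias tables, cross-entropy). Every operator's gradient is
checked against central finite differences in the test suite. Weights use
Glorot-uniform initialisation — at the short schedules used here (tens of
optimizer steps) the conventional 0.02 truncated-normal transformer
initialisation converges far too slowly. Attention-projection/MLP output
layers are not special-cased.

## Training

AdamW (decoupled weight decay 0.05 on matrices only) with cross-entropy.
The full-scale defaults follow the reference protocol: 60 epochs,
learning rate 1e-4, batch 32, constant schedule. The CPU-scale preset
(`ModelConfig.tiny`: 64-px input, embed 24, depths (2,2,2), window 4,
fusion 96) pairs with `tiny_train_config`: 5 epochs, learning rate 1e-3,
batch 16, betas (0.9, 0.95) — a short from-scratch schedule favours a
larger step and faster-adapting second moment. Training is reproducible
per (model seed, config seed) on CPU; the best-validation checkpoint and
a per-epoch CSV history are written when an output directory is given.
Non-finite loss aborts with diagnostics.

### Smoke protocol

`protocols.smoke_training` generates 300 kernels (100 per class),
balance-augments the training set to 300 per class — augmentation before
training is the package's standard pipeline, mirroring how such datasets
are prepared in practice — trains the tiny preset for 5 epochs on three
seeds, and scores accuracy on the 300 original kernels. Typical result:
two of three seeds above 0.90 (≈ 0.90/0.92/0.88 at the frozen test
seeds). The residual seed-dependence is expected: the moldy class is
linearly visible to pooled features (intensity), while the broken class
requires learning rotation-invariant concavity detection from ~200
examples in ~100 optimizer steps, and some initialisations escape that
plateau later than others.

`protocols.ablation_accuracies` runs the three variants at a smaller
scale (60 kernels per class, 4:1 split, training set augmented to 150 per
class, 4 epochs, 3 seeds) and reports mean test accuracy side by side.
At this scale the ordering baseline < +fusion holds; the attention term
is within noise of +fusion, so the comparison is reported, not asserted.

## Numerical and degenerate-input choices

* Otsu on a constant image raises (degenerate histogram); a blank tray
  short-circuits to an empty crop list before thresholding.
* Metric zero-divisions (class never predicted / zero support) report 0
  and flag the class; macro averages stay finite. F1 with P = R = 0 is 0.
* The paired t-test uses the n−1 sample standard deviation, two-sided
  p-values, and raises on zero-variance differences instead of returning
  ±∞. Positive t means the first series outperforms the second.
* Softmax is computed with max-subtraction; attention masks use −100
  additive logits; weights sum to 1 within 1e-6.
* Crops whose rectangle exceeds the image are clipped with a warning.
* Coordinates are pixel-centred, origin top-left, x = column; boxes are
  (x, y, w, h, angle°).

## Problem sizes used in the shipped measurements

Shape trace: one 224-px forward pass. Segmentation recovery: 20 trays of
8–16 kernels on 320×320 canvases. Metric/t-test oracles: 50 random
matrices / 100 random series against scipy and sklearn references. Smoke
training: 300 kernels, 3 seeds, 5 epochs. Ablation: 36 test kernels per
variant, 3 seeds, 4 epochs. These sizes were chosen as the package's own
single-CPU defaults.

## Known limitations

* Synthetic imagery only; no claim transfers to photographs without
  retraining and re-validation.
* Touching/overlapping kernels are out of scope for the segmenter (no
  watershed separation).
* The 224-px model trains only at impractical speed on this numpy
  engine; full-scale results (60-epoch schedule) are configuration, not
  shipped measurements.
* Stochastic-depth (drop_path) is implemented but defaults to 0 and is
  untested at scale.
* AutoAugment-style policy search is intentionally absent; the six
  explicit operators above are the augmentation vocabulary.
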