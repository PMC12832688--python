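# Methods

## Problem and model

PneuNet is a binary classifier for frontal chest radiographs: given a
grayscale image, it outputs the probability that the lungs show
pneumonia.  The design goal is a *lightweight* network — a few hundred
thousand trainable parameters — that still captures the two things that
matter for consolidation detection: multi-scale spatial context and
selective attention to the lung fields.

The graph, in order:

1. **Stem**: a 3×3 convolution with 32 filters (ReLU, batch norm).
2. **Depthwise-separable fusion**: three sequential blocks of
   depthwise 3×3 + pointwise 1×1 convolutions (32 channels each, batch
   norm and ReLU after every convolution, dropout after each block).
   The stem output and the three block outputs are concatenated into a
   128-channel tensor, so the fusion tensor mixes four depths of
   representation.  A depthwise-separable pair costs
   k²·C_in + C_in·C_out multiply-accumulates per position against
   k²·C_in·C_out for the standard convolution it replaces — for the
   32→32 blocks, 1,312 versus 9,216.
3. **Squeeze-and-excitation**: channels are pooled to their spatial
   means s_c = (1/HW)·Σ_ij x_ijc, passed through a Dense(8)→ReLU→
   Dense(128)→sigmoid bottleneck, and the resulting gates in (0,1)
   rescale the channels.
4. **Downsample**: depthwise 3×3 with stride 2 (112×112 at full
   resolution).
5. **ASPP**: four parallel branches — a 1×1 convolution and three 3×3
   atrous convolutions with dilation rates 1, 3 and 6 — each to 32
   channels, concatenated and fused by a 1×1 convolution back to 128
   channels.  The dilated convolution y[i] = Σ_k x[i + r·k]·w[k]
   enlarges the receptive field without extra parameters; rates
   {1, 3, 6} cover opacity scales from focal to lobar.
6. **Learnable pooling**: a two-stage 1×1-convolution head
   (128→128→1, biases) followed by a sigmoid produces a spatial
   attention map A ∈ (0,1)^{H×W}; the feature vector is the
   attention-weighted sum F_pooled = Σ (F × A).  A `gap` ablation mode
   replaces this with plain global average pooling.
7. **Head**: dropout, then a single dense sigmoid unit.

Per-layer trainable-parameter counts of the default build (the audited
values): stem 896; SE block 2,184; stride-2 depthwise 1,280; ASPP 1×1
branch 4,128; each atrous branch 36,896; fuse 16,512; learnable pooling
16,641 (= 128·128+128 for the hidden stage plus 128+1 for the scoring
stage); classifier 129.

### Design choices where the design was open

* **Learnable-pooling head**: a single 1×1 convolution to a scalar has
  129 parameters; the two-stage 128→128→1 head has 16,641.  We use the
  two-stage head, which subsumes the single-stage design as its second
  stage.  No nonlinearity sits between the two stages; the sigmoid
  produces the map.
* **Pooling normalization**: the pooled vector is the attention-weighted
  *sum*, not a weighted mean — no division by ΣA.  The layer divides by
  the constant H·W purely for numerical conditioning: the constant is
  absorbed by the downstream dense head, so the function class is
  unchanged, but without it the pooled features start at magnitude
  ~HW/2 and Adam's uniform step size responds by collapsing the
  attention gate toward zero instead of training the trunk.  An
  explicitly ΣA-normalized variant is intentionally not the default.
* **Branch topology**: "three repeated depthwise blocks" and "four
  concatenated branches" are reconciled by concatenating the stem
  output with the three (sequential) block outputs.
* **Input channels**: images are grayscale but the stem expects three
  channels (its 896 = 3²·3·32+32 parameter count forces C_in = 3), so
  the grayscale plane is replicated.
* **SE bottleneck activation**: ReLU after the squeeze dense layer
  (standard SE design).
* **Batch-norm placement**: conv → BN → ReLU after every convolution.
  The attention-pooling head carries no batch norm (it is a scoring
  head, not a feature extractor, and extra BN parameters would break
  the 16,641 count).
* **Initialization**: variance-scaling (He) fan-in normal for all
  kernels, zero biases, fixed seed; the classifier weight vector is
  zero-initialized so the first forward pass outputs probability 0.5
  regardless of the pooled-feature scale (a fan-in-scaled head starts
  with |logit| in the hundreds and a saturated sigmoid).

## Training protocol

Adam with β₁ = 0.9, β₂ = 0.999, fixed learning rate 0.001, batch size
32, binary cross-entropy (probabilities clamped to [1e−7, 1−1e−7]), L2
weight decay λ = 0.001 applied to convolution and dense kernels only
(biases and batch-norm parameters exempt), dropout rate 0.3 after each
depthwise-separable block and before the classifier (training mode
only), up to 50 epochs with early stopping at patience 7.  The tracked
loss — training and validation — includes the L2 term.

**Early stopping semantics**: "improvement" is a strict decrease of
validation loss below the running best (min-delta 0); the patience
counter restarts at each improvement, so a run whose best epoch is b
halts at epoch b + patience (e.g. best 42 → halt 49 with patience 7).
The best epoch is the earliest minimum, and the checkpoint captured
there — weights plus batch-norm statistics — is what evaluation uses.

**Precise batch-norm refresh**: desk-scale runs take ~10 optimizer
steps per epoch, far too few for exponential moving averages of the
batch-norm statistics to track the weights; stale statistics compress
eval-mode logits toward a constant and make validation loss
meaningless.  After each epoch the trainer therefore recomputes the
statistics exactly (pooled over up to 8 training batches forward-passed
under the current weights, dropout off) before validating.  This is
deterministic and standard practice for small-step regimes.

**Moving-average momentum** is 0.9 (only relevant outside the
recalibrated path).

## Synthetic radiographs

The generator renders simplified frontal chest phantoms so the whole
pipeline is testable without any external download: a bright thorax
background (intensity 200 on the 8-bit scale), two darker elliptical
lung fields (−80), and per-image Gaussian pixel noise (σ = 8).
Pneumonia phantoms add 1–3 blurred bright opacities (intensity +45,
radii 12–30 px at the 224-px reference scale, Gaussian blur σ = 4)
whose support is confined to the lung-field mask; the ground-truth
opacity mask is retained per image for localization tests.  Radii are
deliberately consolidation-scale (segmental, ~1–3 cm equivalent), not
nodule-scale, matching the radiological appearance of pneumonia.  The
base phantom is deterministic; all per-image variation comes from the
seeded noise field and opacity placement, so a spec with
`noise_sd = 0, opacity_intensity = 0` renders both classes
pixel-identical (a useful null test).

Because the base phantom is fixed, mean lung-field brightness alone
separates the classes; a classifier can therefore succeed with a global
shortcut rather than genuinely localizing opacities.  Grad-CAM
localization quality on phantom-trained models consequently varies
between training runs — the fixed-protocol run used by the test suite
attends to the opacities, but other initializations can solve the task
with diffuse lung attention.  Real radiographs, with per-image exposure
and anatomy variation, do not admit this shortcut.

What the phantoms do **not** emulate: rib and mediastinal structure,
patient pose and exposure variation, pleural effusions, devices and
markers, label noise, and the class imbalance of clinical datasets.
Passing the desk-scale tests therefore demonstrates that the
implementation can learn and localize the kind of signal the
architecture targets; it says nothing about performance on real
radiographs, for which the directory-ingestion path exists.

## Splitting

The stratified splitter allocates per class by largest-remainder
rounding, sequentially per split, so class proportions in every set
deviate from exact proportionality by less than one item and set sizes
are exact.  Ratio mode (default 0.8/0.1/0.1, seed 42) covers the
protocol; counts mode reproduces printed set sizes verbatim (e.g.
4,646/586/624 of 5,856 — note exact 80% of 5,856 would be 4,684.8, so
printed sizes and exact ratios cannot both hold).

## Evaluation statistics

Pneumonia is the positive class: TP = pneumonia called pneumonia,
FN = pneumonia called normal, FP = normal called pneumonia, TN = normal
called normal; a score ≥ 0.5 predicts pneumonia (threshold
configurable).  Precision/recall/F1 are reported per class with macro
(unweighted) and support-weighted averages; zero-denominator scores are
0 and flagged; display rounding is half-up to two decimals.  The ROC
curve is built over all distinct score thresholds with ties grouped,
and AUC is its trapezoidal area (equal to the Mann–Whitney pair-count
estimator with ties counted ½).  McNemar's test on discordant counts b
and c uses χ² = (b−c)²/(b+c), or (|b−c|−1)²/(b+c) with the continuity
correction (numerator floored at zero; the default), referred to χ²
with 1 degree of freedom.

## Grad-CAM

Saliency for the pneumonia output: channel weights are the spatial mean
of ∂p/∂A_l at the target convolutional stage (default: the ASPP fuse
output), the map is the ReLU of the weighted channel sum, min-max
normalized to [0,1] and bilinearly upsampled to input resolution.  An
identically-zero pre-normalization map stays zero and is flagged rather
than divided by zero.  Only the positive-class map is produced (the
model has a single sigmoid output).

## Problem sizes and numerical choices

The implementation is pure numpy (forward and hand-derived backward
passes, float32 activations); no GPU framework is involved, so problem
sizes are chosen for a single CPU:

* Parameter and shape audits run the full 224×224×3 configuration
  (counts are independent of spatial size).
* End-to-end desk-scale runs train on the default synthetic dataset
  (200 images/class) resized to 48×48, batch 32, ≤10 epochs.  At this
  scale the separable-versus-standard cost ordering, the training
  dynamics, and the attention behaviour are all exercised; wall-clock
  is a few minutes.
* Dilated-convolution equivalence is checked to 1e−6 (float64 oracle),
  AUC against pair counting to 1e−9, checkpoint round-trips bit-exactly.
* Degenerate inputs: empty images, single-class AUC, all-zero confusion
  matrices, zero discordant pairs, and too-short dilated-convolution
  signals all raise explicit errors.

## Known limitations

* The printed "~1.84 M total parameters" of the source architecture
  table is inconsistent with the sum of its own per-layer counts
  (~0.17 M); the per-layer counts are treated as authoritative and the
  total is reported but not asserted against.
* FLOPs totals and inference latency are convention- and
  hardware-dependent and are out of scope; the complexity report gives
  per-position multiply-accumulate counts instead.
* Training at 48×48 with ~100 optimizer steps is a scaled-down
  protocol; headline accuracies on the public Kaggle dataset are not
  reproduced here (the directory-ingestion mode supports such runs when
  the data and compute are available).
* McNemar comparisons against the published baseline networks require
  their prediction files; the harness accepts such files but ships no
  baselines.
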