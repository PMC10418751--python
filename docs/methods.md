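# Methods

This note records what the package computes, the parameter defaults and the
reasoning behind them, what the synthetic data generator does and does not
emulate, and the numerical choices made in the implementation.  It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
recompute.

## Model

### Backbone (`graindet.backbone`)

An 8-stage compound-scaled convolutional network.  Stage 1 is a plain 3×3
stride-2 convolution; stages 2–8 are mobile inverted-bottleneck (MBConv)
blocks: an optional 1×1 expansion (factor 6 everywhere except stage 2, which
uses factor 1 and therefore no expansion convolution), a depthwise 3×3 or 5×5
convolution, a squeeze-and-excitation gate, and a 1×1 projection.  A residual
shortcut with stochastic depth applies exactly when a block's input and
output shapes match (stride 1, equal channel counts).

Base stage table (layers, kernel, stride, output channels):

| Stage | Op | Expansion | Kernel | Layers | Stride | Out channels |
| --- | --- | --- | --- | --- | --- | --- |
| 1 | conv | – | 3 | 1 | 2 | 64 |
| 2 | MBConv | 1 | 3 | 4 | 1 | 32 |
| 3 | MBConv | 6 | 3 | 7 | 2 | 48 |
| 4 | MBConv | 6 | 5 | 7 | 2 | 80 |
| 5 | MBConv | 6 | 3 | 10 | 2 | 160 |
| 6 | MBConv | 6 | 5 | 10 | 1 | 224 |
| 7 | MBConv | 6 | 5 | 13 | 2 | 384 |
| 8 | MBConv | 6 | 3 | 4 | 1 | 640 |

Only the stage *entry* resolutions/channels down to stage 8 are externally
specified by the architecture; the stage-8 output width of 640 is this
implementation's choice, continuing the table's widening progression.
Compound scaling multiplies widths (rounded, minimum 1) and depths (ceiling)
by configurable coefficients; `BackboneConfig.tiny()` (width 1/8, one layer
per stage, 152 px input) is the desk-scale variant used throughout the tests.

Numerical details:

- "Same" padding uses ceiling division, so a stride-2 chain maps
  600 → 300 → 150 → 75 → 38 → 19; padding is asymmetric when needed.
- Squeeze-and-excitation bottleneck width is the block *input* width divided
  by 4 (minimum 1), with Swish then sigmoid; the gate multiplies the
  post-depthwise activations.
- Batch normalization uses momentum 0.99 and epsilon 1e-3.
- Stochastic-depth survival probability defaults to 0.8 on shortcut blocks.
- Activations are Swish throughout the backbone.
- An ImageNet-pretrained weight-loading hook exists
  (`Backbone.load_weights`); desk-scale runs use random initialization since
  pretraining is out of scope here.

### Cross-stage integration (`graindet.integration`)

Feature maps are tapped at stage outputs 4, 6 and 8 (75×75, 38×38 and 19×19
for a 600 px input).  The deepest map passes through a 3×3 convolution and a
1×1 projection; each shallower tap passes through a 1×1 lateral.  Exactly two
bilinear upsampling steps (half-pixel alignment) bring the deep path to each
shallower resolution, where the default fusion is elementwise sum (a concat
mode with a 1×1 merge convolution is available).  The result is a stride-8
map with 256 channels by default — 75×75×256 at full scale — on which both
the proposal network and ROI pooling operate.  A 256-channel fused map keeps
the proposal head small while preserving tiny-object resolution; the tiny
configuration uses 48 channels.

### Anchor-based region proposal network (`graindet.arpn`)

- **Anchors.**  9 per cell: area scales {64², 128², 256²} px² × height:width
  ratios {1:1, 1:2, 2:1}, centered at ((j+0.5)·stride, (i+0.5)·stride).  The
  smallest scale matches the tiny-object regime; 75·75·9 = 50,625 anchors
  per 600×600 image.
- **Labeling.**  IoU > 0.7 with any ground-truth box → positive; IoU < 0.3
  with all → negative; otherwise ignored.  Additionally, for each
  ground-truth box the in-bounds anchor with the highest IoU is promoted to
  positive so every object gets at least one anchor.  Anchors crossing the
  image boundary are excluded from training (and from the argmax promotion).
- **Sampling.**  Mini-batches of 256 anchors with at most 128 positives; any
  positive deficit is filled with negatives.
- **Loss.**  (Σ L_cls + Σ c*·L_reg) / 256, where L_cls is −ln of the
  probability assigned to the true objectness label and L_reg is smooth-L1
  over the four box-coding residuals, active for positives only.
- **Box coding.**  r = ((x*−x)/w, (y*−y)/h, ln(w*/w), ln(h*/h)) relative to
  the anchor; decoding clamps the log-size offsets to ±4 to keep exp finite.
- **Proposals.**  Decoded boxes are clipped, degenerate ones dropped, the
  top-K by score kept before NMS at IoU 0.7, and the top-K after
  (2000/2000 in training, 1000/300 at test time).

### Candidate-box head (`graindet.roihead`)

ROI features come from quantized max pooling: the ROI is projected onto the
stride-8 map, cell boundaries are quantized (floor/ceil), and each output
cell takes the maximum over its feature-map cells (7×7 output by default).
The head is two 1024-wide fully connected layers with ReLU, a (k+1)-way
softmax classifier and a 4·(k+1)-output regressor.  The per-ROI loss is
−ln q_v + α·[v>0]·Σ smooth-L1 with α = 1: the Iverson bracket removes the
location term for background ROIs, and only the regression slice of the true
class enters the loss.

Training ROIs are assigned by IoU: ≥ 0.5 foreground, [0.1, 0.5) background,
sampled to 128 per image with a 25% foreground fraction; ground-truth boxes
are added to the proposal pool by default (`add_gt_to_proposals`) so early
training always sees foreground.  Inference keeps detections with score
≥ 0.05, applies class-wise NMS at IoU 0.3 and returns at most 100 per image.

### Metrics (`graindet.metrics`)

COCO-style evaluation: greedy matching per IoU threshold (0.50:0.05:0.95) in
descending score order, 101-point interpolated average precision, average
recall at 10 and 100 detections per image, and a small-object partition at
area < 64² px² with ignore semantics — out-of-range ground truth can absorb
detections without penalty, and unmatched out-of-range detections are not
counted as false positives.  Undefined values (no ground truth in a
partition) are NaN internally and `null` in JSON.  The implementation is
cross-checked in the tests against an independent brute-force evaluator.

### Training (`graindet.trainer`)

Four-phase alternating optimization: (1) train the proposal network (its own
backbone copy) end-to-end; (2) train a freshly initialized detector on the
phase-1 proposals; (3) copy the phase-1 proposal head into the detector
network, freeze the shared convolutions (batch-norm in inference mode), and
fine-tune the proposal head; (4) fine-tune the detection head, producing one
unified network.  Task-specific layers initialize from N(0, 0.01²) with zero
biases; the backbone keeps its own initialization.  Updates use SGD with
momentum 0.9.

Defaults chosen as assumptions (the reference procedure leaves them open):
learning rate 0.01 (divided by 10 for the fine-tuning phases), per-phase
epochs (2, 2, 1, 1), both configurable.  Training writes JSON-lines logs
(per-phase and per-epoch records, evaluation), per-phase checkpoints
(`.npz` weights + `.json` metadata) and supports resuming from any completed
phase; resumed runs reproduce the original weights bitwise because each
phase re-seeds its generator from the run seed and phase index.  A
single-phase approximate-joint mode (`train_joint`) is provided as a
convenience; it is not the reference schedule.

## Synthetic data (`graindet.synthgrain`)

The generator emulates the statistics that matter to a tiny-object detector
on a grain-cleaning stream:

- textured soil-toned background (Gaussian-filtered noise plus a directional
  brightness gradient),
- 3–10 objects per 600×600 scene from seven classes (kernel, damaged,
  rotten, cob, husk, weed, stone), rendered as shaded ellipses or irregular
  polygons with per-class color, aspect and size ranges,
- a configurable tiny-object share (`tiny_fraction`, default 0.5): tiny
  objects sample footprint areas in [22², 62²] px², large ones in [68²,
  class maximum], keeping a margin around the 64² boundary,
- pairwise bounding-box IoU capped at 0.3, tight boxes from the rendered
  pixels, area recorded as width × height,
- augmentations (90°-multiple rotations, mirrors, brightness/contrast,
  Gaussian noise σ = 10, salt-and-pepper density 0.02) with boxes
  transformed consistently with the pixels,
- a 3:1 train/test split at the *base-scene* level, so augmented variants
  never leak across the split; output is COCO JSON plus a YAML manifest of
  all generation parameters.

It does **not** emulate: perspective or lens distortion, occlusion or
touching objects beyond the IoU cap, motion blur, specular reflections,
realistic kernel texture, class imbalance of real streams, or illumination
color shifts.  Results on this data characterize the pipeline, not
field performance.

## Numerical choices

- All tensors are float32; the autograd engine (`graindet.nn`) is a
  tape-based reverse-mode implementation over NumPy.  Convolutions use
  im2col matrix multiplication (with tensordot for 1×1 and a strided-view
  einsum for depthwise); bilinear interpolation is separable matrix form.
- Smooth-L1 uses 0.5x² for |x| < 1 and |x| − 0.5 otherwise (continuous with
  continuous first derivative at |x| = 1).
- NMS suppresses at strictly greater than the threshold and breaks score
  ties by lower index.
- ROI max pooling falls back to the nearest valid cell when quantization
  produces an empty cell, keeping gradients defined for thin ROIs.
- Bilinear upsampling uses half-pixel (align-corners-false) sampling.
- Deterministic seeding throughout: dataset generation, weight
  initialization, anchor/ROI sampling and the training loop all derive from
  explicit integer seeds.

## Desk-scale configurations

The `tiny()` configurations (1/8-width backbone, 152 px inputs, 48-channel
fusion, 64 ROIs, 128-wide head) exist so that the full pipeline — including
the four-phase schedule — runs end to end in minutes on one CPU.  They are
this package's own choice of problem size for testing and demonstration, not
a claim about the full-scale configuration's accuracy.

## Limitations

- No GPU or multi-device support; full-scale (600 px, full-width backbone)
  training is impractical on one CPU — only the forward pass is exercised.
- No ImageNet pretraining is shipped; the loading hook accepts external
  weights but none are bundled.
- The COCO evaluator implements the bounding-box task only (no crowd
  regions, segmentation or keypoints).
- The synthetic generator's realism limits above apply to every empirical
  number produced by the tests and the acceptance script.
- Batch size is one image; batch normalization therefore normalizes over
  spatial positions of a single image during training.
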