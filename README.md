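# graindet

Two-stage detection of maize kernels and impurities in cleaned grain streams,
with an emphasis on **tiny objects** (area below 64×64 px in a 600×600 image).
The package implements the full pipeline in pure NumPy — a compound-scaled
convolutional backbone, cross-stage feature integration, an anchor-based
region proposal network, a candidate-box classification/regression head,
COCO-style evaluation, a synthetic scene generator, and a four-phase
alternating training procedure — together with a command-line interface.

## The problem

Machine-harvested maize arrives at the cleaning stage mixed with impurities:
damaged and rotten kernels, cob fragments, husks, weeds and stones.  Grading
the stream from overhead imagery is a small-object detection problem — most
items occupy well under 1% of the frame — and generic detectors lose exactly
these objects because deep feature maps are too coarse to retain them.  The
model here addresses that with two choices:

1. **Cross-stage integration.**  Feature maps are tapped from three depths of
   the backbone (strides 8, 16 and 32 for a 600 px input), the deeper maps are
   projected and bilinearly upsampled, and all three are fused into a single
   stride-8, 256-channel map (75×75 for a 600 px input).  The proposal and
   detection stages both operate on this high-resolution fused map.
2. **Anchor design for small objects.**  The proposal network places 9
   anchors per fused-map cell — area scales {64², 128², 256²} px² crossed
   with height:width ratios {1:1, 1:2, 2:1} — giving 75·75·9 = 50,625
   candidates per 600×600 image.

The detector is a classic two-stage design: the proposal network scores and
refines anchors, top proposals are pooled to a fixed grid by quantized max
pooling, and a head of two 1024-wide fully connected layers outputs a
(k+1)-way softmax over classes plus per-class box regressions.  Training
follows a four-phase alternating schedule: (1) train the proposal network
end-to-end, (2) train a fresh detector on its proposals, (3) freeze the
shared convolutions and fine-tune the proposal head, (4) fine-tune the
detection head, yielding one unified network.

The backbone is an 8-stage compound-scaled architecture built from
mobile inverted-bottleneck blocks with squeeze-and-excitation, Swish
activations, batch normalization and stochastic depth.  At full scale a
600×600×3 input traces the stage entries 300×300×64 → 300×300×32 →
150×150×48 → 75×75×80 → 38×38×160 → 38×38×224 → 19×19×384 and produces a
19×19×640 output.

Because real grain-stream imagery is not redistributable, the package ships a
synthetic scene generator (`graindet.synthgrain`) that renders textured
backgrounds with ellipse/polygon objects for the seven classes, a
configurable tiny-object share, bounded pairwise overlap, tight COCO-style
boxes, and an augmentation suite (rotations, mirrors, brightness/contrast,
Gaussian and salt-and-pepper noise) applied with a leak-free 3:1
base-scene-level train/test split.

Everything — including convolution, batch normalization, bilinear
interpolation, ROI max pooling and reverse-mode automatic differentiation —
is implemented on top of NumPy (`graindet.nn`), so the package has no
deep-learning framework dependency and runs on a single CPU.

## Worked example

Desk-scale end-to-end run (1/8-width backbone, 152 px inputs, one object
class).  This takes about three minutes on one CPU:

```python
from graindet.synthgrain import SceneSpec, build_dataset
from graindet.trainer import TrainConfig, train_alternating

spec = SceneSpec(image_size=152, class_list=("kernel",),
                 objects_per_image=(2, 5), tiny_fraction=0.0)
paths = build_dataset("scratch/blobs", n_base=133, spec=spec, seed=7)
checkpoint, report = train_alternating(paths, TrainConfig.smoke(seed=1))
print({k: round(v, 4) for k, v in report.to_dict().items()
       if k in ("AP", "AP50", "AR10", "AR100")})
```

Output (deterministic for these seeds):

```
{'AP': 0.4735, 'AP50': 0.9503, 'AR10': 0.5402, 'AR100': 0.5402}
```

Structural quantities are cheap to verify interactively:

```python
import numpy as np
from graindet.arpn import AnchorGridSpec, generate_anchors
from graindet.backbone import BackboneConfig, build_backbone, forward_backbone

print(len(generate_anchors(AnchorGridSpec())))      # 50625

bb = build_backbone(BackboneConfig(), seed=0)       # full-scale backbone
feats = forward_backbone(bb, np.zeros((600, 600, 3), dtype=np.float32))
print([feats.entries[s].shape for s in range(1, 9)])
# [(600, 600, 3), (300, 300, 64), (300, 300, 32), (150, 150, 48),
#  (75, 75, 80), (38, 38, 160), (38, 38, 224), (19, 19, 384)]
```

The same workflow is available from the command line:

```bash
graindet synth --out scratch/data --n-base 32 --image-size 152 --seed 0
graindet train --dataset scratch/data --tiny --classes 7 --seed 0 --out scratch/run
graindet eval  --checkpoint scratch/run/checkpoints/phase4 --dataset-split scratch/data/test --tiny --classes 7
graindet detect --image scratch/data/test/images/<scene>.png \
                --checkpoint scratch/run/checkpoints/phase4 --tiny --classes 7
```

## Layout

| Module | Contents |
| --- | --- |
| `graindet.nn` | NumPy autograd, conv / batch-norm / linear layers, bilinear interpolation, ROI max pooling, SGD |
| `graindet.backbone` | compound-scaled MBConv backbone with squeeze-and-excitation |
| `graindet.integration` | cross-stage feature fusion to a stride-8 map |
| `graindet.arpn` | anchors, labeling, sampling, proposal head, proposal generation |
| `graindet.roihead` | ROI pooling, detection head, losses, post-processing |
| `graindet.metrics` | COCO-style AP/AR evaluation with a small-object partition |
| `graindet.synthgrain` | synthetic scene generator, augmentations, dataset assembly |
| `graindet.trainer` | detector assembly, four-phase alternating training, checkpoints |
| `graindet.cli` | `graindet synth / train / eval / detect` |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
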