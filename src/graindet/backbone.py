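"""EfficientNet-style feature learning network for 600×600 grain images.

Eight convolution stages: a plain 3×3 stem followed by seven stages of
repeated mobile inverted-bottleneck (MBConv) blocks with squeeze-excitation.
The default configuration is the B7-scale variant whose per-stage input
resolutions, widths, depths, kernels and strides are::

    stage  op            input (H*W*C)   layers  first stride
    1      3x3 conv      600*600*3       1       2
    2      MBConv1, k3   300*300*64      4       1
    3      MBConv6, k3   300*300*32      7       2
    4      MBConv6, k5   150*150*48      7       2
    5      MBConv6, k3   75*75*80        10      2
    6      MBConv6, k5   38*38*160       10      1
    7      MBConv6, k5   38*38*224       13      2
    8      MBConv6, k3   19*19*384       4       1

Spatial downsampling uses "same" padding with ceiling division, so the odd
sizes chain correctly (75 → 38 → 19).  Stage 8 produces 640 channels — the
width that follows from compound-scaling the baseline's final 320-channel
stage, doubled like every other stage width in the table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import BatchNorm2d, Conv2d, Linear, Module, Tensor

logger = logging.getLogger("graindet")


class ConfigurationError(ValueError):
    """Raised when a network configuration violates its invariants."""


@dataclass
class StageSpec:
    """One row of the stage table (resolutions are stage *inputs*)."""

    index: int
    op_kind: str               # "plain_conv" | "mbconv"
    expansion: int             # 1 or 6 (1 only for stage 2)
    kernel: int                # 3 or 5
    in_resolution: tuple[int, int, int]   # (H, W, C)
    layers: int
    first_stride: int
    out_channels: int


#: (op_kind, expansion, kernel, in_C, layers, first_stride, out_C) per stage,
#: for a 600 px input at multipliers (1.0, 1.0)
_BASE_STAGES = [
    ("plain_conv", 1, 3, 3, 1, 2, 64),
    ("mbconv", 1, 3, 64, 4, 1, 32),
    ("mbconv", 6, 3, 32, 7, 2, 48),
    ("mbconv", 6, 5, 48, 7, 2, 80),
    ("mbconv", 6, 3, 80, 10, 2, 160),
    ("mbconv", 6, 5, 160, 10, 1, 224),
    ("mbconv", 6, 5, 224, 13, 2, 384),
    ("mbconv", 6, 3, 384, 4, 1, 640),
]


@dataclass
class BackboneConfig:
    """Compound-scaling knobs for the feature learning network.

    The default (1.0, 1.0, 600) reproduces the stage table above.  Scaled
    configurations round channel counts to a positive integer and depths
    with ceiling.
    """

    width_multiplier: float = 1.0
    depth_multiplier: float = 1.0
    input_size: int = 600
    dropout_survival: float = 0.8   # stochastic-depth survival on residual branches
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3
    stage_overrides: list[StageSpec] | None = None

    def validate(self):
        if not self.width_multiplier > 0:
            raise ConfigurationError("width_multiplier must be > 0")
        if not self.depth_multiplier > 0:
            raise ConfigurationError("depth_multiplier must be > 0")
        if not (isinstance(self.input_size, int) and self.input_size >= 32):
            raise ConfigurationError("input_size must be an integer >= 32")
        if not (0 < self.dropout_survival <= 1):
            raise ConfigurationError("dropout_survival must be in (0, 1]")

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        """Desk-scale configuration: 1/8 width, one block per stage, 152 px input."""
        return cls(width_multiplier=0.125, depth_multiplier=1 / 13, input_size=152)

    def stage_specs(self) -> list[StageSpec]:
        """Resolve the per-stage table under the current multipliers."""
        self.validate()
        if self.stage_overrides is not None:
            return self.stage_overrides

        def scale_w(c: int) -> int:
            return max(1, round(c * self.width_multiplier))

        def scale_d(n: int) -> int:
            return max(1, math.ceil(n * self.depth_multiplier))

        specs = []
        h = self.input_size
        for i, (op, exp, k, in_c, layers, stride, out_c) in enumerate(_BASE_STAGES, start=1):
            in_c_s = 3 if i == 1 else scale_w(in_c)
            layers_s = layers if op == "plain_conv" else scale_d(layers)
            specs.append(
                StageSpec(
                    index=i,
                    op_kind=op,
                    expansion=exp,
                    kernel=k,
                    in_resolution=(h, h, in_c_s),
                    layers=layers_s,
                    first_stride=stride,
                    out_channels=scale_w(out_c),
                )
            )
            h = -(-h // stride)  # ceiling division, matching "same" padding
        return specs


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling per channel, a bottleneck FC layer of
    ``block_input_width // 4`` neurons with Swish, an FC layer back to the
    post-depthwise channel count with Sigmoid, then per-channel reweighting.
    The bottleneck width follows the *block input* width, not the expanded
    width — the arrangement used ahead of the proposal network here.
    """

    def __init__(self, channels: int, block_input_width: int, rng: np.random.Generator):
        super().__init__()
        reduced = block_input_width // 4
        if block_input_width % 4 != 0:
            logger.debug(
                "SE width %d not divisible by 4; bottleneck rounded down to %d",
                block_input_width, max(1, reduced),
            )
        reduced = max(1, reduced)
        self.fc1 = Linear(channels, reduced, rng=rng)
        self.fc2 = Linear(reduced, channels, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))                  # (N, C)
        z = self.fc1(pooled).swish()
        w = self.fc2(z).sigmoid()                     # (N, C) in (0, 1)
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1)


class MBConv(Module):
    """Mobile inverted-bottleneck block.

    Optional 1×1 expansion (omitted when expansion factor is 1) → BN + Swish
    → depthwise conv → BN + Swish → squeeze-excitation → 1×1 projection → BN.
    A shortcut connection with block-level drop exists if and only if input
    and output grids have identical height, width and channel count.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        expansion: int,
        kernel: int,
        stride: int,
        survival: float,
        rng: np.random.Generator,
        bn_momentum: float = 0.99,
        bn_eps: float = 1e-3,
    ):
        super().__init__()
        if expansion not in (1, 6):
            raise ConfigurationError("expansion must be 1 or 6")
        if kernel not in (3, 5):
            raise ConfigurationError("kernel must be 3 or 5")
        if stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        self.stride = stride
        self.survival = survival
        self.has_shortcut = stride == 1 and in_channels == out_channels
        mid = in_channels * expansion
        bn = lambda c: BatchNorm2d(c, momentum=bn_momentum, eps=bn_eps)
        if expansion != 1:
            self.expand = Conv2d(in_channels, mid, 1, bias=False, rng=rng)
            self.bn_expand = bn(mid)
        else:
            self.expand = None
        self.dw = Conv2d(mid, mid, kernel, stride=stride, padding="same",
                         depthwise=True, bias=False, rng=rng)
        self.bn_dw = bn(mid)
        self.se = SEBlock(mid, block_input_width=in_channels, rng=rng)
        self.project = Conv2d(mid, out_channels, 1, bias=False, rng=rng)
        self.bn_project = bn(out_channels)
        self._drop_rng = np.random.default_rng(int(rng.integers(2**31)))

    def __call__(self, x: Tensor) -> Tensor:
        y = x
        if self.expand is not None:
            y = self.bn_expand(self.expand(y)).swish()
        y = self.bn_dw(self.dw(y)).swish()
        y = self.se(y)
        y = self.bn_project(self.project(y))
        if self.has_shortcut:
            if self.training and self.survival < 1.0:
                keep = self._drop_rng.random(size=(y.data.shape[0], 1, 1, 1)) < self.survival
                y = y * Tensor(keep.astype(np.float32) / self.survival)
            y = y + x
        return y


@dataclass
class FeatureGrid:
    """An activation map with its stride relative to the input image."""

    tensor: Tensor          # (1, C, H, W)
    stride: int = 1

    @property
    def height(self) -> int:
        return self.tensor.data.shape[2]

    @property
    def width(self) -> int:
        return self.tensor.data.shape[3]

    @property
    def channels(self) -> int:
        return self.tensor.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(height, width, channels) — the stage-table convention."""
        return (self.height, self.width, self.channels)

    def values(self) -> np.ndarray:
        """Activations as an H×W×C array."""
        return np.ascontiguousarray(self.tensor.data[0].transpose(1, 2, 0))


@dataclass
class BackboneFeatures:
    """Per-stage grids: ``entries[i]`` enters stage i, ``outputs[i]`` leaves it."""

    entries: dict[int, FeatureGrid]
    outputs: dict[int, FeatureGrid]


class Backbone(Module):
    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.specs = config.stage_specs()
        stem = self.specs[0]
        self.stem_conv = Conv2d(3, stem.out_channels, 3, stride=stem.first_stride,
                                padding="same", bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(stem.out_channels, config.bn_momentum, config.bn_eps)
        self.stages: list[list[MBConv]] = []
        for spec in self.specs[1:]:
            blocks = []
            in_c = spec.in_resolution[2]
            for li in range(spec.layers):
                blocks.append(
                    MBConv(
                        in_channels=in_c if li == 0 else spec.out_channels,
                        out_channels=spec.out_channels,
                        expansion=spec.expansion,
                        kernel=spec.kernel,
                        stride=spec.first_stride if li == 0 else 1,
                        survival=config.dropout_survival,
                        rng=rng,
                        bn_momentum=config.bn_momentum,
                        bn_eps=config.bn_eps,
                    )
                )
            self.stages.append(blocks)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, image: Tensor) -> BackboneFeatures:
        return self.forward(image)

    def forward(self, image: Tensor | np.ndarray) -> BackboneFeatures:
        """Run all eight stages; returns every stage-entry and stage-output grid."""
        if isinstance(image, np.ndarray):
            if image.ndim == 3 and image.shape[2] == 3:   # H, W, C
                image = Tensor(image.transpose(2, 0, 1)[None])
            else:
                image = Tensor(image)
        n, c, h, w = image.data.shape
        if c != 3:
            raise ValueError(f"expected a 3-channel image, got {c} channels")
        if h != w:
            raise ValueError(f"expected a square input, got {h}x{w}")
        if h != self.config.input_size:
            raise ValueError(
                f"input size {h} does not match configured input_size {self.config.input_size}"
            )
        entries: dict[int, FeatureGrid] = {}
        outputs: dict[int, FeatureGrid] = {}
        stride = 1
        x = image
        entries[1] = FeatureGrid(x, stride)
        x = self.stem_bn(self.stem_conv(x)).swish()
        stride *= self.specs[0].first_stride
        outputs[1] = FeatureGrid(x, stride)
        for spec, blocks in zip(self.specs[1:], self.stages):
            entries[spec.index] = outputs[spec.index - 1]
            for block in blocks:
                x = block(x)
            stride *= spec.first_stride
            outputs[spec.index] = FeatureGrid(x, stride)
        return BackboneFeatures(entries=entries, outputs=outputs)

    # -- pretrained-weight hook ------------------------------------------------
    def load_weights(self, archive: dict[str, np.ndarray]):
        """Load a flat name→array archive (see ``state_dict`` for the names)."""
        self.load_state_dict(archive)


def build_backbone(config: BackboneConfig | None = None,
                   seed: int = 0) -> Backbone:
    """Construct the feature learning network for a configuration."""
    config = config or BackboneConfig()
    return Backbone(config, rng=np.random.default_rng(seed))


def forward_backbone(backbone: Backbone, image: np.ndarray | Tensor) -> BackboneFeatures:
    """Evaluation-mode forward pass returning all stage grids."""
    backbone.eval()
    with nn.no_grad():
        return backbone.forward(image)
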