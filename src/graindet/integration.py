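"""Cross-stage feature integration.

Deep stage outputs carry semantic descriptions at coarse resolution; shallow
ones carry spatial detail.  This module fuses them top-down: the deepest
tapped grid passes a 3×3 convolution (local perception) and a 1×1 channel
projection, is bilinearly upsampled to the next-shallower tap's exact spatial
size, and is fused with that tap's 1×1-projected map; the step repeats until
the shallowest tap, producing one integrated multi-scale grid at the
shallowest resolution (75×75 at stride 8 in the default pipeline — the grid
the proposal network tiles its 75·75·9 anchors over).

By default the outputs of stages 4, 6 and 8 are tapped (75, 38 and 19 px —
the three distinct scales below stride 8), giving exactly two bilinear
upsampling steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import BackboneFeatures, ConfigurationError, FeatureGrid
from .nn import Conv2d, Module, Tensor, concat, interp_bilinear


@dataclass
class IntegrationConfig:
    tap_stages: tuple[int, ...] = (4, 6, 8)
    fused_channels: int = 256
    fusion_mode: str = "sum"        # "sum" | "concat"

    def validate(self):
        if len(self.tap_stages) < 2:
            raise ConfigurationError("integration requires at least 2 tap stages")
        if self.fusion_mode not in ("sum", "concat"):
            raise ConfigurationError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.fused_channels < 1:
            raise ConfigurationError("fused_channels must be >= 1")


class Integrator(Module):
    """Top-down fusion network over tapped stage outputs."""

    def __init__(self, config: IntegrationConfig, tap_channels: dict[int, int],
                 rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.taps = sorted(config.tap_stages)           # shallow → deep
        c = config.fused_channels
        deep = self.taps[-1]
        # deepest tap: 3x3 local-perception conv, then 1x1 to fused width
        self.deep_conv3 = Conv2d(tap_channels[deep], tap_channels[deep], 3,
                                 padding="same", rng=rng)
        self.deep_proj = Conv2d(tap_channels[deep], c, 1, rng=rng)
        # shallower taps: 1x1 lateral projections
        self.laterals = [Conv2d(tap_channels[s], c, 1, rng=rng) for s in self.taps[:-1]]
        # per-fusion 3x3 conv applied before the next upsampling step
        self.mid_convs = [Conv2d(c, c, 3, padding="same", rng=rng)
                          for _ in self.taps[:-2]]
        if config.fusion_mode == "concat":
            self.merge_convs = [Conv2d(2 * c, c, 1, rng=rng) for _ in self.taps[:-1]]
        else:
            self.merge_convs = []
        self.upsample_count = 0     # interpolation ops in the last forward

    def __call__(self, stage_features: dict[int, FeatureGrid] | BackboneFeatures) -> FeatureGrid:
        return self.forward(stage_features)

    def forward(self, stage_features: dict[int, FeatureGrid] | BackboneFeatures) -> FeatureGrid:
        if isinstance(stage_features, BackboneFeatures):
            stage_features = stage_features.outputs
        missing = [s for s in self.taps if s not in stage_features]
        if missing:
            raise ConfigurationError(f"missing tapped stages: {missing}")
        grids = [stage_features[s] for s in self.taps]
        sizes = [(g.height, g.width) for g in grids]
        if not all(sizes[i][0] > sizes[i + 1][0] for i in range(len(sizes) - 1)):
            raise ConfigurationError(
                f"tapped grids must have strictly decreasing spatial size, got {sizes}"
            )
        self.upsample_count = 0
        x = self.deep_proj(self.deep_conv3(grids[-1].tensor).swish())
        for level in range(len(self.taps) - 2, -1, -1):
            shallow = grids[level]
            if level < len(self.taps) - 2:
                x = self.mid_convs[level](x).swish()
            x = interp_bilinear(x, shallow.height, shallow.width)
            self.upsample_count += 1
            lateral = self.laterals[level](shallow.tensor)
            if self.config.fusion_mode == "sum":
                x = x + lateral
            else:
                x = self.merge_convs[level](concat([x, lateral], axis=1))
        return FeatureGrid(x, stride=grids[0].stride)


def integrate(stage_features: dict[int, FeatureGrid] | BackboneFeatures,
              config: IntegrationConfig | None = None,
              integrator: Integrator | None = None,
              seed: int = 0) -> FeatureGrid:
    """One-shot fusion (builds an :class:`Integrator` if none is supplied)."""
    if integrator is None:
        config = config or IntegrationConfig()
        feats = stage_features.outputs if isinstance(stage_features, BackboneFeatures) \
            else stage_features
        tap_channels = {s: feats[s].channels for s in config.tap_stages if s in feats}
        missing = [s for s in config.tap_stages if s not in feats]
        if missing:
            raise ConfigurationError(f"missing tapped stages: {missing}")
        integrator = Integrator(config, tap_channels, rng=np.random.default_rng(seed))
    integrator.eval()
    with nn.no_grad():
        return integrator.forward(stage_features)
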