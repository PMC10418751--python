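"""Adaptive region proposal network (ARPN).

Anchors tuned to kernel-sized objects in 600×600 images: area scales 64²,
128² and 256² px² at aspect ratios (h:w) 1:1, 1:2 and 2:1, nine per cell of
the stride-8 integrated feature grid — 75·75·9 = 50 625 anchors per image.

Training labels: an anchor is positive when its IoU with any ground-truth
box exceeds 0.7 *or* it has the highest IoU for some ground-truth box;
negative when its IoU with every ground-truth box is below 0.3; otherwise it
is ignored.  Anchors crossing the image boundary are ignored during training
(excluded even from the per-ground-truth argmax).  Mini-batches hold 256
anchors with at most 128 positives, any deficit filled with negatives.

The loss is (Σ classification + Σ positives-only regression) / N_m with
log loss on the probability of the true label and smooth-L1 on the box
regression residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeatureGrid
from .boxes import (  # noqa: F401  (re-exported module surface)
    BoxArray,
    decode_boxes,
    encode_boxes,
    iou,
    nms,
    smooth_l1,
)
from .nn import Conv2d, Module, Tensor, log_softmax, smooth_l1_t

logger = logging.getLogger("graindet")

IGNORE = -1  #: label for anchors excluded from training


@dataclass
class AnchorGridSpec:
    grid_height: int = 75
    grid_width: int = 75
    stride: int = 8
    area_scales: tuple[float, ...] = (64.0**2, 128.0**2, 256.0**2)
    aspect_ratios: tuple[float, ...] = (1.0, 0.5, 2.0)   # h:w

    @property
    def anchors_per_cell(self) -> int:
        return len(self.area_scales) * len(self.aspect_ratios)

    @property
    def total(self) -> int:
        return self.grid_height * self.grid_width * self.anchors_per_cell


@dataclass
class RPNTargets:
    """Per-anchor labels c* (1 positive / 0 negative / -1 ignore), regression
    targets r* for positives, and the sampled mini-batch mask."""

    labels: np.ndarray                     # (A,) int
    regression_targets: np.ndarray         # (A, 4), defined where labels == 1
    sampled: np.ndarray | None = None      # (A,) bool


@dataclass
class RPNOutput:
    """Per-anchor objectness (foreground, background) probabilities and
    predicted regression parameters."""

    cls_logits: Tensor      # (A, 2) — columns (background, foreground)
    regression: Tensor      # (A, 4)

    @property
    def objectness(self) -> np.ndarray:
        z = self.cls_logits.data
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return (e[:, 1] / e.sum(axis=1)).astype(np.float64)


@dataclass
class Proposal:
    box: np.ndarray         # corner form (x1, y1, x2, y2)
    score: float

    def to_coco(self, image_id: int = 0) -> dict:
        x1, y1, x2, y2 = (float(v) for v in self.box)
        return {
            "image_id": image_id,
            "bbox": [x1, y1, x2 - x1, y2 - y1],
            "score": float(self.score),
        }


def generate_anchors(spec: AnchorGridSpec) -> BoxArray:
    """Tile one anchor per (cell, scale, ratio), centered at
    ((j+0.5)·stride, (i+0.5)·stride); each satisfies w·h = scale, h/w = ratio."""
    ratios = np.asarray(spec.aspect_ratios, dtype=np.float64)
    scales = np.asarray(spec.area_scales, dtype=np.float64)
    # per (scale, ratio): w = sqrt(area / ratio), h = ratio * w
    ws = np.sqrt(scales[:, None] / ratios[None, :]).ravel()
    hs = (np.sqrt(scales[:, None] / ratios[None, :]) * ratios[None, :]).ravel()
    jj, ii = np.meshgrid(np.arange(spec.grid_width), np.arange(spec.grid_height))
    cx = (jj.ravel() + 0.5) * spec.stride
    cy = (ii.ravel() + 0.5) * spec.stride
    n = spec.anchors_per_cell
    return BoxArray(
        np.repeat(cx, n),
        np.repeat(cy, n),
        np.tile(ws, cx.size),
        np.tile(hs, cy.size),
    )


def cross_boundary_mask(anchors: BoxArray, image_size: tuple[int, int]) -> np.ndarray:
    """True for anchors extending past the image rectangle (width, height)."""
    c = anchors.corners()
    w, h = image_size
    return (c[:, 0] < 0) | (c[:, 1] < 0) | (c[:, 2] > w) | (c[:, 3] > h)


def label_anchors(
    anchors: BoxArray,
    gt_boxes: BoxArray,
    image_size: tuple[int, int] | None = None,
    pos_iou: float = 0.7,
    neg_iou: float = 0.3,
) -> RPNTargets:
    """Assign training labels and regression targets to anchors.

    The per-ground-truth argmax rule is applied after the IoU>0.7 rule and can
    promote an anchor labeled ignore or negative; boundary-crossing anchors
    (when ``image_size`` is given) never participate, not even via argmax.
    """
    a = len(anchors)
    labels = np.full(a, IGNORE, dtype=np.int64)
    reg = np.zeros((a, 4), dtype=np.float64)
    in_bounds = np.ones(a, dtype=bool)
    if image_size is not None:
        in_bounds = ~cross_boundary_mask(anchors, image_size)
    if len(gt_boxes) == 0:
        labels[in_bounds] = 0
        return RPNTargets(labels, reg)
    overlaps = iou(anchors, gt_boxes)          # (A, G)
    overlaps_v = np.where(in_bounds[:, None], overlaps, -1.0)
    max_per_anchor = overlaps_v.max(axis=1)
    labels[in_bounds & (max_per_anchor < neg_iou)] = 0
    labels[in_bounds & (max_per_anchor > pos_iou)] = 1
    # argmax rule: every ground truth claims its best in-bounds anchor(s)
    gt_best = overlaps_v.max(axis=0)           # (G,)
    for g in range(len(gt_boxes)):
        if gt_best[g] <= 0:
            continue    # no in-bounds anchor overlaps this ground truth
        best = np.flatnonzero(overlaps_v[:, g] == gt_best[g])
        labels[best] = 1
    pos = np.flatnonzero(labels == 1)
    if pos.size:
        match = overlaps_v[pos].argmax(axis=1)
        reg[pos] = encode_boxes(anchors[pos], gt_boxes[match])
    return RPNTargets(labels, reg)


def sample_minibatch(
    targets: RPNTargets,
    rng: np.random.Generator | int | None = None,
    batch_size: int = 256,
    max_positives: int = 128,
) -> RPNTargets:
    """Uniformly sample up to ``max_positives`` positives and fill the batch
    to ``batch_size`` with negatives."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = np.flatnonzero(targets.labels == 1)
    neg = np.flatnonzero(targets.labels == 0)
    n_pos = min(len(pos), max_positives)
    n_neg = min(len(neg), batch_size - n_pos)
    if n_pos + n_neg < batch_size:
        warnings.warn(
            f"only {n_pos + n_neg} labeled anchors available for a "
            f"mini-batch of {batch_size}; sampling all", stacklevel=2,
        )
    sampled = np.zeros(len(targets.labels), dtype=bool)
    if n_pos:
        sampled[rng.choice(pos, size=n_pos, replace=False)] = True
    if n_neg:
        sampled[rng.choice(neg, size=n_neg, replace=False)] = True
    return RPNTargets(targets.labels, targets.regression_targets, sampled)


class RPNHead(Module):
    """3×3 conv over the integrated feature (same size and dimension), then
    two parallel 1×1 convs emitting 2n classification and 4n regression
    channels per cell."""

    def __init__(self, in_channels: int, anchors_per_cell: int = 9,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n = anchors_per_cell
        self.conv = Conv2d(in_channels, in_channels, 3, padding="same", rng=rng)
        self.cls = Conv2d(in_channels, 2 * anchors_per_cell, 1, rng=rng)
        self.reg = Conv2d(in_channels, 4 * anchors_per_cell, 1, rng=rng)

    def __call__(self, integrated: FeatureGrid | Tensor) -> RPNOutput:
        x = integrated.tensor if isinstance(integrated, FeatureGrid) else integrated
        t = self.conv(x).swish()
        cls = self.cls(t)   # (1, 2n, H, W)
        reg = self.reg(t)   # (1, 4n, H, W)
        _, _, h, w = cls.data.shape
        # anchor order must match generate_anchors: cell-major, then anchor index
        cls = cls.reshape(self.n, 2, h, w).transpose(2, 3, 0, 1).reshape(h * w * self.n, 2)
        reg = reg.reshape(self.n, 4, h, w).transpose(2, 3, 0, 1).reshape(h * w * self.n, 4)
        return RPNOutput(cls_logits=cls, regression=reg)


def rpn_head(integrated: FeatureGrid, n: int = 9, seed: int = 0) -> RPNOutput:
    """One-shot head application (builds an :class:`RPNHead`)."""
    head = RPNHead(integrated.channels, n, rng=np.random.default_rng(seed))
    head.eval()
    with nn.no_grad():
        return head(integrated)


def rpn_loss(
    output: RPNOutput,
    targets: RPNTargets,
    eps: float = 1e-12,
) -> tuple[Tensor, dict[str, float]]:
    """Mini-batch loss: [Σ L_cls + Σ c*·L_reg] / N_m over sampled anchors.

    L_cls is −ln of the probability assigned to the true label; L_reg sums
    smooth-L1 over the four regression residuals; negatives contribute no
    regression term.
    """
    if targets.sampled is None:
        raise ValueError("targets must carry a sampled mask (see sample_minibatch)")
    idx = np.flatnonzero(targets.sampled)
    n_m = max(1, idx.size)
    labels = targets.labels[idx]
    logp = log_softmax(output.cls_logits[idx], axis=1)
    if np.any(np.exp(logp.data[np.arange(idx.size), labels]) < eps):
        warnings.warn("true-label probability clamped in RPN loss", stacklevel=2)
    cls_sum = -(logp[np.arange(idx.size), labels].sum())
    pos = idx[targets.labels[idx] == 1]
    breakdown = {"cls": float(cls_sum.data) / n_m, "reg": 0.0}
    total = cls_sum
    if pos.size:
        resid = output.regression[pos] - Tensor(
            targets.regression_targets[pos].astype(np.float32))
        reg_sum = smooth_l1_t(resid).sum()
        breakdown["reg"] = float(reg_sum.data) / n_m
        total = total + reg_sum
    total = total * (1.0 / n_m)
    breakdown["total"] = float(total.data)
    return total, breakdown


@dataclass
class ProposalConfig:
    nms_threshold: float = 0.7
    pre_nms_train: int = 2000
    post_nms_train: int = 2000
    pre_nms_test: int = 1000
    post_nms_test: int = 300
    min_size: float = 1.0


def generate_proposals(
    output: RPNOutput,
    anchors: BoxArray,
    image_size: tuple[int, int],
    mode: str = "test",
    config: ProposalConfig | None = None,
) -> list[Proposal]:
    """Decode anchors, clip to the image, drop degenerate boxes, keep the
    top-K by objectness, suppress at IoU 0.7, keep the top-K survivors."""
    config = config or ProposalConfig()
    k_pre = config.pre_nms_train if mode == "train" else config.pre_nms_test
    k_post = config.post_nms_train if mode == "train" else config.post_nms_test
    scores = output.objectness
    boxes = decode_boxes(anchors, output.regression.data.astype(np.float64),
                         image_size=image_size)
    valid = (boxes.w >= config.min_size) & (boxes.h >= config.min_size)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    order = idx[np.argsort(-scores[idx], kind="stable")][:k_pre]
    keep = nms(boxes[order], scores[order], config.nms_threshold)[:k_post]
    kept = order[keep]
    corners = boxes[kept].corners()
    return [Proposal(box=corners[i], score=float(scores[kept[i]]))
            for i in range(len(kept))]
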