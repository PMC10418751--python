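"""Candidate-box classification and regression layers.

Proposals from the ARPN are projected onto the stride-8 integrated feature
(quantized max ROI pooling to a fixed grid), flattened, passed through two
1024-neuron fully connected layers, and fed to (a) a softmax classifier over
k+1 classes (background included) and (b) a per-class box regressor with
4·(k+1) outputs.  Final boxes decode as

    U_x = P_w·f_x + P_x,  U_y = P_h·f_y + P_y,
    U_w = P_w·e^{f_w},    U_h = P_h·e^{f_h}

and the per-ROI loss is −ln q_v + α·[v>0]·Σ smooth_l1(b^g − s), with the
Iverson bracket excluding background ROIs from the location term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeatureGrid
from .boxes import BoxArray, decode_boxes, encode_boxes, iou, nms
from .nn import Linear, Module, Tensor, log_softmax, roi_max_pool, smooth_l1_t

logger = logging.getLogger("graindet")


@dataclass
class RoI:
    """A region of interest in image pixel coordinates (corner form)."""

    box: np.ndarray                 # (4,) x1, y1, x2, y2
    score: float = 0.0


@dataclass
class DetHeadOutput:
    class_probs: Tensor             # (R, k+1), rows sum to 1
    regression: Tensor              # (R, k+1, 4)


@dataclass
class Detection:
    box: np.ndarray                 # corner form (x1, y1, x2, y2)
    label: int                      # 1..k (never background)
    confidence: float

    def to_coco(self, image_id: int = 0) -> dict:
        x1, y1, x2, y2 = (float(v) for v in self.box)
        return {
            "image_id": image_id,
            "category_id": int(self.label),
            "bbox": [x1, y1, x2 - x1, y2 - y1],
            "score": float(self.confidence),
        }


@dataclass
class DetLossConfig:
    alpha: float = 1.0              # balance between category and location loss
    rois_per_image: int = 128
    fg_fraction: float = 0.25
    fg_iou_min: float = 0.5
    bg_iou_range: tuple[float, float] = (0.1, 0.5)


def roi_pool(
    integrated: FeatureGrid,
    rois: list[RoI] | np.ndarray,
    output_size: int = 7,
) -> Tensor:
    """Project ROIs to feature coordinates (divide by the stride), quantize,
    and max-pool each into an ``output_size``² grid.  Returns (R, C, S, S)."""
    boxes = np.asarray([r.box for r in rois] if rois and isinstance(rois[0], RoI) else rois,
                       dtype=np.float64).reshape(-1, 4)
    h, w = integrated.height, integrated.width
    feat_boxes = boxes / integrated.stride
    fully_out = (
        (feat_boxes[:, 2] <= 0) | (feat_boxes[:, 3] <= 0)
        | (feat_boxes[:, 0] >= w) | (feat_boxes[:, 1] >= h)
    )
    if np.any(fully_out):
        raise ValueError(
            f"{int(fully_out.sum())} ROI(s) fall entirely outside the feature grid; "
            "clip proposals to the image first"
        )
    return roi_max_pool(integrated.tensor, feat_boxes, output_size)


class DetHead(Module):
    """Two 1024-neuron fully connected layers feeding a (k+1)-way softmax
    classifier and a 4·(k+1)-output box regressor."""

    def __init__(self, in_features: int, num_classes: int, hidden: int = 1024,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.num_classes = num_classes              # k (foreground classes)
        self.hidden = hidden
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.fc2 = Linear(hidden, hidden, rng=rng)
        self.classifier = Linear(hidden, num_classes + 1, rng=rng)
        self.regressor = Linear(hidden, 4 * (num_classes + 1), rng=rng)

    def __call__(self, pooled: Tensor) -> DetHeadOutput:
        r = pooled.data.shape[0]
        x = pooled.reshape(r, -1)
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        probs = log_softmax(self.classifier(x), axis=1).exp()
        reg = self.regressor(x).reshape(r, self.num_classes + 1, 4)
        return DetHeadOutput(class_probs=probs, regression=reg)


def det_head(pooled: Tensor, k: int, hidden: int = 1024, seed: int = 0) -> DetHeadOutput:
    """One-shot head application (builds a :class:`DetHead`)."""
    in_features = int(np.prod(pooled.data.shape[1:]))
    head = DetHead(in_features, k, hidden=hidden, rng=np.random.default_rng(seed))
    head.eval()
    with nn.no_grad():
        return head(pooled)


def decode_final(roi: RoI | BoxArray, f: np.ndarray,
                 image_size: tuple[int, int] | None = None) -> BoxArray:
    """Apply per-class regression parameters f to candidate boxes."""
    boxes = BoxArray.from_corners(roi.box) if isinstance(roi, RoI) else roi
    return decode_boxes(boxes, f, image_size=image_size)


def det_loss(
    q: Tensor,
    v: np.ndarray,
    b_g: Tensor,
    s: np.ndarray,
    config: DetLossConfig | None = None,
    eps: float = 1e-12,
) -> tuple[Tensor, dict[str, float]]:
    """Per-ROI loss −ln q_v + α·[v>0]·Σ_i smooth_l1(b^g_i − s_i), averaged
    over the batch.

    ``q`` is (R, k+1) class probabilities, ``v`` (R,) true labels in 0..k
    (0 = background), ``b_g`` (R, k+1, 4) per-class regression output —
    only the slice for the true class g=v enters the loss — and ``s`` (R, 4)
    encoded regression targets (defined where v > 0).
    """
    config = config or DetLossConfig()
    v = np.asarray(v, dtype=np.int64)
    r = v.shape[0]
    qv = q[np.arange(r), v]
    if np.any(qv.data < eps):
        warnings.warn("true-class probability clamped in detection loss", stacklevel=2)
        qv = qv + eps
    cat = -(qv.log().sum())
    fg = np.flatnonzero(v > 0)
    breakdown = {"cat": float(cat.data) / r, "loc": 0.0}
    total = cat
    if fg.size and config.alpha != 0.0:
        picked = b_g[fg, v[fg]]                     # (F, 4) true-class slice
        resid = picked - Tensor(np.asarray(s, dtype=np.float32)[fg])
        loc = smooth_l1_t(resid).sum()
        breakdown["loc"] = config.alpha * float(loc.data) / r
        total = total + config.alpha * loc
    total = total * (1.0 / r)
    breakdown["total"] = float(total.data)
    return total, breakdown


@dataclass
class RoIBatch:
    rois: list[RoI]
    labels: np.ndarray              # (R,) v in 0..k
    regression_targets: np.ndarray  # (R, 4), defined where labels > 0


def assign_rois(
    proposals: list,
    gt_boxes: BoxArray,
    gt_labels: np.ndarray,
    config: DetLossConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RoIBatch:
    """Match proposals to ground truth and sample a training batch.

    Foreground when IoU ≥ ``fg_iou_min``, background when IoU falls in
    ``bg_iou_range``; everything else is excluded.  Sampling keeps at most
    ``rois_per_image`` ROIs with a ``fg_fraction`` share of foregrounds.
    Regression targets use the proposal as the reference box.
    """
    config = config or DetLossConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    boxes = np.asarray([p.box for p in proposals], dtype=np.float64).reshape(-1, 4)
    scores = np.asarray([getattr(p, "score", 0.0) for p in proposals], dtype=np.float64)
    prop = BoxArray.from_corners(boxes) if len(boxes) else BoxArray([], [], [], [])
    gt_labels = np.asarray(gt_labels, dtype=np.int64)
    if len(gt_boxes) == 0 or len(prop) == 0:
        overlaps = np.zeros((len(prop), max(1, len(gt_boxes))))
    else:
        overlaps = iou(prop, gt_boxes)
    best_gt = overlaps.argmax(axis=1) if overlaps.size else np.zeros(len(prop), dtype=int)
    best_iou = overlaps.max(axis=1) if overlaps.size else np.zeros(len(prop))
    fg_idx = np.flatnonzero(best_iou >= config.fg_iou_min)
    lo, hi = config.bg_iou_range
    bg_idx = np.flatnonzero((best_iou >= lo) & (best_iou < hi))
    n_fg = min(len(fg_idx), int(round(config.rois_per_image * config.fg_fraction)))
    n_bg = min(len(bg_idx), config.rois_per_image - n_fg)
    if n_fg == 0:
        warnings.warn("no foreground ROIs; all-background batch", stacklevel=2)
    sel_fg = rng.choice(fg_idx, size=n_fg, replace=False) if n_fg else np.empty(0, dtype=int)
    sel_bg = rng.choice(bg_idx, size=n_bg, replace=False) if n_bg else np.empty(0, dtype=int)
    sel = np.concatenate([sel_fg, sel_bg]).astype(int)
    labels = np.zeros(len(sel), dtype=np.int64)
    labels[: len(sel_fg)] = gt_labels[best_gt[sel_fg]]
    reg = np.zeros((len(sel), 4), dtype=np.float64)
    if len(sel_fg):
        reg[: len(sel_fg)] = encode_boxes(prop[sel_fg], gt_boxes[best_gt[sel_fg]])
    rois = [RoI(box=boxes[i], score=scores[i]) for i in sel]
    return RoIBatch(rois=rois, labels=labels, regression_targets=reg)


@dataclass
class PostprocessConfig:
    score_threshold: float = 0.05
    nms_threshold: float = 0.3
    max_detections: int = 100


def postprocess(
    outputs: DetHeadOutput,
    rois: list[RoI],
    image_size: tuple[int, int],
    config: PostprocessConfig | None = None,
) -> list[Detection]:
    """Per-class decode, clip, score-filter, class-wise NMS, top-100 keep."""
    config = config or PostprocessConfig()
    probs = outputs.class_probs.data
    reg = outputs.regression.data
    k = probs.shape[1] - 1
    boxes = BoxArray.from_corners(np.asarray([r.box for r in rois]).reshape(-1, 4))
    detections: list[Detection] = []
    for cls in range(1, k + 1):
        scores = probs[:, cls].astype(np.float64)
        keep_score = np.flatnonzero(scores >= config.score_threshold)
        if keep_score.size == 0:
            continue
        decoded = decode_final(boxes[keep_score], reg[keep_score, cls],
                               image_size=image_size)
        valid = np.flatnonzero((decoded.w > 0) & (decoded.h > 0))
        if valid.size == 0:
            continue
        decoded = decoded[valid]
        cls_scores = scores[keep_score][valid]
        kept = nms(decoded, cls_scores, config.nms_threshold)
        corners = decoded.corners()
        detections.extend(
            Detection(box=corners[i], label=cls, confidence=float(cls_scores[i]))
            for i in kept
        )
    detections.sort(key=lambda d: -d.confidence)
    return detections[: config.max_detections]
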