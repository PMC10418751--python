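"""Axis-aligned box geometry shared by the proposal network, the detection
head and the evaluator.

Boxes live in 0-based, half-open pixel coordinates.  :class:`BoxArray` keeps
the center/size parameterization used by the regression transforms and
converts to corner form on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class BoxArray:
    """A batch of rectangles: centers (x, y) and sizes (w, h), shape (N,)."""

    cx: np.ndarray
    cy: np.ndarray
    w: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        self.cx = np.asarray(self.cx, dtype=np.float64)
        self.cy = np.asarray(self.cy, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)

    def __len__(self) -> int:
        return self.cx.shape[0]

    def __getitem__(self, idx) -> "BoxArray":
        return BoxArray(self.cx[idx], self.cy[idx], self.w[idx], self.h[idx])

    @classmethod
    def from_corners(cls, corners: np.ndarray) -> "BoxArray":
        """Build from (N, 4) corner form (x1, y1, x2, y2)."""
        corners = np.atleast_2d(np.asarray(corners, dtype=np.float64))
        x1, y1, x2, y2 = corners.T
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    @classmethod
    def from_xywh(cls, xywh: np.ndarray) -> "BoxArray":
        """Build from COCO-style (x, y, w, h) with (x, y) the top-left corner."""
        xywh = np.atleast_2d(np.asarray(xywh, dtype=np.float64))
        x, y, w, h = xywh.T
        return cls(x + w / 2, y + h / 2, w, h)

    def corners(self) -> np.ndarray:
        """(N, 4) corner form (x1, y1, x2, y2)."""
        return np.stack(
            [self.cx - self.w / 2, self.cy - self.h / 2,
             self.cx + self.w / 2, self.cy + self.h / 2], axis=1
        )

    def xywh(self) -> np.ndarray:
        """(N, 4) COCO-style (x_topleft, y_topleft, w, h)."""
        return np.stack(
            [self.cx - self.w / 2, self.cy - self.h / 2, self.w, self.h], axis=1
        )

    def areas(self) -> np.ndarray:
        return self.w * self.h

    def clip(self, width: int, height: int) -> "BoxArray":
        """Clip boxes to the image rectangle [0, width) × [0, height)."""
        c = self.corners()
        c[:, 0::2] = np.clip(c[:, 0::2], 0, width)
        c[:, 1::2] = np.clip(c[:, 1::2], 0, height)
        return BoxArray.from_corners(c)


def iou(a: BoxArray, b: BoxArray) -> np.ndarray:
    """Pairwise intersection-over-union, shape (len(a), len(b)), values in [0, 1]."""
    ca, cb = a.corners(), b.corners()
    area_a, area_b = a.areas(), b.areas()
    if np.any(area_a <= 0) or np.any(area_b <= 0):
        warnings.warn("degenerate zero-area box in IoU; its overlaps are 0", stacklevel=2)
    ix1 = np.maximum(ca[:, None, 0], cb[None, :, 0])
    iy1 = np.maximum(ca[:, None, 1], cb[None, :, 1])
    ix2 = np.minimum(ca[:, None, 2], cb[None, :, 2])
    iy2 = np.minimum(ca[:, None, 3], cb[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def encode_boxes(before: BoxArray, target: BoxArray) -> np.ndarray:
    """Regression parameters r = ((x*-x)/w, (y*-y)/h, ln(w*/w), ln(h*/h)).

    ``before`` is the reference box (an anchor or a proposal), ``target`` the
    box it should move to.
    """
    if np.any(before.w <= 0) or np.any(before.h <= 0) or np.any(target.w <= 0) or np.any(target.h <= 0):
        raise ValueError("encode_boxes requires strictly positive widths and heights")
    return np.stack(
        [
            (target.cx - before.cx) / before.w,
            (target.cy - before.cy) / before.h,
            np.log(target.w / before.w),
            np.log(target.h / before.h),
        ],
        axis=1,
    )


#: clamp on log-size deltas before exponentiation (e^4 ≈ 54.6× growth)
LOG_SIZE_CLAMP = 4.0


def decode_boxes(
    before: BoxArray,
    r: np.ndarray,
    image_size: tuple[int, int] | None = None,
) -> BoxArray:
    """Inverse of :func:`encode_boxes`; optionally clip to (width, height)."""
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    dlog = r[:, 2:4]
    if np.any(np.abs(dlog) > LOG_SIZE_CLAMP):
        warnings.warn("log-size deltas clamped to ±4 in decode_boxes", stacklevel=2)
        dlog = np.clip(dlog, -LOG_SIZE_CLAMP, LOG_SIZE_CLAMP)
    out = BoxArray(
        before.w * r[:, 0] + before.cx,
        before.h * r[:, 1] + before.cy,
        before.w * np.exp(dlog[:, 0]),
        before.h * np.exp(dlog[:, 1]),
    )
    if image_size is not None:
        out = out.clip(*image_size)
    return out


def smooth_l1(x):
    """Robust loss: 0.5 x² for |x| < 1, |x| − 0.5 otherwise.

    Continuous with continuous first derivative at |x| = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    return out if out.ndim else float(out)


def nms(boxes: BoxArray, scores: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Greedy non-maximum suppression.

    Returns indices of kept boxes in descending score order; a box is
    suppressed when its IoU with an already-kept box exceeds ``threshold``.
    Score ties break toward the lower original index.
    """
    scores = np.asarray(scores, dtype=np.float64)
    order = np.lexsort((np.arange(len(scores)), -scores))
    mat = iou(boxes, boxes)
    keep: list[int] = []
    alive = np.ones(len(scores), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        keep.append(int(i))
        alive &= mat[i] <= threshold
        alive[i] = False
    return np.asarray(keep, dtype=np.int64)
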