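"""COCO-style detection evaluation.

Implements the standard COCO protocol: greedy score-ordered one-to-one
matching per IoU threshold, 101-point interpolated precision–recall area,
AP averaged over IoU thresholds 0.5:0.05:0.95 and over classes, AP50,
small-object AP/AR (ground-truth area < 64² px²) and average recall at
detection budgets of 10 and 100.  Average recall is the standard COCO
normalization 2·∫_{0.5}^{1} recall(t) dt, realized as the mean of the
per-threshold recalls over the ten thresholds.

Ground truth and detections use COCO-JSON conventions: bbox = [x, y, w, h]
with (x, y) the top-left corner, area = w·h (no masks exist here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import BoxArray, iou

IOU_THRESHOLDS = np.arange(0.5, 0.951, 0.05)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)
SMALL_AREA_MAX = 64.0**2


@dataclass
class MetricsReport:
    """Headline detection metrics; values in [0, 1], NaN when undefined."""

    AP: float
    AP50: float
    APs: float
    AR10: float
    AR100: float
    ARs: float
    per_class_ap50: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        return {
            "AP": clean(self.AP),
            "AP50": clean(self.AP50),
            "APs": clean(self.APs),
            "AR10": clean(self.AR10),
            "AR100": clean(self.AR100),
            "ARs": clean(self.ARs),
            "per_class_AP50": {str(k): clean(v) for k, v in self.per_class_ap50.items()},
        }

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def per_class_table(self, names: dict[int, str] | None = None) -> str:
        lines = [f"{'category':<16} {'AP50':>8}"]
        for cid, ap in sorted(self.per_class_ap50.items()):
            name = (names or {}).get(cid, str(cid))
            val = "  n/a" if np.isnan(ap) else f"{ap:8.4f}"
            lines.append(f"{name:<16} {val}")
        return "\n".join(lines)


def match_detections(
    detections: np.ndarray,
    det_scores: np.ndarray,
    ground_truths: np.ndarray,
    iou_threshold: float,
) -> np.ndarray:
    """Greedy one-to-one matching (no ignore regions).

    Boxes are (N, 4) corner form.  Detections are processed in descending
    score order; each matches the unmatched ground truth of highest IoU,
    provided that IoU ≥ threshold.  Returns a boolean TP flag per detection
    (in the original detection order).
    """
    detections = np.asarray(detections, dtype=np.float64).reshape(-1, 4)
    ground_truths = np.asarray(ground_truths, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-np.asarray(det_scores), kind="stable")
    tp = np.zeros(len(detections), dtype=bool)
    if len(ground_truths) == 0 or len(detections) == 0:
        return tp
    mat = iou(BoxArray.from_corners(detections), BoxArray.from_corners(ground_truths))
    taken = np.zeros(len(ground_truths), dtype=bool)
    for d in order:
        cand = np.where(taken, -1.0, mat[d])
        g = int(cand.argmax())
        if cand[g] >= iou_threshold:
            tp[d] = True
            taken[g] = True
    return tp


def average_precision(flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from score-ordered TP flags.

    ``flags`` are TP(1)/FP(0) indicators sorted by descending score; ``n_gt``
    is the number of ground-truth objects.  Returns NaN when n_gt == 0.
    """
    if n_gt == 0:
        return float("nan")
    flags = np.asarray(flags, dtype=np.float64)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # enforce monotone non-increasing precision envelope
    for i in range(len(precision) - 1, 0, -1):
        precision[i - 1] = max(precision[i - 1], precision[i])
    idx = np.searchsorted(recall, RECALL_THRESHOLDS, side="left")
    q = np.where(idx < len(precision), precision[np.clip(idx, 0, len(precision) - 1)], 0.0)
    return float(q.mean())


# -----------------------------------------------------------------------------
# full COCO-style accumulation (with ignore semantics for area partitions)
# -----------------------------------------------------------------------------

def _match_image(
    det_boxes: np.ndarray,
    det_scores: np.ndarray,
    gt_boxes: np.ndarray,
    gt_ignore: np.ndarray,
    thresholds: np.ndarray,
    max_dets: int,
    area_range: tuple[float, float] | None,
):
    """Per-image greedy matching at every threshold, honoring ignore flags.

    Ground truths flagged ignore can absorb detections without making them
    false positives; unmatched detections whose own area falls outside the
    range are likewise excluded from scoring.
    """
    order = np.argsort(-det_scores, kind="stable")[:max_dets]
    det_boxes = det_boxes[order]
    det_scores = det_scores[order]
    g_order = np.argsort(gt_ignore, kind="stable")      # valid ground truths first
    gt_boxes = gt_boxes[g_order]
    gt_ignore = gt_ignore[g_order]
    nd, ng = len(det_boxes), len(gt_boxes)
    nt = len(thresholds)
    dt_matched = np.zeros((nt, nd), dtype=bool)
    dt_ignore = np.zeros((nt, nd), dtype=bool)
    if nd and ng:
        mat = iou(BoxArray.from_corners(det_boxes), BoxArray.from_corners(gt_boxes))
        for ti, t in enumerate(thresholds):
            gt_taken = np.full(ng, False)
            for d in range(nd):
                best = min(t, 1 - 1e-10)
                m = -1
                for g in range(ng):
                    if gt_taken[g]:
                        continue
                    if m > -1 and not gt_ignore[m] and gt_ignore[g]:
                        break           # only ignored ground truths remain
                    if mat[d, g] < best:
                        continue
                    best = mat[d, g]
                    m = g
                if m > -1:
                    gt_taken[m] = True
                    dt_matched[ti, d] = True
                    dt_ignore[ti, d] = gt_ignore[m]
    if area_range is not None and nd:
        areas = (det_boxes[:, 2] - det_boxes[:, 0]) * (det_boxes[:, 3] - det_boxes[:, 1])
        out = (areas < area_range[0]) | (areas >= area_range[1])
        dt_ignore |= (~dt_matched) & out[None, :]
    return det_scores, dt_matched, dt_ignore, int((~gt_ignore).sum())


def _accumulate_class(
    per_image: list[tuple],
    thresholds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """AP and final recall per threshold for one class; NaN when no ground truth."""
    npig = sum(rec[3] for rec in per_image)
    nt = len(thresholds)
    if npig == 0:
        return np.full(nt, np.nan), np.full(nt, np.nan)
    scores = np.concatenate([rec[0] for rec in per_image]) if per_image else np.empty(0)
    order = np.argsort(-scores, kind="stable")
    ap = np.zeros(nt)
    rc = np.zeros(nt)
    for ti in range(nt):
        matched = np.concatenate([rec[1][ti] for rec in per_image])[order]
        ignored = np.concatenate([rec[2][ti] for rec in per_image])[order]
        keep = ~ignored
        flags = matched[keep]
        ap[ti] = average_precision(flags, npig)
        rc[ti] = flags.sum() / npig if flags.size else 0.0
    return ap, rc


def evaluate_detections(
    ground_truths: list[dict],
    detections: list[dict],
    category_ids: list[int],
    image_ids: list[int] | None = None,
) -> MetricsReport:
    """Compute the full metrics report from COCO-style record lists.

    ``ground_truths``: dicts with image_id, category_id, bbox, area.
    ``detections``: dicts with image_id, category_id, bbox, score.
    """
    if image_ids is None:
        image_ids = sorted(
            {g["image_id"] for g in ground_truths} | {d["image_id"] for d in detections}
        )
    gt_by_key: dict[tuple, list] = {}
    for g in ground_truths:
        gt_by_key.setdefault((g["image_id"], g["category_id"]), []).append(g)
    dt_by_key: dict[tuple, list] = {}
    for d in detections:
        dt_by_key.setdefault((d["image_id"], d["category_id"]), []).append(d)

    def corner(bbox):
        x, y, w, h = bbox
        return [x, y, x + w, y + h]

    def run(area_range, max_dets):
        ap_cls, rc_cls, ap50_cls = [], [], {}
        for cid in category_ids:
            per_image = []
            for img in image_ids:
                gts = gt_by_key.get((img, cid), [])
                dts = dt_by_key.get((img, cid), [])
                gt_boxes = np.asarray([corner(g["bbox"]) for g in gts]).reshape(-1, 4)
                gt_areas = np.asarray(
                    [g.get("area", g["bbox"][2] * g["bbox"][3]) for g in gts], dtype=float)
                gt_ig = np.asarray([bool(g.get("ignore", False)) for g in gts], dtype=bool)
                if area_range is not None:
                    gt_ig |= (gt_areas < area_range[0]) | (gt_areas >= area_range[1])
                det_boxes = np.asarray([corner(d["bbox"]) for d in dts]).reshape(-1, 4)
                det_scores = np.asarray([d["score"] for d in dts], dtype=np.float64)
                per_image.append(
                    _match_image(det_boxes, det_scores, gt_boxes, gt_ig,
                                 IOU_THRESHOLDS, max_dets, area_range)
                )
            ap, rc = _accumulate_class(per_image, IOU_THRESHOLDS)
            ap_cls.append(ap)
            rc_cls.append(rc)
            ap50_cls[cid] = float(ap[0])
        ap_cls = np.asarray(ap_cls)         # (C, T)
        rc_cls = np.asarray(rc_cls)
        with np.errstate(invalid="ignore"):
            return ap_cls, rc_cls, ap50_cls

    ap_all, rc_all, ap50_table = run(None, 100)
    ap_small, rc_small, _ = run((0.0, SMALL_AREA_MAX), 100)
    _, rc_10, _ = run(None, 10)

    def nm(x):
        return float(np.nanmean(x)) if not np.all(np.isnan(x)) else float("nan")

    return MetricsReport(
        AP=nm(ap_all),
        AP50=nm(ap_all[:, 0]),
        APs=nm(ap_small),
        AR10=nm(rc_10),
        AR100=nm(rc_all),
        ARs=nm(rc_small),
        per_class_ap50=ap50_table,
    )


def average_recall(
    ground_truths: list[dict],
    detections: list[dict],
    category_ids: list[int],
    max_dets: int = 100,
) -> float:
    """AR at a detection budget: per-class mean recall over the ten IoU
    thresholds, then mean over classes with ground truth."""
    image_ids = sorted(
        {g["image_id"] for g in ground_truths} | {d["image_id"] for d in detections}
    )

    def corner(bbox):
        x, y, w, h = bbox
        return [x, y, x + w, y + h]

    recalls = []
    for cid in category_ids:
        per_image = []
        for img in image_ids:
            gts = [g for g in ground_truths if g["image_id"] == img and g["category_id"] == cid]
            dts = [d for d in detections if d["image_id"] == img and d["category_id"] == cid]
            gt_boxes = np.asarray([corner(g["bbox"]) for g in gts]).reshape(-1, 4)
            det_boxes = np.asarray([corner(d["bbox"]) for d in dts]).reshape(-1, 4)
            det_scores = np.asarray([d["score"] for d in dts], dtype=np.float64)
            per_image.append(
                _match_image(det_boxes, det_scores, gt_boxes,
                             np.zeros(len(gts), dtype=bool),
                             IOU_THRESHOLDS, max_dets, None)
            )
        _, rc = _accumulate_class(per_image, IOU_THRESHOLDS)
        if not np.all(np.isnan(rc)):
            recalls.append(np.nanmean(rc))
    return float(np.mean(recalls)) if recalls else float("nan")


# -----------------------------------------------------------------------------
# COCO-JSON file interface
# -----------------------------------------------------------------------------

def load_coco_ground_truth(path: str | Path) -> tuple[list[dict], list[int], dict[int, str]]:
    """Read a COCO-JSON annotation file; returns (annotations, category ids,
    id→name map)."""
    data = json.loads(Path(path).read_text())
    cids = [c["id"] for c in data.get("categories", [])]
    names = {c["id"]: c.get("name", str(c["id"])) for c in data.get("categories", [])}
    return data["annotations"], cids, names


def evaluate_files(gt_path: str | Path, det_path: str | Path) -> MetricsReport:
    """Evaluate a COCO-detection JSON file against a COCO annotation file."""
    gts, cids, _ = load_coco_ground_truth(gt_path)
    dets = json.loads(Path(det_path).read_text())
    return evaluate_detections(gts, dets, cids)
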