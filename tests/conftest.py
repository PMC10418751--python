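import numpy as np
import pytest

from graindet.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of a scalar-valued fn at x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return g


def random_boxes_int(rng, n, lo=0, hi=64, max_side=40):
    """Random boxes with integer corners (so pixel counting is exact)."""
    x1 = rng.integers(lo, hi - 2, size=n)
    y1 = rng.integers(lo, hi - 2, size=n)
    w = rng.integers(1, max_side, size=n)
    h = rng.integers(1, max_side, size=n)
    return np.stack([x1, y1, np.minimum(x1 + w, hi), np.minimum(y1 + h, hi)], axis=1).astype(float)


def raster_iou(a, b, size=128):
    """IoU by exact pixel counting for integer-corner boxes."""
    def mask(box):
        m = np.zeros((size, size), dtype=bool)
        x1, y1, x2, y2 = (int(v) for v in box)
        m[y1:y2, x1:x2] = True
        return m

    ma, mb = mask(a), mask(b)
    inter = (ma & mb).sum()
    union = (ma | mb).sum()
    return inter / union if union else 0.0


def brute_force_nms(boxes_corners, scores, threshold):
    """O(n²) reference NMS: repeatedly take the highest-score live box and
    kill everything overlapping it beyond the threshold."""
    from graindet.boxes import BoxArray, iou

    n = len(scores)
    mat = iou(BoxArray.from_corners(boxes_corners), BoxArray.from_corners(boxes_corners))
    alive = [True] * n
    keep = []
    while any(alive):
        best, best_score = -1, -np.inf
        for i in range(n):
            if alive[i] and scores[i] > best_score:
                best, best_score = i, scores[i]
        keep.append(best)
        alive[best] = False
        for j in range(n):
            if alive[j] and mat[best, j] > threshold:
                alive[j] = False
    return keep


def naive_coco_eval(gts, dets, category_ids):
    """Independent slow evaluator: per class and IoU threshold, match
    detections in global score order against unmatched ground truths in the
    same image (best IoU >= t), then 101-point interpolated AP and final
    recall.  Returns (AP, AP50, AR100-style mean recall)."""
    from graindet.boxes import BoxArray, iou as iou_fn

    thresholds = [0.5 + 0.05 * i for i in range(10)]
    recall_points = [i / 100 for i in range(101)]
    ap_per, rc_per = [], []
    for cid in category_ids:
        class_gts = [g for g in gts if g["category_id"] == cid]
        class_dts = sorted(
            (d for d in dets if d["category_id"] == cid),
            key=lambda d: -d["score"],
        )
        n_gt = len(class_gts)
        if n_gt == 0:
            continue
        ap_t, rc_t = [], []
        for t in thresholds:
            matched_gt = set()
            flags = []
            for d in class_dts:
                dx, dy, dw, dh = d["bbox"]
                best_iou, best_g = 0.0, None
                for gi, gbox in enumerate(class_gts):
                    if gi in matched_gt or gbox["image_id"] != d["image_id"]:
                        continue
                    gx, gy, gw, gh = gbox["bbox"]
                    val = iou_fn(
                        BoxArray.from_corners([[dx, dy, dx + dw, dy + dh]]),
                        BoxArray.from_corners([[gx, gy, gx + gw, gy + gh]]),
                    )[0, 0]
                    if val >= t and val > best_iou:
                        best_iou, best_g = val, gi
                if best_g is not None:
                    matched_gt.add(best_g)
                    flags.append(1)
                else:
                    flags.append(0)
            # precision-recall
            tp = fp = 0
            prs = []
            for f in flags:
                tp += f
                fp += 1 - f
                prs.append((tp / n_gt, tp / (tp + fp)))
            # interpolated precision at 101 recall points
            ap_vals = []
            for r in recall_points:
                candidates = [p for (rec, p) in prs if rec >= r - 1e-12]
                ap_vals.append(max(candidates) if candidates else 0.0)
            ap_t.append(sum(ap_vals) / len(ap_vals))
            rc_t.append(tp / n_gt)
        ap_per.append(ap_t)
        rc_per.append(rc_t)
    ap = float(np.mean(ap_per))
    ap50 = float(np.mean([row[0] for row in ap_per]))
    ar = float(np.mean(rc_per))
    return ap, ap50, ar


def random_detection_fixture(rng, n_images=3, n_classes=2, size=100):
    """A random small detection problem: ground truths plus noisy detections."""
    gts, dets = [], []
    for img in range(n_images):
        for _ in range(int(rng.integers(1, 5))):
            cid = int(rng.integers(1, n_classes + 1))
            box = random_boxes_int(rng, 1, hi=size, max_side=40)[0]
            bbox = [box[0], box[1], box[2] - box[0], box[3] - box[1]]
            gts.append({"image_id": img, "category_id": cid, "bbox": bbox,
                        "area": bbox[2] * bbox[3]})
            if rng.random() < 0.8:     # noisy matching detection
                jitter = rng.normal(0, 2, 4)
                dets.append({"image_id": img, "category_id": cid,
                             "bbox": [bbox[0] + jitter[0], bbox[1] + jitter[1],
                                      max(2.0, bbox[2] + jitter[2]),
                                      max(2.0, bbox[3] + jitter[3])],
                             "score": float(rng.random())})
        for _ in range(int(rng.integers(0, 3))):   # false positives
            cid = int(rng.integers(1, n_classes + 1))
            box = random_boxes_int(rng, 1, hi=size, max_side=30)[0]
            dets.append({"image_id": img, "category_id": cid,
                         "bbox": [box[0], box[1], box[2] - box[0], box[3] - box[1]],
                         "score": float(rng.random())})
    return gts, dets
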