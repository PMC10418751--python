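"""Synthetic impurity-containing grain scenes with COCO-JSON ground truth.

Real imagery of grain cleaning streams is not redistributable, so this module
renders stand-in scenes that preserve the statistics that matter to a tiny-
object detector: a textured soil-toned background with a brightness gradient,
3–10 objects per 600×600 image drawn from the class inventory of a maize
cleaning stream (normal kernels plus damaged/rotten kernels, cob fragments,
husks, weeds and stones), a configurable share of objects below the 64² px²
tiny-object limit, and bounded pairwise overlap.  Every rendered object is
annotated with a tight bounding box.

The augmentation suite covers 90°-multiple rotations, vertical and horizontal
mirroring, brightness/contrast adjustment, Gaussian noise and salt-and-pepper
noise; geometric operations transform the boxes consistently with the pixels,
photometric ones leave them untouched.  All operations are deterministic
given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from .boxes import BoxArray, iou

DEFAULT_CLASSES = ("kernel", "damaged", "rotten", "cob", "husk", "weed", "stone")

#: per-class render style: shape, base RGB, aspect (h/w) range, max area px²
_STYLES = {
    "kernel": ("ellipse", (230, 190, 60), (0.7, 1.4), 90.0**2),
    "damaged": ("polygon", (180, 140, 50), (0.7, 1.5), 85.0**2),
    "rotten": ("ellipse", (90, 60, 30), (0.7, 1.4), 85.0**2),
    "cob": ("ellipse", (190, 80, 60), (2.0, 3.5), 220.0**2),
    "husk": ("polygon", (200, 200, 140), (2.5, 4.0), 180.0**2),
    "weed": ("polygon", (70, 140, 60), (1.5, 3.0), 120.0**2),
    "stone": ("polygon", (130, 130, 125), (0.8, 1.3), 100.0**2),
}
_FALLBACK_STYLE = ("ellipse", (160, 160, 160), (0.7, 1.4), 120.0**2)

TINY_AREA = 64.0**2


@dataclass
class SceneSpec:
    image_size: int = 600
    class_list: tuple[str, ...] = DEFAULT_CLASSES
    class_probs: tuple[float, ...] | None = None    # uniform when None
    objects_per_image: tuple[int, int] = (3, 10)
    tiny_fraction: float = 0.5
    max_overlap: float = 0.3        # max pairwise bbox IoU between objects
    margin: int = 4                 # keep boxes this far inside the frame

    def probs(self) -> np.ndarray:
        if self.class_probs is None:
            return np.full(len(self.class_list), 1.0 / len(self.class_list))
        p = np.asarray(self.class_probs, dtype=np.float64)
        return p / p.sum()


@dataclass
class ObjectSpec:
    cls: str
    shape: str
    w: float
    h: float
    cx: float
    cy: float
    orientation: float
    color: tuple[int, int, int]


@dataclass
class AnnotationRecord:
    image_id: int
    category_id: int
    bbox: tuple[float, float, float, float]     # x, y, w, h (top-left origin)
    area: float

    def to_coco(self, ann_id: int) -> dict:
        return {
            "id": ann_id,
            "image_id": self.image_id,
            "category_id": self.category_id,
            "bbox": [float(v) for v in self.bbox],
            "area": float(self.area),
            "iscrowd": 0,
        }


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([120, 100, 80], dtype=np.float64)
    noise = rng.normal(0, 18, size=(size, size))
    texture = ndimage.gaussian_filter(noise, sigma=3)
    gy, gx = np.mgrid[0:size, 0:size] / size
    angle = rng.uniform(0, 2 * np.pi)
    gradient = 25 * ((gx - 0.5) * np.cos(angle) + (gy - 0.5) * np.sin(angle))
    img = base[None, None, :] + texture[:, :, None] + gradient[:, :, None]
    img += rng.normal(0, 4, size=(size, size, 3))
    return np.clip(img, 0, 255)


def _sample_object(spec: SceneSpec, cls: str, rng: np.random.Generator) -> ObjectSpec:
    shape, color, aspect_rng, max_area = _STYLES.get(cls, _FALLBACK_STYLE)
    tiny = rng.random() < spec.tiny_fraction
    if tiny:
        area = rng.uniform(22.0**2, 62.0**2)
    else:
        area = rng.uniform(68.0**2, max(max_area, 70.0**2))
    aspect = rng.uniform(*aspect_rng)
    w = float(np.sqrt(area / aspect))
    h = float(w * aspect)
    limit = spec.image_size - 2 * spec.margin
    scale = min(1.0, limit / max(w, h))
    w, h = w * scale, h * scale
    jitter = rng.integers(-20, 21, size=3)
    col = tuple(int(np.clip(c + j, 0, 255)) for c, j in zip(color, jitter))
    cx = rng.uniform(spec.margin + w / 2, spec.image_size - spec.margin - w / 2)
    cy = rng.uniform(spec.margin + h / 2, spec.image_size - spec.margin - h / 2)
    return ObjectSpec(cls, shape, w, h, cx, cy, rng.uniform(0, np.pi), col)


def _render_object(img: np.ndarray, obj: ObjectSpec, rng: np.random.Generator):
    """Draw the object, return its tight bbox (x, y, w, h) or None if empty."""
    size = img.shape[0]
    if obj.shape == "ellipse":
        rr, cc = skdraw.ellipse(
            obj.cy, obj.cx, max(obj.h / 2, 1.0), max(obj.w / 2, 1.0),
            shape=(size, size), rotation=obj.orientation,
        )
    else:
        # convex-ish polygon: jittered points on the bounding ellipse
        k = int(rng.integers(5, 9))
        th = np.sort(rng.uniform(0, 2 * np.pi, k))
        radii = rng.uniform(0.7, 1.0, k)
        px = obj.w / 2 * radii * np.cos(th)
        py = obj.h / 2 * radii * np.sin(th)
        ca, sa = np.cos(obj.orientation), np.sin(obj.orientation)
        rx = obj.cx + px * ca - py * sa
        ry = obj.cy + px * sa + py * ca
        rr, cc = skdraw.polygon(ry, rx, shape=(size, size))
    if rr.size == 0:
        return None
    shade = rng.normal(1.0, 0.06, size=rr.size)
    for ch in range(3):
        img[rr, cc, ch] = np.clip(obj.color[ch] * shade, 0, 255)
    x1, x2 = int(cc.min()), int(cc.max()) + 1
    y1, y2 = int(rr.min()), int(rr.max()) + 1
    return (float(x1), float(y1), float(x2 - x1), float(y2 - y1))


def render_scene(
    spec: SceneSpec,
    seed: int,
    image_id: int = 0,
    max_retries: int = 50,
) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Render one scene deterministically; objects keep pairwise bbox IoU
    below ``spec.max_overlap`` (fewer objects are placed when packing fails)."""
    rng = np.random.default_rng(seed)
    img = _background(spec.image_size, rng)
    lo, hi = spec.objects_per_image
    n_objects = int(rng.integers(lo, hi + 1))
    classes = rng.choice(len(spec.class_list), size=n_objects, p=spec.probs())
    placed_boxes: list[tuple] = []
    records: list[AnnotationRecord] = []
    for ci in classes:
        cls = spec.class_list[int(ci)]
        bbox = None
        for _ in range(max_retries):
            obj = _sample_object(spec, cls, rng)
            cand = (obj.cx - obj.w / 2, obj.cy - obj.h / 2, obj.w, obj.h)
            if placed_boxes:
                overlaps = iou(BoxArray.from_xywh(np.asarray([cand])),
                               BoxArray.from_xywh(np.asarray(placed_boxes)))
                if overlaps.max() > spec.max_overlap:
                    continue
            bbox = _render_object(img, obj, rng)
            break
        if bbox is None:
            warnings.warn(f"could not place a {cls} object; scene has fewer objects",
                          stacklevel=2)
            continue
        placed_boxes.append(bbox)
        records.append(
            AnnotationRecord(
                image_id=image_id,
                category_id=int(ci) + 1,
                bbox=bbox,
                area=bbox[2] * bbox[3],
            )
        )
    return img.astype(np.uint8), records


# -----------------------------------------------------------------------------
# augmentation suite
# -----------------------------------------------------------------------------

AUGMENT_OPS = ("rotate90k", "mirror_h", "mirror_v", "brightness_contrast",
               "gaussian_noise", "salt_pepper")


def _transform_bbox(bbox, op: str, k: int, size: int):
    x, y, w, h = bbox
    x2, y2 = x + w, y + h
    if op == "mirror_h":
        return (size - x2, y, w, h)
    if op == "mirror_v":
        return (x, size - y2, w, h)
    if op == "rotate90k":
        for _ in range(k % 4):
            # one counter-clockwise quarter turn: (x1,y1,x2,y2) -> (y1, S-x2, y2, S-x1)
            x, y, x2, y2 = y, size - x2, y2, size - x
        return (x, y, x2 - x, y2 - y)
    return bbox


def augment(
    image: np.ndarray,
    annotations: list[AnnotationRecord],
    op: str,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Apply one augmentation; geometric ops move boxes with the pixels."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    size = image.shape[0]
    img = image
    k = int(params.get("k", 1))
    if op == "rotate90k":
        img = np.rot90(image, k).copy()
    elif op == "mirror_h":
        img = np.fliplr(image).copy()
    elif op == "mirror_v":
        img = np.flipud(image).copy()
    elif op == "brightness_contrast":
        alpha = float(params.get("alpha", 1.0))
        beta = float(params.get("beta", 0.0))
        img = np.clip(alpha * (image.astype(np.float64) - 128.0) + 128.0 + beta,
                      0, 255).astype(np.uint8)
    elif op == "gaussian_noise":
        sigma = float(params.get("sigma", 10.0))
        img = np.clip(image.astype(np.float64) + rng.normal(0, sigma, image.shape),
                      0, 255).astype(np.uint8)
    elif op == "salt_pepper":
        density = float(params.get("density", 0.02))
        img = image.copy()
        if density > 0:
            mask = rng.random(image.shape[:2])
            img[mask < density / 2] = 0
            img[(mask >= density / 2) & (mask < density)] = 255
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    if op in ("rotate90k", "mirror_h", "mirror_v"):
        new_anns = []
        for a in annotations:
            bbox = _transform_bbox(a.bbox, op, k, size)
            new_anns.append(
                AnnotationRecord(a.image_id, a.category_id,
                                 tuple(float(v) for v in bbox), bbox[2] * bbox[3])
            )
        return img, new_anns
    return img, [AnnotationRecord(a.image_id, a.category_id, a.bbox, a.area)
                 for a in annotations]


# -----------------------------------------------------------------------------
# dataset assembly
# -----------------------------------------------------------------------------

@dataclass
class DatasetPaths:
    root: Path
    train_images: Path
    test_images: Path
    train_json: Path
    test_json: Path
    manifest: Path


def _write_coco(path: Path, images: list[dict], annotations: list[dict],
                class_list: tuple[str, ...]):
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i + 1, "name": n} for i, n in enumerate(class_list)],
    }
    path.write_text(json.dumps(payload))


def build_dataset(
    out_dir: str | Path,
    n_base: int,
    augmentations_per_image: int = 0,
    split_ratio: tuple[int, int] = (3, 1),
    spec: SceneSpec | None = None,
    seed: int = 0,
) -> DatasetPaths:
    """Generate base scenes plus augmented variants and split them
    train:test at the base-scene level (all variants of a scene stay on one
    side, so augmentation never leaks across the split)."""
    if n_base < 4:
        raise ValueError("n_base must be >= 4")
    spec = spec or SceneSpec()
    out = Path(out_dir)
    train_img_dir = out / "train" / "images"
    test_img_dir = out / "test" / "images"
    train_img_dir.mkdir(parents=True, exist_ok=True)
    test_img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_base)
    n_train = int(round(n_base * split_ratio[0] / sum(split_ratio)))
    train_base = set(order[:n_train].tolist())

    splits = {"train": ([], []), "test": ([], [])}   # (images, annotations)
    next_image_id = {"train": 0, "test": 0}
    next_ann_id = {"train": 0, "test": 0}
    aug_rng = np.random.default_rng(seed + 1)

    def emit(side: str, img: np.ndarray, anns: list[AnnotationRecord], name: str):
        images, annotations = splits[side]
        iid = next_image_id[side]
        next_image_id[side] += 1
        fname = f"{name}.png"
        target = train_img_dir if side == "train" else test_img_dir
        Image.fromarray(img).save(target / fname)
        images.append({"id": iid, "file_name": fname,
                       "width": img.shape[1], "height": img.shape[0]})
        for a in anns:
            rec = AnnotationRecord(iid, a.category_id, a.bbox, a.area)
            annotations.append(rec.to_coco(next_ann_id[side]))
            next_ann_id[side] += 1

    for i in range(n_base):
        side = "train" if i in train_base else "test"
        scene_seed = int(seed) * 1_000_003 % (2**31) + i
        img, anns = render_scene(spec, scene_seed)
        emit(side, img, anns, f"scene{i:05d}")
        for v in range(augmentations_per_image):
            op = AUGMENT_OPS[int(aug_rng.integers(len(AUGMENT_OPS)))]
            params = {
                "k": int(aug_rng.integers(1, 4)),
                "alpha": float(aug_rng.uniform(0.8, 1.2)),
                "beta": float(aug_rng.uniform(-20, 20)),
                "sigma": 10.0,
                "density": 0.02,
            }
            aug_img, aug_anns = augment(img, anns, op, params,
                                        seed=scene_seed + 7919 * (v + 1))
            emit(side, aug_img, aug_anns, f"scene{i:05d}_aug{v}")

    train_json = out / "train" / "annotations.json"
    test_json = out / "test" / "annotations.json"
    _write_coco(train_json, *splits["train"], spec.class_list)
    _write_coco(test_json, *splits["test"], spec.class_list)
    manifest = out / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({
        "seed": int(seed),
        "n_base": int(n_base),
        "augmentations_per_image": int(augmentations_per_image),
        "split_ratio": list(split_ratio),
        "n_train_base": int(n_train),
        "image_size": spec.image_size,
        "class_list": list(spec.class_list),
        "objects_per_image": list(spec.objects_per_image),
        "tiny_fraction": float(spec.tiny_fraction),
    }))
    return DatasetPaths(out, train_img_dir, test_img_dir, train_json, test_json, manifest)


def load_split(json_path: str | Path) -> tuple[list[dict], list[dict], list[int]]:
    """Read a split's COCO JSON: (images, annotations, category ids)."""
    data = json.loads(Path(json_path).read_text())
    return data["images"], data["annotations"], [c["id"] for c in data["categories"]]
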