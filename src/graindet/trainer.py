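"""Detector assembly and the alternating training procedure.

The full network chains the feature learning backbone, the cross-stage
integrator, the ARPN and the candidate-box head.  Training follows the
four-phase alternating optimization:

1. train the ARPN end-to-end (its own backbone copy);
2. re-initialize the feature learning network and train the detector on the
   proposals generated by the phase-1 ARPN;
3. share the detector's convolutional layers (frozen) and fine-tune the
   layers unique to the ARPN;
4. fine-tune the layers unique to the detector, forming a unified network.

Task-specific layers initialize from a zero-mean Gaussian with standard
deviation 0.01 (biases zero).  Updates use stochastic gradient descent with
momentum.  Learning rates and per-phase epoch counts are configuration
values.  A single-phase approximate-joint mode is offered as a convenience;
it is not the reference schedule.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .arpn import (
    AnchorGridSpec,
    Proposal,
    ProposalConfig,
    RPNHead,
    generate_anchors,
    generate_proposals,
    label_anchors,
    rpn_loss,
    sample_minibatch,
)
from .backbone import Backbone, BackboneConfig, FeatureGrid
from .boxes import BoxArray
from .integration import IntegrationConfig, Integrator
from .metrics import MetricsReport, evaluate_detections
from .nn import SGD, Conv2d, Linear, Module, Tensor
from .roihead import (
    DetHead,
    DetLossConfig,
    Detection,
    PostprocessConfig,
    RoI,
    assign_rois,
    det_loss,
    postprocess,
    roi_pool,
)
from .synthgrain import DatasetPaths, load_split

logger = logging.getLogger("graindet")


@dataclass
class DetectorConfig:
    """Everything needed to assemble the two-stage detector."""

    num_classes: int = 7                    # foreground classes k
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    proposals: ProposalConfig = field(default_factory=ProposalConfig)
    det: DetLossConfig = field(default_factory=DetLossConfig)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)
    anchors_per_cell: int = 9
    area_scales: tuple[float, ...] = (64.0**2, 128.0**2, 256.0**2)
    aspect_ratios: tuple[float, ...] = (1.0, 0.5, 2.0)
    roi_output_size: int = 7
    head_hidden: int = 1024
    add_gt_to_proposals: bool = True

    @classmethod
    def tiny(cls, num_classes: int = 1) -> "DetectorConfig":
        """Desk-scale variant: 1/8-width backbone, 152 px input, slimmer heads."""
        return cls(
            num_classes=num_classes,
            backbone=BackboneConfig.tiny(),
            integration=IntegrationConfig(fused_channels=48),
            det=DetLossConfig(rois_per_image=64),
            roi_output_size=5,
            head_hidden=128,
        )


class GrainDetector(Module):
    """Backbone + integrator + ARPN + candidate-box head."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = Backbone(config.backbone, rng=rng)
        tap_channels = {spec.index: spec.out_channels for spec in self.backbone.specs}
        self.integrator = Integrator(config.integration, tap_channels, rng=rng)
        n = len(config.area_scales) * len(config.aspect_ratios)
        self.rpn = RPNHead(config.integration.fused_channels, n, rng=rng)
        in_features = config.integration.fused_channels * config.roi_output_size**2
        self.head = DetHead(in_features, config.num_classes,
                            hidden=config.head_hidden, rng=rng)
        init_task_layers(self, seed=int(rng.integers(2**31)))

    # -- plumbing --------------------------------------------------------------
    def preprocess(self, image: np.ndarray) -> Tensor:
        """HWC uint8/float image → normalized NCHW tensor in [-1, 1]."""
        x = np.asarray(image, dtype=np.float32) / 127.5 - 1.0
        return Tensor(x.transpose(2, 0, 1)[None])

    def features(self, x: Tensor) -> FeatureGrid:
        return self.integrator(self.backbone(x))

    def anchor_spec(self, integrated: FeatureGrid) -> AnchorGridSpec:
        return AnchorGridSpec(
            grid_height=integrated.height,
            grid_width=integrated.width,
            stride=integrated.stride,
            area_scales=self.config.area_scales,
            aspect_ratios=self.config.aspect_ratios,
        )

    # -- inference -------------------------------------------------------------
    def detect(self, image: np.ndarray) -> list[Detection]:
        """End-to-end detection on one HWC image."""
        self.eval()
        size = image.shape[0]
        with nn.no_grad():
            integrated = self.features(self.preprocess(image))
            out = self.rpn(integrated)
            anchors = generate_anchors(self.anchor_spec(integrated))
            proposals = generate_proposals(out, anchors, (size, size),
                                           mode="test", config=self.config.proposals)
            if not proposals:
                return []
            rois = [RoI(p.box, p.score) for p in proposals]
            pooled = roi_pool(integrated, rois, self.config.roi_output_size)
            head_out = self.head(pooled)
        return postprocess(head_out, rois, (size, size), self.config.post)


def init_task_layers(model: GrainDetector, seed: int = 0):
    """Re-initialize ARPN and detection-head weights ~ N(0, 0.01²), biases 0.

    The backbone keeps its own initialization (or pretrained weights)."""
    rng = np.random.default_rng(seed)
    for module in (model.rpn, model.head):
        for _, m in module.named_modules():
            if isinstance(m, (Conv2d, Linear)):
                m.weight.data = rng.normal(0.0, 0.01, m.weight.data.shape).astype(np.float32)
                if m.bias is not None:
                    m.bias.data[...] = 0.0
    return model


# -----------------------------------------------------------------------------
# training schedule
# -----------------------------------------------------------------------------

@dataclass
class PhaseSpec:
    name: str
    scope: str           # arpn | detector | arpn_unique | detector_unique
    epochs: int = 1
    lr: float = 0.01
    momentum: float = 0.9


def default_phases(epochs: tuple[int, int, int, int] = (2, 2, 1, 1),
                   lr: float = 0.01) -> list[PhaseSpec]:
    return [
        PhaseSpec("train-arpn", "arpn", epochs[0], lr),
        PhaseSpec("train-detector", "detector", epochs[1], lr),
        PhaseSpec("finetune-arpn", "arpn_unique", epochs[2], lr / 10),
        PhaseSpec("finetune-detector", "detector_unique", epochs[3], lr / 10),
    ]


@dataclass
class TrainConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    phases: list[PhaseSpec] = field(default_factory=default_phases)
    seed: int = 0
    log_path: str | Path | None = None
    checkpoint_dir: str | Path | None = None

    def validate(self):
        scopes = [p.scope for p in self.phases]
        if scopes != ["arpn", "detector", "arpn_unique", "detector_unique"]:
            raise ValueError(
                "the reference schedule has exactly 4 phases "
                "(arpn, detector, arpn_unique, detector_unique); got " + repr(scopes)
            )

    @classmethod
    def smoke(cls, seed: int = 0, **kwargs) -> "TrainConfig":
        """Desk-scale regime: tiny detector, single blob class, short schedule."""
        return cls(
            detector=DetectorConfig.tiny(num_classes=1),
            phases=default_phases(epochs=(3, 3, 1, 1), lr=0.02),
            seed=seed,
            **kwargs,
        )


@dataclass
class Checkpoint:
    phase_index: int                       # number of completed phases
    weights: dict[str, np.ndarray]         # "netA/..." and "netB/..." entries
    loss_history: list[dict]

    def save(self, path: str | Path):
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.weights)
        path.with_suffix(".json").write_text(json.dumps({
            "phase_index": self.phase_index,
            "loss_history": self.loss_history,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            weights = {k: z[k] for k in z.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(meta["phase_index"], weights, meta["loss_history"])


def _split_weights(net_a: GrainDetector, net_b: GrainDetector) -> dict[str, np.ndarray]:
    out = {}
    for prefix, net in (("netA/", net_a), ("netB/", net_b)):
        for k, v in net.state_dict().items():
            out[prefix + k] = v
    return out


class _JsonlLog:
    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.write_text("")

    def write(self, record: dict):
        logger.info("%s", record)
        if self.path:
            with self.path.open("a") as f:
                f.write(json.dumps(record) + "\n")


class _TrainingData:
    """In-memory split: images plus per-image ground truth."""

    def __init__(self, image_dir: Path, json_path: Path):
        images, annotations, self.category_ids = load_split(json_path)
        self.images = []
        self.gt_boxes: list[BoxArray] = []
        self.gt_labels: list[np.ndarray] = []
        by_image: dict[int, list] = {}
        for a in annotations:
            by_image.setdefault(a["image_id"], []).append(a)
        self.annotations = annotations
        self.image_records = images
        for rec in images:
            arr = np.asarray(Image.open(Path(image_dir) / rec["file_name"]))
            self.images.append(arr)
            anns = by_image.get(rec["id"], [])
            self.gt_boxes.append(
                BoxArray.from_xywh(np.asarray([a["bbox"] for a in anns]).reshape(-1, 4))
            )
            self.gt_labels.append(np.asarray([a["category_id"] for a in anns], dtype=np.int64))

    def __len__(self):
        return len(self.images)


def _check_finite(loss_value: float, phase: str, image_index: int, log: _JsonlLog):
    if not np.isfinite(loss_value):
        log.write({"event": "nan_loss", "phase": phase, "image_index": image_index})
        raise RuntimeError(
            f"non-finite loss in phase {phase!r} on image {image_index}; "
            "diagnostic record written to the training log"
        )


def _rpn_iteration(net: GrainDetector, image, gt, rng, train_backbone: bool):
    size = image.shape[0]
    x = net.preprocess(image)
    if train_backbone:
        integrated = net.features(x)
    else:
        with nn.no_grad():
            integrated = net.features(x)
    out = net.rpn(integrated)
    anchors = generate_anchors(net.anchor_spec(integrated))
    targets = label_anchors(anchors, gt, image_size=(size, size))
    targets = sample_minibatch(targets, rng)
    return rpn_loss(out, targets)


def _detector_iteration(net: GrainDetector, proposal_net: GrainDetector,
                        image, gt, labels, rng, train_backbone: bool):
    size = image.shape[0]
    x = net.preprocess(image)
    proposal_net.eval()
    with nn.no_grad():
        p_feat = proposal_net.features(x)
        p_out = proposal_net.rpn(p_feat)
        anchors = generate_anchors(proposal_net.anchor_spec(p_feat))
        proposals = generate_proposals(p_out, anchors, (size, size), mode="train",
                                       config=net.config.proposals)
    if net.config.add_gt_to_proposals and len(gt):
        proposals = proposals + [Proposal(box=c, score=1.0) for c in gt.corners()]
    if not proposals:
        return None
    batch = assign_rois(proposals, gt, labels, net.config.det, rng)
    if not batch.rois:
        return None
    if train_backbone:
        net.train()
        integrated = net.features(x)
    else:
        with nn.no_grad():
            integrated = net.features(x)
    pooled = roi_pool(integrated, batch.rois, net.config.roi_output_size)
    head_out = net.head(pooled)
    return det_loss(head_out.class_probs, batch.labels, head_out.regression,
                    batch.regression_targets, net.config.det)


def train_alternating(
    dataset: DatasetPaths | str | Path,
    config: TrainConfig,
    resume: Checkpoint | None = None,
) -> tuple[Checkpoint, MetricsReport | None]:
    """Run the four-phase alternating schedule; returns the final checkpoint
    and the metrics report on the held-out split."""
    config.validate()
    root = dataset.root if isinstance(dataset, DatasetPaths) else Path(dataset)
    train_data = _TrainingData(root / "train" / "images", root / "train" / "annotations.json")
    log = _JsonlLog(config.log_path)

    net_a = GrainDetector(config.detector, seed=config.seed)          # phase-1 ARPN
    net_b = GrainDetector(config.detector, seed=config.seed + 1)      # unified network
    history: list[dict] = []
    start_phase = 0
    if resume is not None:
        start_phase = resume.phase_index
        history = list(resume.loss_history)
        net_a.load_state_dict({k[5:]: v for k, v in resume.weights.items()
                               if k.startswith("netA/")})
        net_b.load_state_dict({k[5:]: v for k, v in resume.weights.items()
                               if k.startswith("netB/")})

    for pi, phase in enumerate(config.phases):
        if pi < start_phase:
            continue
        t0 = time.time()
        log.write({"event": "phase_start", "phase": phase.name, "scope": phase.scope,
                   "epochs": phase.epochs, "lr": phase.lr})
        rng = np.random.default_rng((config.seed * 10 + pi) % (2**31))
        if phase.scope == "arpn":
            net = net_a
            net.train()
            params = (net.backbone.parameters() + net.integrator.parameters()
                      + net.rpn.parameters())
        elif phase.scope == "detector":
            net = net_b
            net.train()
            params = (net.backbone.parameters() + net.integrator.parameters()
                      + net.head.parameters())
        elif phase.scope == "arpn_unique":
            # convolutional layers are now shared and frozen
            net_b.rpn.load_state_dict(net_a.rpn.state_dict())
            net = net_b
            net.eval()
            net.rpn.train()
            params = net.rpn.parameters()
        else:  # detector_unique
            net = net_b
            net.eval()
            net.head.train()
            params = net.head.parameters()
        opt = SGD(params, lr=phase.lr, momentum=phase.momentum)
        for epoch in range(phase.epochs):
            order = rng.permutation(len(train_data))
            epoch_losses = []
            for ii in order:
                image = train_data.images[ii]
                gt = train_data.gt_boxes[ii]
                labels = train_data.gt_labels[ii]
                if phase.scope in ("arpn", "arpn_unique"):
                    result = _rpn_iteration(net, image, gt, rng,
                                            train_backbone=phase.scope == "arpn")
                else:
                    source = net_a if phase.scope == "detector" else net_b
                    result = _detector_iteration(net, source, image, gt, labels, rng,
                                                 train_backbone=phase.scope == "detector")
                    if phase.scope == "detector_unique":
                        net.head.train()
                if result is None:
                    continue
                loss, breakdown = result
                _check_finite(float(loss.data), phase.name, int(ii), log)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(breakdown["total"])
            rec = {"event": "epoch", "phase": phase.name, "epoch": epoch,
                   "mean_loss": float(np.mean(epoch_losses)) if epoch_losses else None}
            history.append(rec)
            log.write(rec)
        log.write({"event": "phase_end", "phase": phase.name,
                   "seconds": round(time.time() - t0, 2)})
        if config.checkpoint_dir:
            ckpt = Checkpoint(pi + 1, _split_weights(net_a, net_b), history)
            ckpt.save(Path(config.checkpoint_dir) / f"phase{pi + 1}")

    final = Checkpoint(len(config.phases), _split_weights(net_a, net_b), history)
    report = evaluate(net_b, root / "test")
    log.write({"event": "evaluation", **report.to_dict()})
    return final, report


def train_joint(
    dataset: DatasetPaths | str | Path,
    config: TrainConfig,
) -> tuple[GrainDetector, MetricsReport]:
    """Approximate joint training: a single phase alternating RPN and
    detector losses per image.  A convenience mode, not the reference
    four-phase schedule."""
    root = dataset.root if isinstance(dataset, DatasetPaths) else Path(dataset)
    train_data = _TrainingData(root / "train" / "images", root / "train" / "annotations.json")
    log = _JsonlLog(config.log_path)
    net = GrainDetector(config.detector, seed=config.seed)
    total_epochs = sum(p.epochs for p in config.phases)
    rng = np.random.default_rng(config.seed)
    opt = SGD(net.parameters(), lr=config.phases[0].lr, momentum=config.phases[0].momentum)
    for epoch in range(total_epochs):
        order = rng.permutation(len(train_data))
        for ii in order:
            image, gt = train_data.images[ii], train_data.gt_boxes[ii]
            labels = train_data.gt_labels[ii]
            net.train()
            loss_r, _ = _rpn_iteration(net, image, gt, rng, train_backbone=True)
            result = _detector_iteration(net, net, image, gt, labels, rng,
                                         train_backbone=True)
            loss = loss_r if result is None else loss_r + result[0]
            _check_finite(float(loss.data), "joint", int(ii), log)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return net, evaluate(net, root / "test")


def build_from_checkpoint(checkpoint: Checkpoint, config: DetectorConfig) -> GrainDetector:
    """Materialize the unified network from a checkpoint."""
    net = GrainDetector(config, seed=0)
    net.load_state_dict({k[5:]: v for k, v in checkpoint.weights.items()
                         if k.startswith("netB/")})
    return net


def evaluate(
    model: GrainDetector | tuple[Checkpoint, DetectorConfig],
    split_dir: str | Path,
) -> MetricsReport:
    """Run detection over a dataset split and score it COCO-style."""
    if isinstance(model, tuple):
        model = build_from_checkpoint(*model)
    split_dir = Path(split_dir)
    images, annotations, category_ids = load_split(split_dir / "annotations.json")
    detections = []
    for rec in images:
        arr = np.asarray(Image.open(split_dir / "images" / rec["file_name"]))
        for det in model.detect(arr):
            detections.append(det.to_coco(rec["id"]))
    return evaluate_detections(annotations, detections, category_ids,
                               image_ids=[r["id"] for r in images])
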