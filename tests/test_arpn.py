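"""Adaptive region proposal network: anchor geometry, labeling, sampling,
regression transforms, losses, head wiring and proposal generation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graindet import nn
from graindet.arpn import (
    IGNORE,
    AnchorGridSpec,
    ProposalConfig,
    RPNHead,
    RPNOutput,
    RPNTargets,
    cross_boundary_mask,
    generate_anchors,
    generate_proposals,
    label_anchors,
    rpn_loss,
    sample_minibatch,
)
from graindet.backbone import FeatureGrid
from graindet.boxes import BoxArray, decode_boxes, encode_boxes, iou, nms, smooth_l1
from graindet.nn import Tensor

from conftest import brute_force_nms, random_boxes_int, raster_iou


class TestAnchors:
    def test_default_grid_census(self):
        spec = AnchorGridSpec()
        anchors = generate_anchors(spec)
        assert spec.total == len(anchors) == 75 * 75 * 9

    def test_single_cell_anchor_geometry(self):
        spec = AnchorGridSpec(grid_height=1, grid_width=1, stride=8,
                              area_scales=(64.0**2,), aspect_ratios=(1.0,))
        a = generate_anchors(spec)
        assert len(a) == 1
        assert a.w[0] == a.h[0] == 64.0
        assert (a.cx[0], a.cy[0]) == (4.0, 4.0)

    def test_area_and_ratio_satisfied(self):
        # h:w = 2:1 at area 128² solves to w = 128/sqrt(2), h = 2w
        spec = AnchorGridSpec(grid_height=1, grid_width=1,
                              area_scales=(128.0**2,), aspect_ratios=(2.0,))
        a = generate_anchors(spec)
        assert math.isclose(a.w[0], 128 / math.sqrt(2), rel_tol=1e-12)
        assert math.isclose(a.h[0], 2 * a.w[0], rel_tol=1e-12)
        assert math.isclose(a.w[0] * a.h[0], 128.0**2, abs_tol=1e-6)

    def test_every_scale_ratio_combination_present(self):
        spec = AnchorGridSpec(grid_height=2, grid_width=3)
        a = generate_anchors(spec)
        areas = np.unique(np.round(a.areas(), 3))
        assert np.allclose(sorted(areas), [64.0**2, 128.0**2, 256.0**2])
        ratios = np.unique(np.round(a.h / a.w, 6))
        assert np.allclose(sorted(ratios), [0.5, 1.0, 2.0])


class TestIoU:
    def test_identical_and_disjoint(self):
        a = BoxArray.from_corners([[0, 0, 10, 10]])
        b = BoxArray.from_corners([[20, 20, 30, 30]])
        assert iou(a, a)[0, 0] == 1.0
        assert iou(a, b)[0, 0] == 0.0

    def test_matches_pixel_rasterization_oracle(self, rng):
        boxes_a = random_boxes_int(rng, 30, hi=100)
        boxes_b = random_boxes_int(rng, 30, hi=100)
        mat = iou(BoxArray.from_corners(boxes_a), BoxArray.from_corners(boxes_b))
        for i in range(0, 30, 3):
            for j in range(0, 30, 3):
                assert abs(mat[i, j] - raster_iou(boxes_a[i], boxes_b[j])) < 1e-3

    def test_symmetry(self, rng):
        boxes = BoxArray.from_corners(random_boxes_int(rng, 12, hi=80))
        mat = iou(boxes, boxes)
        assert np.allclose(mat, mat.T)

    def test_degenerate_box_warns_and_scores_zero(self):
        a = BoxArray.from_corners([[0, 0, 0, 10]])
        b = BoxArray.from_corners([[0, 0, 10, 10]])
        with pytest.warns(UserWarning, match="degenerate"):
            assert iou(a, b)[0, 0] == 0.0


class TestLabeling:
    def _anchors(self):
        return generate_anchors(AnchorGridSpec(grid_height=10, grid_width=10, stride=8,
                                               area_scales=(32.0**2,),
                                               aspect_ratios=(1.0,)))

    def test_identical_anchor_is_positive(self):
        anchors = self._anchors()
        gt = anchors[[45]]
        t = label_anchors(anchors, gt)
        assert t.labels[45] == 1

    def test_low_overlap_everywhere_is_negative(self):
        anchors = BoxArray.from_corners([[0, 0, 10, 10]])
        gt = BoxArray.from_corners([[8, 8, 30, 30]])   # IoU ≈ 0.007
        t = label_anchors(anchors, gt)
        assert t.labels[0] == 1     # argmax rule: sole anchor is the best for the gt
        # with another, better anchor present the weak one becomes negative
        anchors2 = BoxArray.from_corners([[0, 0, 10, 10], [8, 8, 30, 30]])
        t2 = label_anchors(anchors2, gt)
        assert t2.labels[0] == 0 and t2.labels[1] == 1

    def test_argmax_rule_promotes_below_threshold_anchor(self):
        # best anchor reaches IoU 0.5 < 0.7 yet must be positive
        anchors = BoxArray.from_corners([[0, 0, 10, 20], [50, 50, 60, 60]])
        gt = BoxArray.from_corners([[0, 0, 10, 10]])
        mat = iou(anchors, gt)
        assert abs(mat[0, 0] - 0.5) < 1e-9
        t = label_anchors(anchors, gt)
        assert t.labels[0] == 1

    def test_intermediate_overlap_is_ignored(self):
        # IoU 0.5 with one gt while another anchor is that gt's argmax
        anchors = BoxArray.from_corners([[0, 0, 10, 20], [0, 0, 10, 11], [50, 0, 60, 10]])
        gt = BoxArray.from_corners([[0, 0, 10, 10]])
        t = label_anchors(anchors, gt)
        assert t.labels[1] == 1      # argmax (IoU 10/11)
        assert t.labels[0] == IGNORE  # 0.3 < 0.5 < 0.7, not argmax
        assert t.labels[2] == 0

    def test_cross_boundary_anchors_ignored_in_training(self):
        anchors = BoxArray.from_corners([[-5, 0, 15, 20], [20, 20, 40, 40]])
        gt = BoxArray.from_corners([[-5, 0, 15, 20]])
        t = label_anchors(anchors, gt, image_size=(100, 100))
        assert t.labels[0] == IGNORE    # crosses the boundary, even though IoU = 1
        mask = cross_boundary_mask(anchors, (100, 100))
        assert mask.tolist() == [True, False]

    def test_empty_gt_makes_in_bounds_anchors_negative(self):
        anchors = BoxArray.from_corners([[-5, 0, 15, 20], [20, 20, 40, 40]])
        t = label_anchors(anchors, BoxArray([], [], [], []), image_size=(100, 100))
        assert t.labels.tolist() == [IGNORE, 0]

    def test_every_gt_gets_a_positive_anchor(self, rng):
        anchors = generate_anchors(AnchorGridSpec(grid_height=19, grid_width=19, stride=8))
        gt = BoxArray.from_xywh(np.column_stack([
            rng.uniform(10, 90, 5), rng.uniform(10, 90, 5),
            rng.uniform(20, 50, 5), rng.uniform(20, 50, 5)]))
        t = label_anchors(anchors, gt, image_size=(152, 152))
        pos = np.flatnonzero(t.labels == 1)
        assert len(pos) >= 1
        mat = iou(anchors[pos], gt)
        assert np.all(mat.max(axis=0) > 0)   # every gt overlaps some positive


class TestSampling:
    def _targets(self, n_pos, n_neg, n_total=2000):
        labels = np.full(n_total, IGNORE, dtype=np.int64)
        labels[:n_pos] = 1
        labels[n_pos:n_pos + n_neg] = 0
        return RPNTargets(labels, np.zeros((n_total, 4)))

    @pytest.mark.parametrize("n_pos,n_neg,exp_pos,exp_neg", [
        (300, 300, 128, 128),
        (10, 1000, 10, 246),
        (0, 500, 0, 256),
    ])
    def test_balance_and_supplement_rules(self, n_pos, n_neg, exp_pos, exp_neg):
        t = sample_minibatch(self._targets(n_pos, n_neg), rng=0)
        sampled = t.labels[t.sampled]
        assert (sampled == 1).sum() == exp_pos
        assert (sampled == 0).sum() == exp_neg
        assert t.sampled.sum() == exp_pos + exp_neg

    def test_short_supply_samples_all_with_warning(self):
        with pytest.warns(UserWarning, match="mini-batch"):
            t = sample_minibatch(self._targets(5, 30, n_total=100), rng=0)
        assert t.sampled.sum() == 35

    def test_sampling_deterministic_given_seed(self):
        t1 = sample_minibatch(self._targets(300, 300), rng=42)
        t2 = sample_minibatch(self._targets(300, 300), rng=42)
        assert np.array_equal(t1.sampled, t2.sampled)


class TestEncodeDecode:
    def test_identity_encoding_is_zero(self):
        b = BoxArray([50.0], [60.0], [20.0], [30.0])
        assert np.allclose(encode_boxes(b, b), 0.0)

    def test_hand_computed_example(self):
        before = BoxArray([100.0], [100.0], [50.0], [50.0])
        target = BoxArray([110.0], [95.0], [100.0], [25.0])
        r = encode_boxes(before, target)
        assert np.allclose(r[0], [0.2, -0.1, math.log(2), -math.log(2)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_inverse(self, seed):
        rg = np.random.default_rng(seed)
        before = BoxArray(rg.uniform(20, 500, 6), rg.uniform(20, 500, 6),
                          rg.uniform(5, 100, 6), rg.uniform(5, 100, 6))
        target = BoxArray(rg.uniform(20, 500, 6), rg.uniform(20, 500, 6),
                          rg.uniform(5, 100, 6), rg.uniform(5, 100, 6))
        r = encode_boxes(before, target)
        back = decode_boxes(before, r)
        for attr in ("cx", "cy", "w", "h"):
            assert np.allclose(getattr(back, attr), getattr(target, attr), atol=1e-6)

    def test_nonpositive_size_rejected(self):
        bad = BoxArray([10.0], [10.0], [0.0], [5.0])
        good = BoxArray([10.0], [10.0], [5.0], [5.0])
        with pytest.raises(ValueError):
            encode_boxes(bad, good)

    def test_decode_clamps_huge_log_deltas(self):
        before = BoxArray([50.0], [50.0], [10.0], [10.0])
        with pytest.warns(UserWarning, match="clamped"):
            out = decode_boxes(before, np.array([[0, 0, 50.0, 0]]))
        assert np.isfinite(out.w[0])
        assert out.w[0] == 10.0 * math.exp(4.0)


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (0.5, 0.125), (-2.0, 1.5), (1.0, 0.5), (-1.0, 0.5), (3.0, 2.5),
    ])
    def test_piecewise_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_c1_continuity_at_one(self):
        eps = 1e-6
        assert abs(smooth_l1(1 + eps) - smooth_l1(1 - eps)) < 1e-5
        # derivative approaches 1 from both sides
        d_in = (smooth_l1(1.0) - smooth_l1(1 - 1e-4)) / 1e-4
        d_out = (smooth_l1(1 + 1e-4) - smooth_l1(1.0)) / 1e-4
        assert abs(d_in - 1.0) < 1e-3 and abs(d_out - 1.0) < 1e-3

    def test_nonnegative_and_symmetric(self, rng):
        x = rng.normal(size=100) * 3
        assert np.all(smooth_l1(x) >= 0)
        assert np.allclose(smooth_l1(x), smooth_l1(-x))


def _make_output(n, cls_logits=None, reg=None):
    cls = np.zeros((n, 2), dtype=np.float32) if cls_logits is None else cls_logits
    r = np.zeros((n, 4), dtype=np.float32) if reg is None else reg
    return RPNOutput(Tensor(cls), Tensor(r))


class TestRPNLoss:
    def _perfect(self, n=256, n_pos=10):
        labels = np.zeros(n, dtype=np.int64)
        labels[:n_pos] = 1
        logits = np.zeros((n, 2), dtype=np.float32)
        logits[np.arange(n), labels] = 50.0     # prob(true label) -> 1
        targets = RPNTargets(labels, np.zeros((n, 4)), np.ones(n, dtype=bool))
        return _make_output(n, logits), targets

    def test_perfect_predictions_give_zero(self):
        out, targets = self._perfect()
        loss, bd = rpn_loss(out, targets)
        assert loss.data == pytest.approx(0.0, abs=1e-6)

    def test_single_imperfect_positive_contributes_one_over_nm(self):
        out, targets = self._perfect(n=256, n_pos=10)
        # one positive's true-label probability forced to e^{-1}
        z = out.cls_logits.data.copy()
        p_true = math.exp(-1)
        z[0] = [math.log(1 - p_true), math.log(p_true)]
        out = _make_output(256, z)
        loss, bd = rpn_loss(out, targets)
        assert loss.data == pytest.approx(1.0 / 256, rel=1e-4)

    def test_negative_anchor_regression_is_inert(self):
        out, targets = self._perfect()
        loss0, _ = rpn_loss(out, targets)
        reg = out.regression.data.copy()
        reg[200] = [5, 5, 5, 5]                 # a negative anchor
        out2 = _make_output(256, out.cls_logits.data, reg)
        loss1, _ = rpn_loss(out2, targets)
        assert loss0.data == loss1.data

    def test_positive_regression_error_raises_loss(self):
        out, targets = self._perfect()
        reg = out.regression.data.copy()
        reg[0] = [0.5, 0, 0, 0]                 # a positive anchor
        out2 = _make_output(256, out.cls_logits.data, reg)
        loss1, bd = rpn_loss(out2, targets)
        assert bd["reg"] == pytest.approx(0.125 / 256, rel=1e-4)

    def test_requires_sampled_mask(self):
        out, _ = self._perfect()
        with pytest.raises(ValueError, match="sampled"):
            rpn_loss(out, RPNTargets(np.zeros(256, dtype=np.int64), np.zeros((256, 4))))


class TestRPNHeadWiring:
    def test_channel_counts_2n_4n(self):
        head = RPNHead(in_channels=16, anchors_per_cell=9, rng=np.random.default_rng(0))
        assert head.cls.weight.data.shape[0] == 18
        assert head.reg.weight.data.shape[0] == 36

    def test_intermediate_grid_keeps_shape_and_probs_normalize(self, rng):
        head = RPNHead(in_channels=8, anchors_per_cell=3, rng=np.random.default_rng(1))
        head.eval()
        grid = FeatureGrid(Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32)), 8)
        with nn.no_grad():
            inter = head.conv(grid.tensor).swish()
            out = head(grid)
        assert inter.data.shape == grid.tensor.data.shape
        assert out.cls_logits.data.shape == (6 * 6 * 3, 2)
        z = out.cls_logits.data
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_head_order_matches_anchor_order(self, rng):
        """Perturbing one cell of the head input moves exactly that cell's anchors."""
        head = RPNHead(in_channels=4, anchors_per_cell=2, rng=np.random.default_rng(2))
        head.eval()
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        with nn.no_grad():
            base = head(FeatureGrid(Tensor(x), 8)).regression.data
            x2 = x.copy()
            x2[0, :, 2, 3] += 10.0   # cell (i=2, j=3)
            pert = head(FeatureGrid(Tensor(x2), 8)).regression.data
        changed = np.flatnonzero(np.abs(pert - base).sum(axis=1) > 1e-4)
        cells = np.unique(changed // 2)          # anchors-per-cell = 2
        affected = {(c // 5, c % 5) for c in cells}
        # 3x3 head conv: only the 3x3 neighborhood of (2,3) may respond
        assert all(abs(i - 2) <= 1 and abs(j - 3) <= 1 for i, j in affected)
        assert (2, 3) in affected


class TestNMS:
    def test_high_overlap_suppressed_low_kept(self):
        boxes = BoxArray.from_corners([[0, 0, 10, 10], [1, 0, 11, 10]])   # IoU ≈ 0.82
        keep = nms(boxes, np.array([0.9, 0.8]), 0.7)
        assert keep.tolist() == [0]
        boxes2 = BoxArray.from_corners([[0, 0, 10, 10], [5, 0, 15, 10]])  # IoU = 1/3
        keep2 = nms(boxes2, np.array([0.9, 0.8]), 0.7)
        assert sorted(keep2.tolist()) == [0, 1]

    def test_threshold_is_strict_inequality(self):
        # IoU exactly 0.5 at threshold 0.5: both kept (suppress only above)
        boxes = BoxArray.from_corners([[0, 0, 10, 10], [0, 5, 10, 15]])
        assert iou(boxes, boxes)[0, 1] == pytest.approx(1 / 3)
        boxes_half = BoxArray.from_corners([[0, 0, 20, 10], [0, 5, 20, 25]])
        keep = nms(boxes_half, np.array([0.9, 0.8]), 0.7)
        assert len(keep) == 2

    def test_matches_brute_force_oracle_on_random_boxes(self, rng):
        boxes = random_boxes_int(rng, 200, hi=120, max_side=50)
        scores = rng.random(200)
        keep = nms(BoxArray.from_corners(boxes), scores, 0.5)
        ref = brute_force_nms(boxes, scores, 0.5)
        assert keep.tolist() == ref

    def test_output_properties(self, rng):
        boxes = BoxArray.from_corners(random_boxes_int(rng, 60, hi=100))
        scores = rng.random(60)
        keep = nms(boxes, scores, 0.6)
        kept_scores = scores[keep]
        assert np.all(np.diff(kept_scores) <= 0)        # score-sorted
        mat = iou(boxes[keep], boxes[keep])
        np.fill_diagonal(mat, 0.0)
        assert np.all(mat <= 0.6 + 1e-12)               # pairwise below threshold


class TestProposals:
    def test_single_anchor_zero_regression_returns_anchor(self):
        anchors = BoxArray([50.0], [50.0], [20.0], [20.0])
        out = _make_output(1)
        props = generate_proposals(out, anchors, (100, 100))
        assert len(props) == 1
        assert np.allclose(props[0].box, [40, 40, 60, 60])

    def test_post_nms_cap_respected(self, rng):
        n = 500
        anchors = BoxArray(rng.uniform(50, 550, n), rng.uniform(50, 550, n),
                           np.full(n, 40.0), np.full(n, 40.0))
        out = _make_output(n, rng.normal(size=(n, 2)).astype(np.float32))
        cfg = ProposalConfig(post_nms_test=25)
        props = generate_proposals(out, anchors, (600, 600), config=cfg)
        assert len(props) <= 25

    def test_well_separated_high_scorers_all_survive(self):
        anchors = BoxArray([50.0, 300.0, 550.0], [50.0, 300.0, 550.0],
                           [40.0, 40.0, 40.0], [40.0, 40.0, 40.0])
        logits = np.zeros((3, 2), dtype=np.float32)
        logits[:, 1] = 5.0
        props = generate_proposals(_make_output(3, logits), anchors, (600, 600))
        assert len(props) == 3

    def test_proposals_clipped_to_image(self, rng):
        anchors = BoxArray([5.0], [5.0], [40.0], [40.0])    # extends past origin
        props = generate_proposals(_make_output(1), anchors, (100, 100))
        x1, y1, x2, y2 = props[0].box
        assert x1 >= 0 and y1 >= 0 and x2 <= 100 and y2 <= 100

    def test_coco_serialization_round(self):
        anchors = BoxArray([50.0], [50.0], [20.0], [20.0])
        props = generate_proposals(_make_output(1), anchors, (100, 100))
        rec = props[0].to_coco(image_id=7)
        assert rec["image_id"] == 7
        assert rec["bbox"] == [40.0, 40.0, 20.0, 20.0]
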