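"""Trainer contracts: assignment, losses, NMS, determinism, smoke descent."""

import numpy as np
import pytest

import lynodet as L
from lynodet.model import make_anchors
from lynodet.train import (TrainConfig, assign_targets, batch_loss, nms,
                           predict, train, _to_batch, flatten_heads,
                           decode_distances, distances_to_boxes,
                           compute_losses)
from lynodet.metrics import Detection
from lynodet.data import LeakageError, Provenance, LabeledImage, BoundingBox


def small_cfg(**kw):
    kw.setdefault("image_size", 64)
    kw.setdefault("batch_size", 4)
    kw.setdefault("epochs", 1)
    kw.setdefault("augment", False)
    return TrainConfig(**kw)


class TestAssignTargets:
    def grid(self, n=4, stride=8, nc=2):
        pts, strides = make_anchors([(n, n)], [stride])
        return pts * strides[:, None], n * n

    def test_single_gt_one_cell_k1(self):
        pts_px, A = self.grid()
        scores = np.full((A, 2), 0.5)
        boxes = np.tile([0., 0., 8., 8.], (A, 1))
        boxes[5] = [8, 8, 16, 16]      # cell (1,1) predicts the gt box exactly
        gt = np.array([[8., 8., 16., 16.]])
        fg, idx, ts = assign_targets(scores, boxes, pts_px, gt,
                                     np.array([1]), topk=1)
        assert fg.sum() == 1 and fg[5] and idx[5] == 0
        assert ts[5, 1] > 0 and ts[5, 0] == 0

    def test_zero_gt_all_background(self):
        pts_px, A = self.grid()
        fg, idx, ts = assign_targets(np.full((A, 2), 0.5),
                                     np.zeros((A, 4)), pts_px,
                                     np.zeros((0, 4)), np.zeros(0, int))
        assert not fg.any() and ts.sum() == 0

    def test_contested_cell_goes_to_higher_iou(self):
        """Two overlapping boxes both claim cell (1,1); enumeration of the
        alignment rule says the box its prediction overlaps more wins."""
        pts_px, A = self.grid()
        scores = np.full((A, 2), 0.5)
        boxes = np.tile([100., 100., 101., 101.], (A, 1))
        boxes[5] = [7, 7, 17, 17]
        gt = np.array([[6., 6., 18., 18.],     # iou vs cell 5 pred: higher
                       [4., 4., 20., 20.]])    # lower
        iou_a = 100 / 144
        iou_b = 100 / 256
        assert iou_a > iou_b
        fg, idx, _ = assign_targets(scores, boxes, pts_px, gt,
                                    np.array([0, 1]), topk=1)
        assert idx[5] == 0


class TestLosses:
    def build(self, nc=2, reg_max=4, size=32):
        spec = L.make_arch_spec("baseline", input_size=size, num_classes=nc,
                                width_mult=0.25)
        spec.reg_max = reg_max
        return L.DetectorNet(spec, seed=3, dtype=np.float64), spec

    def test_perfect_box_zero_box_loss(self):
        """CIoU of identical boxes is 1, so (1 - CIoU) vanishes."""
        from lynodet.train import _ciou
        from lynodet.autodiff import Tensor
        b = Tensor(np.array([[2., 3., 10., 12.]]), requires_grad=True)
        c = _ciou(b, np.array([[2., 3., 10., 12.]]))
        np.testing.assert_allclose(c.data, [1.0], atol=1e-6)

    def test_cls_loss_saturates_to_zero(self):
        """Logits giving probability 1 on the true class and 0 elsewhere
        drive the binary cross-entropy to 0 in the saturation limit."""
        from lynodet.autodiff import Tensor
        cfg = small_cfg()
        reg_max = 4
        points = np.array([[0.5, 0.5]])
        strides = np.array([8.0])
        tbox = np.array([[0., 0., 8., 8.]])
        pd = Tensor(np.zeros((1, 1, 4 * reg_max)))
        ts = np.zeros((1, 2))
        ts[0, 0] = 1.0                              # hard one-hot target
        pc = Tensor(np.where(ts[None] > 0, 30.0, -30.0))
        dist = decode_distances(pd, reg_max)
        boxes_t = distances_to_boxes(dist, points, strides)
        _, bd = compute_losses(pd, pc, boxes_t,
                               [(np.array([True]), np.array([0]), ts)],
                               points, strides, [(tbox, np.array([0]))],
                               reg_max, cfg)
        assert bd.cls_loss < 1e-10

    def test_dfl_two_bin_closed_form(self):
        """Hand-computed two-bin cross-entropy on a reg_max=4 toy."""
        from lynodet.autodiff import Tensor
        cfg = small_cfg()
        reg_max = 4
        # one anchor at cell center (0.5, 0.5), stride 8; target edges at
        # 1.3 cells left/top, 1.7 right/bottom
        points = np.array([[0.5, 0.5]])
        strides = np.array([8.0])
        tbox = np.array([[(0.5 - 1.3) * 8, (0.5 - 1.3) * 8,
                          (0.5 + 1.7) * 8, (0.5 + 1.7) * 8]])
        logits = np.zeros((1, 1, 4 * reg_max))      # uniform distributions
        pd = Tensor(logits, requires_grad=True)
        pc = Tensor(np.full((1, 1, 2), -5.0), requires_grad=True)
        dist = decode_distances(pd, reg_max)
        boxes_t = distances_to_boxes(dist, points, strides)
        fg = np.array([True])
        ts = np.zeros((1, 2))
        ts[0, 0] = 1.0
        bl, bd = compute_losses(pd, pc, boxes_t, [(fg, np.array([0]), ts)],
                                points, strides, [(tbox, np.array([0]))],
                                reg_max, cfg)
        # uniform softmax: log p = -log 4 for every bin; the two-bin CE is
        # (wl + wr) * log 4 per edge, averaged over 4 edges
        assert bd.dfl_loss == pytest.approx(np.log(4.0), rel=1e-6)

    def test_no_positives_flagged(self):
        model, spec = self.build()
        cfg = small_cfg(image_size=32, batch_size=1)
        x = np.random.default_rng(1).random((1, 3, 32, 32))
        total, bd = batch_loss(model, x, [[]], cfg)
        assert bd.no_positives and bd.box_loss == 0.0 and bd.dfl_loss == 0.0
        assert bd.cls_loss >= 0

    def test_gradient_sanity_finite_difference(self):
        """Backprop against central differences on a 1-image micro-batch,
        with the (intentionally detached) assignment frozen."""
        model, spec = self.build()
        model.eval()     # freeze batch statistics for a deterministic loss
        cfg = small_cfg(image_size=32, batch_size=1)
        rng = np.random.default_rng(0)
        x = rng.random((1, 3, 32, 32))
        gb = np.array([[4., 4., 20., 20.]])
        gc = np.array([0])
        frozen = {}

        def loss():
            heads = model(x)
            pd, pc, shapes = flatten_heads(heads, spec.reg_max,
                                           spec.num_classes)
            points, strides = make_anchors(shapes, model.head_strides)
            dist = decode_distances(pd, spec.reg_max)
            boxes_t = distances_to_boxes(dist, points, strides)
            if "asn" not in frozen:
                sc = 1 / (1 + np.exp(-pc.data[0]))
                frozen["asn"] = [assign_targets(sc, boxes_t.data[0],
                                                points * strides[:, None],
                                                gb, gc)]
            return compute_losses(pd, pc, boxes_t, frozen["asn"], points,
                                  strides, [(gb, gc)], spec.reg_max, cfg)[0]

        total = loss()
        total.backward()
        params = model.parameters()
        checked = 0
        for pi in rng.choice(len(params), size=6, replace=False):
            p = params[pi]
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            idx = np.unravel_index(rng.integers(p.data.size), p.data.shape)
            eps, orig = 1e-6, p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss().data)
            p.data[idx] = orig - eps
            lm = float(loss().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = grad[idx]
            assert abs(fd - an) <= 1e-3 * max(1.0, abs(fd), abs(an))
            checked += 1
        assert checked == 6


class TestNMS:
    def test_duplicate_same_class_keeps_best(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.]])
        kept = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert kept == [0]

    def test_different_classes_both_survive(self, tiny_model):
        dets = [Detection(np.array([0, 0, 10, 10.]), 0, 0.9),
                Detection(np.array([0, 0, 10, 10.]), 1, 0.8)]
        # class-wise NMS is exercised through predict's per-class loop;
        # directly: each class pool has one box
        for d in dets:
            assert nms(d.box[None], np.array([d.conf]), 0.5) == [0]

    def test_chain_matches_bruteforce(self, rng):
        """Five boxes with pairwise overlaps: greedy suppression equals an
        exhaustive re-implementation."""
        for _ in range(20):
            boxes = np.stack([np.array([x, x, x + 10, x + 10.])
                              for x in rng.uniform(0, 12, size=5)])
            scores = rng.random(5)
            kept = nms(boxes, scores, 0.3)
            alive = list(range(5))
            expect = []
            while alive:
                best = max(alive, key=lambda i: (scores[i], -i))
                expect.append(best)
                alive = [i for i in alive
                         if i != best and L.iou(boxes[best], boxes[i]) <= 0.3]
            assert kept == expect

    def test_predict_idempotent_and_clipped(self, tiny_model, rng):
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        dets = predict(tiny_model, x, 0.0001, 0.7)
        boxes = np.array([d.box for d in dets[0]]).reshape(-1, 4)
        assert (boxes >= 0).all() and (boxes <= 64).all()
        confs = [d.conf for d in dets[0]]
        assert confs == sorted(confs, reverse=True)
        # NMS applied twice equals once
        for d in dets[0][:5]:
            assert nms(d.box[None], np.array([d.conf]), 0.7) == [0]


class TestTrainLoop:
    def make_records(self, n=12, seed=0):
        cfg = L.easy_two_class_config(n_images=n, image_size=64, seed=seed)
        records, images = L.generate_records(cfg)
        for i, r in enumerate(records):
            r.split = "train" if i % 3 else "val"
        return cfg, records, images

    def test_epochs_zero_returns_untrained(self):
        cfg, records, images = self.make_records()
        spec = L.make_arch_spec("baseline", 64, num_classes=2, width_mult=0.25)
        model = L.DetectorNet(spec, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        ckpt, hist = train(model, records, [], small_cfg(epochs=0),
                           images=images)
        assert hist == []
        for a, b in zip(before, ckpt.weights):
            np.testing.assert_array_equal(a, b)

    def test_identical_seed_identical_first_epoch(self):
        cfg, records, images = self.make_records()
        tr = [r for r in records if r.split == "train"]
        losses = []
        for _ in range(2):
            spec = L.make_arch_spec("baseline", 64, num_classes=2,
                                    width_mult=0.25)
            model = L.DetectorNet(spec, seed=5)
            _, hist = train(model, tr, [], small_cfg(epochs=1, seed=5),
                            images=images)
            losses.append(hist[0]["total"])
        assert losses[0] == losses[1]

    def test_leakage_audit_aborts_before_epoch_zero(self):
        cfg, records, images = self.make_records()
        manifest = L.split_holdout([r.image_id for r in records], seed=0)
        for r in records:
            r.split = manifest.assignment[r.image_id]
        victim = next(r for r in records if r.split == "test")
        bad = LabeledImage(image_id=victim.image_id + "_augX",
                           width=64, height=64, boxes=victim.boxes,
                           split="train",
                           provenance=Provenance(origin_id=victim.image_id,
                                                 ops=[["hflip", None]]))
        images[bad.image_id] = images[victim.image_id][:, ::-1]
        tr = [r for r in records if r.split == "train"] + [bad]
        spec = L.make_arch_spec("baseline", 64, num_classes=2, width_mult=0.25)
        model = L.DetectorNet(spec, seed=0)
        with pytest.raises(LeakageError):
            train(model, tr, [], small_cfg(), images=images, manifest=manifest)

    def test_loss_decreases_on_easy_set(self):
        """Moving-average total loss falls over a short run."""
        cfg, records, images = self.make_records(n=24, seed=1)
        tr = [r for r in records if r.split == "train"]
        spec = L.make_arch_spec("baseline", 64, num_classes=2, width_mult=0.25)
        model = L.DetectorNet(spec, seed=1)
        _, hist = train(model, tr, [], small_cfg(epochs=6, batch_size=8,
                                                 seed=1), images=images)
        first = np.mean([h["total"] for h in hist[:2]])
        last = np.mean([h["total"] for h in hist[-2:]])
        assert last < first

    def test_checkpoint_roundtrip(self, tmp_path):
        spec = L.make_arch_spec("baseline", 64, num_classes=2, width_mult=0.25)
        model = L.DetectorNet(spec, seed=9)
        from lynodet.train import Checkpoint
        ckpt = Checkpoint.of(model, config=small_cfg())
        ckpt.save(tmp_path / "m.npz")
        loaded = Checkpoint.load(tmp_path / "m.npz")
        rebuilt = loaded.build_model()
        x = np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32)
        model.eval()
        np.testing.assert_array_equal(model(x)[0].data, rebuilt.eval()(x)[0].data)


class TestForwardContract:
    def test_map_shapes_and_determinism(self, tiny_model, rng):
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        a = tiny_model(x)
        b = tiny_model(x)
        assert [h.shape[2:] for h in a] == [(8, 8), (4, 4), (2, 2)]
        for ha, hb in zip(a, b):
            np.testing.assert_array_equal(ha.data, hb.data)

    def test_full_p6_small_input_maps(self):
        spec = L.make_arch_spec("full_p6", input_size=128, num_classes=3,
                                width_mult=0.0625)
        model = L.DetectorNet(spec, seed=0)
        maps = model(np.zeros((1, 3, 128, 128), np.float32))
        assert [h.shape[2:] for h in maps] == [(8, 8), (4, 4), (2, 2)]
        assert all(h.shape[1] == 4 * spec.reg_max + 3 for h in maps)

    def test_wrong_channel_count_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="expected"):
            tiny_model(np.zeros((1, 4, 64, 64), np.float32))

    def test_input_smaller_than_deepest_stride_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="stride"):
            tiny_model(np.zeros((1, 3, 16, 16), np.float32))
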