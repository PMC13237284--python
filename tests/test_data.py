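"""Data pipeline: label I/O, splits, augmentation geometry, leakage audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lynodet as L
from lynodet.data import (BoundingBox, LabeledImage, Provenance,
                          LabelFormatError, read_yolo_labels,
                          write_yolo_labels, split_holdout, split_kfold,
                          augment_record, audit_leakage, balance_classes,
                          expand_training_set, SplitManifest)


class TestLabelIO:
    def test_single_line(self):
        boxes = read_yolo_labels("3 0.5 0.5 0.2 0.1")
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.class_id, b.cx, b.cy, b.w, b.h) == (3, 0.5, 0.5, 0.2, 0.1)

    def test_empty_text_is_background(self):
        assert read_yolo_labels("") == []
        assert write_yolo_labels([]) == ""

    def test_confidence_column_roundtrip(self):
        text = "2 0.300000 0.400000 0.100000 0.200000 0.750000\n"
        boxes = read_yolo_labels(text)
        assert boxes[0].conf == 0.75
        assert write_yolo_labels(boxes) == text

    def test_bad_class_id_names_line(self):
        with pytest.raises(LabelFormatError, match="line 2"):
            read_yolo_labels("0 .5 .5 .1 .1\n99 .5 .5 .1 .1")

    def test_out_of_range_clipped_or_strict(self):
        text = "0 0.05 0.5 0.2 0.2"
        b = read_yolo_labels(text)[0]
        assert b.cx - b.w / 2 >= -1e-9
        with pytest.raises(LabelFormatError):
            read_yolo_labels(text, strict=True)

    @given(st.lists(st.tuples(st.integers(0, 14),
                              st.floats(0.05, 0.95), st.floats(0.05, 0.95),
                              st.floats(0.01, 0.1), st.floats(0.01, 0.1)),
                    max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_fixpoint(self, raw):
        boxes = [BoundingBox(c, round(x, 6), round(y, 6), round(w, 6),
                             round(h, 6)) for c, x, y, w, h in raw]
        text = write_yolo_labels(boxes)
        parsed = read_yolo_labels(text)
        assert write_yolo_labels(parsed) == text


class TestHoldoutSplit:
    def test_published_dataset_size_arithmetic(self):
        """1931 ids split 80/10/10 by largest remainder -> 1545/193/193."""
        ids = [f"im{i}" for i in range(1931)]
        man = split_holdout(ids, seed=0)
        sizes = {s: len(man.ids(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 1545, "val": 193, "test": 193}

    def test_ten_ids(self):
        man = split_holdout([str(i) for i in range(10)], seed=1)
        assert [len(man.ids(s)) for s in ("train", "val", "test")] == [8, 1, 1]

    def test_deterministic_per_seed(self):
        ids = [f"x{i}" for i in range(57)]
        a = split_holdout(ids, seed=3).to_json()
        b = split_holdout(ids, seed=3).to_json()
        assert a == b
        assert a != split_holdout(ids, seed=4).to_json()

    def test_partition_and_stratification(self):
        rng = np.random.default_rng(0)
        ids = [f"i{n}" for n in range(300)]
        key_by = {i: int(rng.integers(5)) for i in ids}
        man = split_holdout(ids, seed=2, key_by=key_by)
        all_ids = sorted(sum((man.ids(s) for s in ("train", "val", "test")), []))
        assert all_ids == sorted(ids)
        for cls in range(5):
            members = [i for i in ids if key_by[i] == cls]
            tr = sum(1 for i in members if man.assignment[i] == "train")
            assert abs(tr - 0.8 * len(members)) <= 1.0

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            split_holdout(["a", "b"], seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            split_holdout(list("abcdefgh"), fractions=(0.5, 0.4), seed=0)

    def test_manifest_serialization_fixpoint(self, tmp_path):
        man = split_holdout([f"q{i}" for i in range(20)], seed=5)
        p1 = tmp_path / "m1.json"
        man.save(p1)
        again = SplitManifest.load(p1)
        p2 = tmp_path / "m2.json"
        again.save(p2)
        assert p1.read_text() == p2.read_text()


class TestKFold:
    def test_each_fold_val_size_two(self):
        folds = split_kfold([str(i) for i in range(10)], k=5, seed=0)
        assert all(len(m.ids("val")) == 2 for m in folds)

    def test_every_id_validates_exactly_once(self):
        ids = [f"z{i}" for i in range(37)]
        folds = split_kfold(ids, k=5, seed=1)
        seen = sum((m.ids("val") for m in folds), [])
        assert sorted(seen) == sorted(ids)

    def test_stratified_within_one(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(150)]
        key_by = {i: int(rng.integers(15)) for i in ids}
        folds = split_kfold(ids, k=5, seed=2, key_by=key_by)
        for cls in range(15):
            members = [i for i in ids if key_by[i] == cls]
            per_fold = [sum(1 for i in members if m.assignment[i] == "val")
                        for m in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            split_kfold(["a", "b"], k=5, seed=0)


class TestAugmentation:
    def gray(self, v=128):
        return np.full((32, 32, 3), v, np.uint8)

    def test_hflip_involution(self, rng):
        boxes = [BoundingBox(0, 0.3, 0.6, 0.2, 0.1)]
        img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
        i1, b1, _ = augment_record(img, boxes, ["hflip"], rng)
        i2, b2, _ = augment_record(i1, b1, ["hflip"], rng)
        np.testing.assert_array_equal(img, i2)
        assert b2[0].cx == pytest.approx(0.3) and b2[0].cy == 0.6

    def test_vflip_maps_cy(self, rng):
        _, b, _ = augment_record(self.gray(), [BoundingBox(1, 0.5, 0.2, 0.1,
                                                           0.1)],
                                 ["vflip"], rng)
        assert b[0].cy == pytest.approx(0.8)

    def test_rot45_centered_square_enclosure(self, rng):
        """A centered square of side 0.2 re-encloses to side 0.2*sqrt(2)."""
        _, b, _ = augment_record(self.gray(), [BoundingBox(0, 0.5, 0.5, 0.2,
                                                           0.2)],
                                 ["rot+45"], rng)
        assert b[0].w == pytest.approx(0.2 * np.sqrt(2), abs=1e-9)
        assert b[0].h == pytest.approx(0.2 * np.sqrt(2), abs=1e-9)

    def test_rotation_labels_follow_pixels(self, rng):
        """The rotated box must still cover the rotated bright blob."""
        img = np.zeros((64, 64, 3), np.uint8)
        img[8:16, 40:56] = 255          # off-center bright rectangle
        boxes = [BoundingBox(0, 48 / 64, 12 / 64, 16 / 64, 8 / 64)]
        for op in ("rot+45", "rot-45"):
            rimg, rboxes, _ = augment_record(img, boxes, [op], rng)
            assert rboxes, op
            ys, xs = np.nonzero(rimg[..., 0] > 200)
            x1, y1, x2, y2 = rboxes[0].to_xyxy(64, 64)
            inside = ((xs >= x1 - 1.5) & (xs <= x2 + 1.5)
                      & (ys >= y1 - 1.5) & (ys <= y2 + 1.5))
            assert inside.mean() > 0.98, op

    def test_brightness_multiplicative(self, rng):
        img, b, trace = augment_record(self.gray(128),
                                       [BoundingBox(0, .5, .5, .1, .1)],
                                       [("brightness", 0.4)], rng)
        assert img[0, 0, 0] == 179            # floor(128 * 1.4)
        assert b[0].cx == 0.5                 # labels unchanged
        assert trace == [("brightness", 0.4)]

    def test_brightness_clips_at_255(self, rng):
        img, _, _ = augment_record(self.gray(250), [], [("brightness", 0.4)],
                                   rng)
        assert img.max() == 255

    def test_zoom_scales_boxes_about_center(self, rng):
        _, b, _ = augment_record(self.gray(), [BoundingBox(0, 0.4, 0.6, 0.2,
                                                           0.2)],
                                 [("zoom", 1.5)], rng)
        assert b[0].cx == pytest.approx(0.5 + (0.4 - 0.5) * 1.5)
        assert b[0].w == pytest.approx(0.3)

    def test_zoom_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_record(self.gray(), [], [("zoom", 2.0)], rng)

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment_record(self.gray(), [], ["sharpen"], rng)

    def test_geometric_ops_preserve_class_multiset(self, rng):
        boxes = [BoundingBox(c, 0.5, 0.5, 0.15, 0.15) for c in (0, 1, 1, 2)]
        for op in ("hflip", "vflip", ("brightness", -0.2)):
            _, out, _ = augment_record(self.gray(), boxes, [op], rng)
            assert sorted(b.class_id for b in out) == [0, 1, 1, 2]


class TestLeakageAudit:
    def pipeline(self, n=30, seed=0):
        ids = [f"p{i}" for i in range(n)]
        man = split_holdout(ids, seed=seed)
        records = [LabeledImage(image_id=i, width=8, height=8,
                                split=man.assignment[i]) for i in ids]
        return man, records

    def test_clean_pipeline_passes(self):
        man, records = self.pipeline()
        assert audit_leakage(man, records) == []

    def test_augmented_test_copy_in_train_named(self):
        man, records = self.pipeline()
        victim = man.ids("test")[0]
        bad = LabeledImage(image_id=victim + "_aug0", width=8, height=8,
                           split="train",
                           provenance=Provenance(victim, [["vflip", None]]))
        vio = audit_leakage(man, records + [bad])
        assert len(vio) == 1
        assert vio[0]["record"] == victim + "_aug0"
        assert vio[0]["origin"] == victim

    def test_randomized_manifests_match_bruteforce(self):
        """Auditor output equals naive set-intersection logic on 200
        adversarial manifests."""
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(6, 20))
            ids = [f"r{trial}_{i}" for i in range(n)]
            assignment = {i: ("train", "val", "test")[rng.integers(3)]
                          for i in ids}
            man = SplitManifest(scheme="holdout_80_10_10", seed=0,
                                assignment=assignment)
            records = []
            for i in ids:
                records.append(LabeledImage(image_id=i, width=4, height=4,
                                            split=assignment[i]))
                if rng.random() < 0.4:
                    origin = ids[rng.integers(n)]
                    records.append(LabeledImage(
                        image_id=i + "_d", width=4, height=4, split="train",
                        provenance=Provenance(origin, [["hflip", None]])))
            got = {(v["kind"], v["record"]) for v in audit_leakage(man, records)}
            holdout = {i for i, s in assignment.items() if s != "train"}
            expect = set()
            for r in records:
                aug = r.provenance.ops != []
                if aug and assignment.get(r.image_id) in ("val", "test"):
                    expect.add(("augmented_in_holdout", r.image_id))
                if (r.split or assignment.get(r.image_id)) == "train" \
                        and r.provenance.origin_id in holdout:
                    expect.add(("holdout_derivative_in_train", r.image_id))
            assert got == expect

    def test_offline_expansion_is_clean_and_sized(self, rng):
        cfg = L.easy_two_class_config(n_images=12, image_size=32, seed=3)
        records, images = L.generate_records(cfg)
        man = split_holdout([r.image_id for r in records], seed=3)
        for r in records:
            r.split = man.assignment[r.image_id]
        n_train = sum(1 for r in records if r.split == "train")
        out, imgs = expand_training_set(records, images, multiplier=3, seed=0)
        assert len(out) == len(records) + 2 * n_train
        aug = [r for r in out if not r.provenance.is_original]
        assert len(aug) == 2 * n_train
        assert all(r.split == "train" for r in aug)
        assert audit_leakage(man, out) == []


class TestBalanceClasses:
    def make(self, counts):
        records = []
        for cls, n in counts.items():
            for i in range(n):
                records.append(LabeledImage(
                    image_id=f"c{cls}_{i}", width=4, height=4,
                    boxes=[BoundingBox(cls, .5, .5, .1, .1)]))
        return records

    def test_oversized_class_cut_to_target(self):
        plan = balance_classes(self.make({0: 300, 1: 168}), 168, seed=0)
        assert plan["per_class"] == {0: 168, 1: 168}

    def test_rare_class_kept_whole_with_shortfall(self):
        plan = balance_classes(self.make({0: 200, 6: 14, 8: 9}), 168, seed=0)
        assert plan["per_class"][6] == 14 and plan["per_class"][8] == 9
        assert plan["shortfall"] == {6: 154, 8: 159}

    def test_deterministic(self):
        records = self.make({0: 50, 1: 40})
        a = balance_classes(records, 30, seed=7)
        b = balance_classes(records, 30, seed=7)
        assert a == b
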