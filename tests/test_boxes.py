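"""Box geometry, training-box sampling, padding, and the dynamic-box logic."""

import numpy as np
import pytest

import thrombseg as ts
from thrombseg.boxes import BoxError, acceptable_size

from conftest import gt_clipped_predictor

GRID = (182, 218, 182)


class TestInitialBox:
    def test_reference_point_spans(self):
        box = ts.make_initial_box((100, 80, 80), GRID)
        assert box.start == (35, 56, 56)
        assert box.stop == (116, 105, 105)
        assert box.shape == (81, 49, 49)

    def test_clamped_at_caudal_border(self):
        box = ts.make_initial_box((10, 80, 80), GRID)
        assert box.start[0] == 0
        assert box.stop[0] == 26  # cranial face unaffected

    def test_point_outside_grid_rejected(self):
        with pytest.raises(BoxError):
            ts.make_initial_box((200, 80, 80), GRID)

    def test_random_points_always_contained_and_sized(self):
        rng = np.random.default_rng(0)
        cfg = ts.InitialBoxConfig()
        for _ in range(1000):
            p = tuple(int(rng.integers(0, g)) for g in GRID)
            box = ts.make_initial_box(p, GRID, cfg)
            assert box.contains_point(p)
            # before clamping the size is fixed
            unclamped_start = (p[0] - 65, p[1] - 24, p[2] - 24)
            unclamped_stop = (p[0] + 16, p[1] + 25, p[2] + 25)
            assert all(box.start[i] == max(0, unclamped_start[i]) for i in range(3))
            assert all(box.stop[i] == min(GRID[i], unclamped_stop[i]) for i in range(3))
        assert cfg.unclamped_shape == (81, 49, 49)


class TestTrainingBoxes:
    def _gt(self, rng):
        gt = np.zeros((64, 64, 64), dtype=bool)
        z, y, x = rng.integers(10, 40, 3)
        gt[z:z + rng.integers(5, 20), y:y + rng.integers(2, 8),
           x:x + rng.integers(2, 8)] = True
        return gt

    def test_exactly_five_boxes_by_default(self):
        rng = np.random.default_rng(1)
        boxes = ts.sample_training_boxes(self._gt(rng), seed=2)
        assert len(boxes) == 5

    def test_zero_offsets_recover_tight_box(self, monkeypatch):
        rng = np.random.default_rng(1)
        gt = self._gt(rng)
        cfg = ts.TrainingBoxConfig(offset_factors=(1e-12,), shrink_fraction=0.0)
        boxes = ts.sample_training_boxes(gt, cfg, seed=0)
        assert boxes[0] == ts.tight_box(gt)

    def test_sampled_offsets_within_stated_intervals(self):
        rng = np.random.default_rng(3)
        cfg = ts.TrainingBoxConfig()
        init = np.array(cfg.initial_box.unclamped_shape)
        checked = 0
        for _ in range(40):  # 40 masks x 5 boxes = 200 samples
            gt = self._gt(rng)
            tight = ts.tight_box(gt)
            extents = np.array(tight.shape)
            for n, box in zip(cfg.offset_factors,
                              ts.sample_training_boxes(gt, cfg, seed=rng)):
                # every box intersects the tight box
                assert all(box.start[i] < tight.stop[i] and
                           box.stop[i] > tight.start[i] for i in range(3))
                for axis in range(3):
                    lo = -0.1 * extents[axis] - 0.51  # rounding slack
                    hi = n * init[axis] + 0.51
                    start_off = tight.start[axis] - box.start[axis]
                    stop_off = box.stop[axis] - tight.stop[axis]
                    # clamping can only pull the box inward
                    assert start_off <= hi and stop_off <= hi
                    if 0 < box.start[axis] and box.stop[axis] < gt.shape[axis]:
                        assert start_off >= lo and stop_off >= lo
                checked += 1
        assert checked == 200

    def test_empty_gt_rejected(self):
        with pytest.raises(BoxError):
            ts.sample_training_boxes(np.zeros((8, 8, 8), dtype=bool))


class TestPadding:
    @pytest.mark.parametrize("extent,depth,expected", [
        (96, 4, 96),   # already acceptable
        (81, 4, 96),   # next multiple of 16
        (81, 3, 88),
        (1, 1, 2),
        (17, 1, 18),
    ])
    def test_acceptable_size(self, extent, depth, expected):
        assert acceptable_size(extent, depth) == expected
        # brute force: smallest multiple of 2**depth >= extent
        unit = 2**depth
        brute = next(m for m in range(unit, extent + unit, unit) if m >= extent)
        assert brute == expected

    def test_pad_then_unpad_is_identity(self):
        rng = np.random.default_rng(4)
        crop = rng.random((81, 49, 49))
        padded, record = ts.pad_to_acceptable(crop, depth=4)
        assert padded.shape == (96, 64, 64)
        np.testing.assert_array_equal(ts.unpad(padded, record), crop)

    def test_padding_appended_at_high_end(self):
        crop = np.ones((3, 3, 3))
        padded, _ = ts.pad_to_acceptable(crop, depth=2)
        assert padded[:3, :3, :3].all() and padded.sum() == 27


class TestMovingBox:
    def test_large_prediction_skips_candidates(self):
        gt = np.zeros((64, 64, 64), dtype=bool)
        gt[20:30, 20:30, 20:30] = True  # 1000 voxels
        calls = []

        def predictor(box):
            calls.append(box)
            return box.extract(gt)

        box = ts.BoundingBox((10, 10, 10), (40, 40, 40))
        out_box, pred, info = ts.moving_box(box, predictor, grid_shape=gt.shape)
        assert out_box == box and not info["activated"]
        assert len(calls) == 1  # only the gate evaluation

    def test_displaced_thrombus_recovered_along_correct_axis(self):
        # thrombus fully outside the box along +axis1; brute force over the
        # 7 candidates says the +axis1 shift maximizes in-box gt volume
        gt = np.zeros((96, 96, 96), dtype=bool)
        gt[40:60, 70:80, 40:50] = True
        box = ts.BoundingBox((30, 30, 30), (70, 60, 60))
        predictor = gt_clipped_predictor(gt)
        out_box, pred, info = ts.moving_box(box, predictor, grid_shape=gt.shape)
        assert info["activated"]
        # independent brute force over all 7 candidates
        step = [int(np.floor(2 / 3 * e)) for e in box.shape]
        candidates = [box]
        for axis in range(3):
            for sign in (+1, -1):
                candidates.append(box.translate(axis, sign * step[axis]).clamp(gt.shape))
        volumes = [int(c.extract(gt).sum()) for c in candidates]
        assert out_box == candidates[int(np.argmax(volumes))]
        assert out_box == candidates[3]  # +axis1 shift
        assert pred.sum() == max(volumes)

    def test_all_empty_ties_keep_original_box(self):
        box = ts.BoundingBox((10, 10, 10), (30, 30, 30))
        predictor = lambda b: np.zeros(b.shape, dtype=bool)
        out_box, pred, _ = ts.moving_box(box, predictor, grid_shape=(64, 64, 64))
        assert out_box == box and not pred.any()

    def test_never_returns_smaller_prediction_than_original(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            gt = np.zeros((60, 60, 60), dtype=bool)
            z, y, x = rng.integers(5, 45, 3)
            gt[z:z + 10, y:y + 8, x:x + 8] = True
            start = rng.integers(0, 30, 3)
            box = ts.BoundingBox(tuple(start), tuple(start + rng.integers(15, 25, 3)))
            predictor = gt_clipped_predictor(gt)
            n0 = int(box.extract(gt).sum())
            _, pred, _ = ts.moving_box(box, predictor, grid_shape=gt.shape)
            assert int(pred.sum()) >= n0


class TestFlexibleBox:
    def test_far_prediction_leaves_box_unchanged(self):
        box = ts.BoundingBox((0, 0, 0), (30, 30, 30))
        pred = np.zeros(box.shape, dtype=bool)
        pred[10:20, 10:20, 10:20] = True  # >= 6 voxels from every face
        out_box, _, info = ts.flexible_box(box, pred, lambda b: pred,
                                           grid_shape=(100, 100, 100))
        assert out_box == box and info["iterations"] == 0

    def test_25_voxel_overhang_takes_three_growths(self):
        # thrombus extends 25 voxels past the cranial face; each growth adds
        # 10 voxels, so the 3rd growth leaves 5 voxels of clearance
        gt = np.zeros((120, 64, 64), dtype=bool)
        gt[20:65, 28:36, 28:36] = True
        box = ts.BoundingBox((10, 20, 20), (40, 44, 44))  # face at 40, overhang 25
        predictor = gt_clipped_predictor(gt)
        out_box, pred, info = ts.flexible_box(box, predictor(box), predictor,
                                              grid_shape=gt.shape)
        assert info["iterations"] == 3
        assert out_box.stop[0] == 70
        # final box fully encloses gt
        assert int(pred.sum()) == int(gt.sum())

    def test_growth_clamped_at_grid_boundary_terminates(self):
        gt = np.ones((20, 20, 20), dtype=bool)
        box = ts.BoundingBox((0, 0, 0), (20, 20, 20))
        predictor = gt_clipped_predictor(gt)
        out_box, _, info = ts.flexible_box(box, predictor(box), predictor,
                                           grid_shape=gt.shape)
        assert out_box == box  # nothing to grow into
        assert info["iterations"] <= 5

    def test_iteration_cap_and_monotone_growth(self):
        # prediction always hugs the face: growth must stop at 5 iterations
        def clingy(box):
            pred = np.zeros(box.shape, dtype=bool)
            pred[-1, 0, 0] = True
            return pred

        box = ts.BoundingBox((10, 10, 10), (20, 20, 20))
        boxes = [box]
        out_box, _, info = ts.flexible_box(box, clingy(box), clingy,
                                           grid_shape=(500, 500, 500))
        assert info["iterations"] == 5
        for rec in info["history"]:
            nxt = ts.BoundingBox.from_json(rec["box"])
            prev = boxes[-1]
            assert all(nxt.start[i] <= prev.start[i] and nxt.stop[i] >= prev.stop[i]
                       for i in range(3))
            boxes.append(nxt)


class TestDynamicBox:
    def test_well_contained_thrombus_keeps_initial_box(self, zero_jitter_case):
        gt = zero_jitter_case.gt.data
        predictor = gt_clipped_predictor(gt)
        box, full, prov = ts.dynamic_box(zero_jitter_case.point, gt.shape, predictor)
        initial = ts.BoundingBox.from_json(prov["initial_box"])
        assert prov["initial_voxels"] >= 100  # moving gate does not fire
        np.testing.assert_array_equal(full, gt & box_mask(box, gt.shape))

    def test_thrombus_outside_initial_box_recovered_by_moving(self):
        gt = np.zeros((128, 160, 128), dtype=bool)
        gt[60:80, 120:130, 60:68] = True
        point = (70, 80, 64)  # 40+ voxels from the thrombus laterally
        assert not ts.make_initial_box(point, gt.shape).extract(gt).any()
        predictor = gt_clipped_predictor(gt)
        box, full, prov = ts.dynamic_box(point, gt.shape, predictor)
        assert full.any() and (full & gt).sum() > 0

    def test_empty_predictor_returns_empty_grid_mask(self):
        predictor = lambda b: np.zeros(b.shape, dtype=bool)
        box, full, prov = ts.dynamic_box((50, 50, 50), (100, 100, 100), predictor)
        assert not full.any()

    def test_gt_fraction_never_decreases_with_stub_predictor(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            gt = np.zeros((128, 128, 128), dtype=bool)
            z, y, x = rng.integers(30, 80, 3)
            gt[z:z + 25, y:y + 8, x:x + 8] = True
            point = tuple(int(v) for v in
                          np.clip(rng.integers(-20, 20, 3) + [z + 12, y + 4, x + 4],
                                  0, 127))
            predictor = gt_clipped_predictor(gt)
            initial = ts.make_initial_box(point, gt.shape)
            frac0 = initial.extract(gt).sum() / gt.sum()
            _, full, _ = ts.dynamic_box(point, gt.shape, predictor)
            assert (full & gt).sum() / gt.sum() >= frac0 - 1e-12


def box_mask(box: ts.BoundingBox, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[box.slices] = True
    return m
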