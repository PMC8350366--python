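"""Evaluation metrics against brute-force voxel-count oracles."""

import numpy as np
import pandas as pd
import pytest

from imsctseg.cascade import BoundingBox3D
from imsctseg.metrics import (
    MetricsConfig,
    aggregate,
    bbox_inclusion,
    detection_flags,
    dice_score,
    evaluate_subject,
    precision_recall,
    volume_differences,
)


class TestDiceScore:
    def test_identical_masks(self, rng):
        m = (rng.random((6, 6, 6)) > 0.4).astype(np.uint8)
        assert dice_score(m, m) == 1.0

    def test_false_positive_scores_zero(self):
        pred = np.ones((4, 4, 4), dtype=np.uint8)
        assert dice_score(pred, np.zeros_like(pred)) == 0.0

    def test_absent_case_excluded(self):
        empty = np.zeros((4, 4, 4), dtype=np.uint8)
        assert dice_score(empty, empty) is None

    def test_shifted_cube_half_overlap(self):
        p = np.zeros((6, 6, 6), dtype=np.uint8)
        g = np.zeros((6, 6, 6), dtype=np.uint8)
        p[0:2, 0:2, 0:2] = 1  # 8-voxel cube
        g[1:3, 0:2, 0:2] = 1  # shifted so the intersection is 4 voxels
        assert dice_score(p, g) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        for _ in range(20):
            p = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
            g = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
            assert dice_score(p, g) == dice_score(g, p)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


class TestDetection:
    def test_overlap_at_threshold_counts(self):
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        p[0, 0, :3] = 1
        g[0, 0, :3] = 1  # 3 voxels x 2 mm^3 = 6 mm^3, inclusive threshold
        tp, fp = detection_flags(p, g, (1, 1, 2))
        assert tp is True and fp is None

    def test_overlap_below_threshold(self):
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        p[0, 0, :2] = 1
        g[0, 0, :4] = 1  # overlap 2 voxels = 4 mm^3 < 6 mm^3
        tp, _ = detection_flags(p, g, (1, 1, 2))
        assert tp is False

    def test_absent_structure_no_prediction(self):
        z = np.zeros((4, 4, 4), dtype=np.uint8)
        assert detection_flags(z, z, (1, 1, 2)) == (None, False)

    def test_false_positive_needs_minimum_volume(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        p[0, 0, :2] = 1  # 4 mm^3 < 6 mm^3: too small to count as FP
        assert detection_flags(p, g, (1, 1, 2))[1] is False
        p[0, 0, :3] = 1
        assert detection_flags(p, g, (1, 1, 2))[1] is True


class TestPrecisionRecall:
    def test_perfect(self, rng):
        m = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        m[0, 0, 0] = 1
        assert precision_recall(m, m) == (1.0, 1.0)

    def test_superset_prediction(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        g[:2, :2, :2] = 1
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        p[:2, :2, :4] = 1  # |P| = 2 |G|
        assert precision_recall(p, g) == (0.5, 1.0)

    def test_disjoint(self):
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        p[0], g[1] = 1, 1
        assert precision_recall(p, g) == (0.0, 0.0)

    def test_empty_prediction_undefined_precision(self):
        g = np.ones((3, 3, 3), dtype=np.uint8)
        prec, rec = precision_recall(np.zeros_like(g), g)
        assert prec is None and rec == 0.0


class TestVolumeDifferences:
    def test_equal_volumes(self, rng):
        g = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        g[0, 0, 0] = 1
        rvd, avd = volume_differences(g, g, (1, 1, 2))
        assert rvd == 0.0 and avd == 0.0

    def test_oversegmentation_is_negative(self):
        g = np.zeros((10, 5, 5), dtype=np.uint8)
        g[:5] = 1
        p = np.zeros((10, 5, 5), dtype=np.uint8)
        p[:6] = 1  # V_pred = 1.2 V_gt
        rvd, avd = volume_differences(p, g, (1, 1, 1))
        assert rvd == pytest.approx(-0.2)
        assert avd == pytest.approx(0.2)

    def test_total_miss(self):
        g = np.ones((3, 3, 3), dtype=np.uint8)
        rvd, avd = volume_differences(np.zeros_like(g), g, (1, 1, 1))
        assert rvd == 1.0 and avd == 1.0

    def test_empty_gt_undefined(self):
        p = np.ones((3, 3, 3), dtype=np.uint8)
        assert volume_differences(p, np.zeros_like(p), (1, 1, 1)) == (None, None)


class TestBBoxInclusion:
    def test_contained(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m[3:6, 3:6, 3:6] = 1
        box = BoundingBox3D((2, 2, 2), (7, 7, 7))
        assert bbox_inclusion(m, box) == (True, 1.0)

    def test_voxel_at_hi_index_excluded_by_half_open_convention(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m[3:6, 3, 3] = 1
        m[6, 3, 3] = 1  # exactly at hi on axis 0
        box = BoundingBox3D((3, 3, 3), (6, 6, 6))
        full, frac = bbox_inclusion(m, box)
        assert full is False and frac == pytest.approx(0.75)

    def test_empty_lesion_contained_by_convention(self):
        box = BoundingBox3D((0, 0, 0), (2, 2, 2))
        assert bbox_inclusion(np.zeros((4, 4, 4)), box) == (True, 1.0)


class TestOracles:
    def test_kernels_match_voxel_count_oracles(self, rng):
        spacing = (1.0, 1.0, 2.0)
        vox = float(np.prod(spacing))
        for _ in range(100):
            p = (rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)).astype(np.uint8)
            g = (rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)).astype(np.uint8)
            np_, ng = int(p.sum()), int(g.sum())
            ni = int((p & g).sum())
            if ng:
                assert dice_score(p, g) == pytest.approx(2 * ni / (np_ + ng), abs=1e-12)
                rvd, avd = volume_differences(p, g, spacing)
                assert rvd == pytest.approx((ng - np_) / ng, abs=1e-12)
                assert avd == pytest.approx(abs(rvd), abs=1e-12)
                assert detection_flags(p, g, spacing)[0] == (ni * vox >= 6.0)
            if np_:
                assert precision_recall(p, g)[0] == pytest.approx(ni / np_, abs=1e-12)


class TestAggregate:
    @staticmethod
    def _frame(dices):
        rows = []
        for i, d in enumerate(dices):
            rows.append({
                "subject_id": f"s{i}", "structure": "whole", "gt_present": d is not None,
                "dice": d, "true_positive": None if d is None else True,
                "false_positive": None, "precision": d, "recall": d,
                "rvd": 0.0 if d is not None else None,
                "avd": 0.0 if d is not None else None,
            })
        return pd.DataFrame(rows)

    def test_single_split_zero_std(self):
        rep = aggregate([self._frame([0.5, 0.7])])
        row = rep.summary.iloc[0]
        assert row["dice_mean"] == pytest.approx(0.6)
        assert row["dice_std"] == 0.0

    def test_two_splits_closed_form(self):
        rep = aggregate([self._frame([0.6]), self._frame([0.8])])
        row = rep.summary.iloc[0]
        assert row["dice_mean"] == pytest.approx(0.7)
        assert row["dice_std"] == pytest.approx(0.1)  # population std

    def test_all_absent_marked_not_evaluable(self):
        rep = aggregate([self._frame([None, None])])
        row = rep.summary.iloc[0]
        assert np.isnan(row["dice_mean"]) and row["dice_n_splits"] == 0

    def test_requires_at_least_one_split(self):
        with pytest.raises(ValueError):
            aggregate([])


def test_restricted_dice_never_below_cohort_dice(rng):
    """Excluding false-positive zeros (absent structures) can only raise
    the cohort mean Dice."""
    dices, present = [], []
    for _ in range(30):
        if rng.random() < 0.5:  # absent structure, sometimes falsely predicted
            dices.append(0.0 if rng.random() < 0.5 else None)
            present.append(False)
        else:
            dices.append(float(rng.uniform(0.3, 0.9)))
            present.append(True)
    cohort = [d for d in dices if d is not None]
    restricted = [d for d, pr in zip(dices, present) if pr]
    assert np.mean(restricted) >= np.mean(cohort)


def test_evaluate_subject_structure_rows(subject):
    pred = subject.labels.data.copy()
    frame = evaluate_subject(pred, subject.labels.data, subject.labels.spacing, "s0")
    assert set(frame["structure"]) == {"whole", "tumor", "cavity", "edema"}
    whole = frame[frame["structure"] == "whole"].iloc[0]
    assert whole["dice"] == 1.0 and whole["true_positive"] is True
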