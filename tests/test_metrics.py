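"""Quality metrics against independent brute-force pixel-level oracles."""

import numpy as np
import pytest

import panfat as pf
from panfat.errors import UndefinedMetricError
from panfat.superpixel import _summaries
from panfat.types import SuperpixelMap

from oracles import (br_oracle, cp_oracle, dice_oracle, random_label_field,
                     ue_oracle)


def make_map(labels):
    labels = np.asarray(labels, dtype=np.int32)
    k, centers, sizes = _summaries(labels)
    return SuperpixelMap(labels=labels, K_actual=k, centers=centers, sizes=sizes)


class TestUndersegmentationError:
    def test_zero_when_boundaries_coincide(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[:, 3:] = 1
        gt = np.zeros((6, 6), dtype=bool)
        gt[:, 3:] = True
        assert pf.compute_ue(make_map(labels), gt) == 0.0

    def test_hand_grid_counts(self):
        # gt = top two rows (8 px); the object superpixel gains 2 background
        # pixels and loses 1 ground-truth pixel: UE = 1 / (8 + 2)
        labels = np.ones((4, 4), dtype=np.int32)
        labels[0, :] = 0
        labels[1, :3] = 0
        labels[2, 0] = labels[2, 1] = 0
        gt = np.zeros((4, 4), dtype=bool)
        gt[:2, :] = True
        spmap = make_map(labels)
        assert pf.compute_ue(spmap, gt) == pytest.approx(0.1)
        assert pf.compute_ue(spmap, gt) == pytest.approx(ue_oracle(labels, gt))

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pf.compute_ue(make_map(np.zeros((4, 4))), np.zeros((4, 4), bool))

    def test_bounded_on_random_fields(self, rng):
        for _ in range(100):
            labels = random_label_field(rng, 8, 8, 5)
            gt = rng.random((8, 8)) < 0.4
            if not gt.any():
                continue
            ue = pf.compute_ue(make_map(labels), gt)
            assert 0.0 <= ue <= 1.0
            assert ue == pytest.approx(ue_oracle(labels, gt))


class TestBoundaryRecall:
    def test_superset_boundary_gives_one(self):
        labels = random_label_field(np.random.default_rng(0), 8, 8, 6)
        gt = np.zeros((8, 8), bool)
        gt[2:5, 2:5] = True
        assert pf.compute_br(make_map(labels), gt, d=7) == 1.0

    def test_no_nearby_boundary_gives_zero(self):
        labels = np.zeros((9, 9), dtype=np.int32)  # no superpixel boundary
        gt = np.zeros((9, 9), bool)
        gt[4, 4] = True
        assert pf.compute_br(make_map(labels), gt, d=2) == 0.0

    def test_three_of_four_matched(self):
        # gt strip has 4 boundary pixels; a label edge coincides with 3 of them
        labels = np.zeros((4, 8), dtype=np.int32)
        labels[1:3, 3:6] = 1
        gt = np.zeros((4, 8), bool)
        gt[1, 1:5] = True
        spmap = make_map(labels)
        assert pf.compute_br(spmap, gt, d=0) == pytest.approx(0.75)
        assert pf.compute_br(spmap, gt, d=0) == pytest.approx(br_oracle(labels, gt, 0))

    def test_flat_ground_truth_rejected(self):
        labels = random_label_field(np.random.default_rng(0), 6, 6, 3)
        with pytest.raises(UndefinedMetricError):
            pf.compute_br(make_map(labels), np.ones((6, 6), bool), d=1)


class TestASA:
    @pytest.mark.parametrize("pred,ref,expected", [
        (100.0, 100.0, 100.0),
        (0.0, 100.0, 0.0),
        (90.0, 100.0, 90.0),
        (250.0, 100.0, 0.0),  # floored
    ])
    def test_area_agreement(self, pred, ref, expected):
        assert pf.compute_asa(pred, ref) == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pf.compute_asa(10.0, 0.0)


class TestCompactness:
    def test_single_square_superpixel(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        n, p = 32 * 32, 4 * 32
        assert pf.compute_cp(make_map(labels)) == pytest.approx(4 * np.pi * n / p**2)

    def test_stripes_are_non_compact(self):
        labels = np.tile(np.arange(16, dtype=np.int32), (16, 1))
        assert pf.compute_cp(make_map(labels)) < 0.3

    def test_matches_oracle_on_random_fields(self, rng):
        for _ in range(30):
            labels = random_label_field(rng, 7, 7, 4)
            spmap = make_map(labels)
            assert pf.compute_cp(spmap) == pytest.approx(cp_oracle(labels))


class TestBalanceIndex:
    def test_equal_terms_balance_to_zero(self):
        assert pf.balance_index(0.5, 0.5) == pytest.approx(0.0)

    def test_direct_evaluations(self):
        assert pf.balance_index(0.75, 1.0) == pytest.approx(0.25)
        assert pf.balance_index(0.9, 0.6) == pytest.approx(-0.5)

    def test_zero_compactness_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pf.balance_index(0.5, 0.0)


class TestDice:
    def test_identity_and_disjoint(self):
        x = np.zeros((5, 5), bool)
        x[1:3, 1:3] = True
        y = np.zeros((5, 5), bool)
        y[3:5, 3:5] = True
        assert pf.dice_coefficient(x, x) == 1.0
        assert pf.dice_coefficient(x, y) == 0.0

    def test_partial_overlap(self):
        x = np.zeros((4, 4), bool)
        x[0, :4] = True  # |X| = 4
        y = np.zeros((4, 4), bool)
        y[0, :2] = True  # |Y| = 2, overlap 2
        assert pf.dice_coefficient(x, y) == pytest.approx(2 * 2 / 6)

    def test_symmetric_and_bounded_on_random_masks(self, rng):
        for _ in range(50):
            x = rng.random((6, 6)) < 0.5
            y = rng.random((6, 6)) < 0.5
            if not (x.any() or y.any()):
                continue
            d = pf.dice_coefficient(x, y)
            assert d == pf.dice_coefficient(y, x)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(dice_oracle(x, y))

    def test_both_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pf.dice_coefficient(np.zeros((3, 3), bool), np.zeros((3, 3), bool))
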