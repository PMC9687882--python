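"""Calibration, erosion, MR-opsy filtering, areas and volumes."""

import numpy as np
import pytest

import panfat as pf
from panfat.errors import (ConfigurationError, FitError, InvalidInputError,
                           UndefinedMetricError)
from panfat.quantify import IntensityCalibration, fat_volume, validate_regression
from panfat.types import CalibrationCurve, FatFractionMap, GraySlice

from oracles import erosion_oracle

IDENTITY = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0,
                            valid_range=(0.0, 100.0))


class TestCalibration:
    def test_noiseless_series_recovers_line_exactly(self):
        series = pf.generate_phantom_series(slope=2.0, intercept=10.0,
                                            noise_sd=0.0, seed=0)
        curve = pf.fit_calibration(series)
        assert curve.slope == pytest.approx(1 / 2.0, abs=1e-9)
        # fraction = (intensity - 10) / 2  =>  intercept = -5
        assert curve.intercept == pytest.approx(-5.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_point_identity_line(self):
        est = IntensityCalibration().fit([0.0, 100.0], [0.0, 100.0])
        assert est.slope_ == pytest.approx(1.0)
        assert est.intercept_ == pytest.approx(0.0)

    def test_noisy_series_keeps_high_r_squared(self):
        series = pf.generate_phantom_series(noise_sd=0.5, seed=3)
        assert pf.fit_calibration(series).r_squared >= 0.99

    def test_degenerate_series_rejected(self):
        with pytest.raises(FitError):
            IntensityCalibration().fit([5.0, 5.0, 5.0], [0.0, 50.0, 100.0])


class TestApplyCalibration:
    def test_identity_curve_passes_values_through(self):
        sl = GraySlice(np.full((8, 8), 50.0), phase="fat")
        ff = pf.apply_calibration(sl, IDENTITY, np.ones((8, 8), bool))
        assert np.allclose(ff.values, 50.0)

    def test_negative_predictions_clip_to_zero(self):
        curve = CalibrationCurve(slope=1.0, intercept=-10.0, r_squared=1.0,
                                 valid_range=(0.0, 100.0))
        sl = GraySlice(np.full((4, 4), 5.0), phase="fat")
        ff = pf.apply_calibration(sl, curve, np.ones((4, 4), bool))
        assert np.allclose(ff.values, 0.0)

    def test_out_of_range_intensities_counted(self):
        sl = GraySlice(np.array([[50.0, 500.0]]), phase="fat")
        ff = pf.apply_calibration(sl, IDENTITY, np.ones((1, 2), bool))
        assert ff.n_out_of_range == 1

    def test_recovers_generated_fraction_map(self, calibration_curve):
        pair = pf.generate_slice_pair(shape=(128, 128), fat_fraction=8.0,
                                      noise_sd=1.0, seed=5)
        ff = pf.apply_calibration(pair.fat, calibration_curve, pair.gt_mask)
        err = np.abs(ff.values[pair.gt_mask]
                     - pair.true_fat_fraction_map[pair.gt_mask])
        assert err.mean() < 1.0


class TestErosion:
    def test_kernel_one_is_identity(self, rng):
        mask = rng.random((12, 12)) < 0.5
        assert np.array_equal(pf.erode_mask(mask, 1), mask)

    def test_square_block_shrinks_to_interior(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        out = pf.erode_mask(mask, 3)
        assert out.sum() == 9
        assert out[3:6, 3:6].all()

    def test_even_kernel_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.erode_mask(np.ones((4, 4), bool), 4)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((14, 14)) < 0.6
            for k in (3, 5):
                assert np.array_equal(pf.erode_mask(mask, k),
                                      erosion_oracle(mask, k))

    def test_anti_extensive_and_monotone(self, rng):
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.7
            e3 = pf.erode_mask(mask, 3)
            e5 = pf.erode_mask(mask, 5)
            assert not (e3 & ~mask).any()
            assert not (e5 & ~e3).any()


class TestMrOpsy:
    def test_band_membership(self):
        vals = np.array([[0.5, 5.0, 15.0, 25.0]])
        ff = FatFractionMap(values=vals, mask=np.ones((1, 4), bool))
        kept, n_kept, n_excl = pf.mr_opsy_filter(ff)
        assert n_kept == 2 and n_excl == 2
        assert kept.tolist() == [[False, True, True, False]]

    def test_all_zero_gives_empty_mask(self):
        ff = FatFractionMap(values=np.zeros((3, 3)), mask=np.ones((3, 3), bool))
        kept, n_kept, _ = pf.mr_opsy_filter(ff)
        assert n_kept == 0 and not kept.any()

    def test_band_endpoints_inclusive(self):
        vals = np.array([[1.0, 20.0]])
        ff = FatFractionMap(values=vals, mask=np.ones((1, 2), bool))
        _, n_kept, _ = pf.mr_opsy_filter(ff)
        assert n_kept == 2


class TestVolumes:
    def test_slice_area_examples(self):
        assert pf.slice_area(np.zeros((8, 8), bool), 1.0) == 0.0
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        assert pf.slice_area(mask, 1.0) == 100.0
        mask250 = np.zeros((25, 10), bool)
        mask250[:, :] = True
        assert pf.slice_area(mask250, 2.0) == 1000.0

    def test_cavalieri_sum_of_constant_slices(self):
        mask = np.zeros((20, 20), bool)
        mask[:, :] = True
        assert pf.pancreas_volume([mask] * 7, spacing=1.0, thickness=3.0) == \
            pytest.approx(7 * 400 * 3)

    def test_requires_slices_and_positive_thickness(self):
        with pytest.raises(InvalidInputError):
            pf.pancreas_volume([], 1.0, 3.0)
        with pytest.raises(InvalidInputError):
            pf.pancreas_volume([np.ones((4, 4), bool)], 1.0, 0.0)


class TestFatVolume:
    def test_zero_fat_stack_quantifies_to_zero(self, calibration_curve):
        stack = pf.generate_stack(n_slices=3, shape=(96, 96), fat_fraction=0.0,
                                  noise_sd=0.0, seed=0)
        res = fat_volume([p.fat for p in stack.slices],
                         [p.gt_mask for p in stack.slices],
                         calibration_curve, spacing=1.0, thickness=3.0)
        assert res.fat_volume_mm3 == 0.0
        assert res.fat_fraction_pct == 0.0

    def test_single_kept_pixel_volume(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True  # erodes (k=5) to the single center pixel
        fat = np.zeros((9, 9))
        fat[4, 4] = 10.0
        res = fat_volume([fat], [mask], IDENTITY, spacing=1.0, thickness=3.0,
                         kernel_size=5)
        assert res.per_slice[0].kept_pixels == 1
        assert res.fat_volume_mm3 == pytest.approx(0.10 * 1.0 * 3.0)

    def test_fat_capped_by_band_ceiling(self, rng, calibration_curve):
        stack = pf.generate_stack(n_slices=3, shape=(96, 96), fat_fraction=12.0,
                                  seed=1)
        res = fat_volume([p.fat for p in stack.slices],
                         [p.gt_mask for p in stack.slices],
                         calibration_curve, spacing=1.0, thickness=3.0)
        eroded_vol = sum(s.eroded_area_mm2 for s in res.per_slice) * 3.0
        assert res.fat_volume_mm3 <= 0.20 * eroded_vol + 1e-6

    def test_missing_calibration_rejected(self):
        with pytest.raises(ConfigurationError):
            fat_volume([np.zeros((8, 8))], [np.ones((8, 8), bool)], None, 1.0)

    def test_deterministic_results(self, calibration_curve):
        stack = pf.generate_stack(n_slices=3, shape=(96, 96), seed=2)
        args = ([p.fat for p in stack.slices], [p.gt_mask for p in stack.slices],
                calibration_curve)
        a = fat_volume(*args, spacing=1.0, thickness=3.0)
        b = fat_volume(*args, spacing=1.0, thickness=3.0)
        assert a.to_dict() == b.to_dict()

    def test_denominator_flag_changes_only_the_fraction(self, calibration_curve):
        stack = pf.generate_stack(n_slices=3, shape=(96, 96), seed=3)
        args = ([p.fat for p in stack.slices], [p.gt_mask for p in stack.slices],
                calibration_curve)
        full = fat_volume(*args, spacing=1.0, thickness=3.0, denominator="full")
        eroded = fat_volume(*args, spacing=1.0, thickness=3.0, denominator="eroded")
        assert full.fat_volume_mm3 == eroded.fat_volume_mm3
        assert eroded.fat_fraction_pct >= full.fat_fraction_pct


class TestValidateRegression:
    def test_perfect_agreement(self):
        out = validate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["slope"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            validate_regression([1.0], [1.0])
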