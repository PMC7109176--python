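"""ROI biomarkers and spatial agreement metrics."""

import math

import numpy as np
import pytest

from petgmm.image import BinaryMask
from petgmm.maps import ADCFitResult
from petgmm.metrics import (
    center_of_gravity,
    cog_displacement,
    dice,
    roi_metrics,
)


def _mask(arr, spacing=(2.0, 2.0), origin=(0.0, 0.0)):
    return BinaryMask(np.asarray(arr, dtype=bool), spacing=spacing, origin=origin)


def _adc_fit(values, valid=None, spacing=(2.0, 2.0)):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return ADCFitResult(
        adc=np.where(valid, values, np.nan),
        s0=np.ones_like(values),
        valid=np.asarray(valid, bool),
        bvalues_used=(200.0, 400.0, 700.0),
        spacing=spacing,
        origin=(0.0, 0.0),
    )


class TestDice:
    def test_identity_symmetry_disjoint(self, rng):
        a_arr = rng.random((10, 10)) > 0.5
        a = _mask(a_arr)
        b = _mask(rng.random((10, 10)) > 0.5)
        assert dice(a, a) == 1.0
        assert dice(a, b) == dice(b, a)
        disjoint = _mask(~a_arr)
        assert dice(a, disjoint) == 0.0

    def test_known_overlap_value(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:4] = True  # |a| = 4
        b.flat[1:7] = True  # |b| = 6, overlap 3
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.6)

    def test_empty_mask_conventions(self):
        empty = _mask(np.zeros((3, 3)))
        full = _mask(np.ones((3, 3)))
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(_mask(np.ones((3, 3))), _mask(np.ones((4, 4))))


class TestCenterOfGravity:
    def test_single_voxel(self):
        arr = np.zeros((8, 8), bool)
        arr[3, 4] = True
        assert center_of_gravity(_mask(arr)) == (6.0, 8.0)

    def test_symmetric_pair_gives_midpoint(self):
        arr = np.zeros((8, 8), bool)
        arr[2, 2] = arr[6, 2] = True
        assert center_of_gravity(_mask(arr)) == (8.0, 4.0)

    def test_matches_bruteforce_loop(self, rng):
        arr = rng.random((15, 15)) < 0.25
        arr[4, 4] = True
        m = _mask(arr, spacing=(1.5, 2.0), origin=(3.0, -1.0))
        xs, ys, n = 0.0, 0.0, 0
        for i in range(15):
            for j in range(15):
                if arr[i, j]:
                    xs += 3.0 + i * 1.5
                    ys += -1.0 + j * 2.0
                    n += 1
        got = center_of_gravity(m)
        assert got[0] == pytest.approx(xs / n)
        assert got[1] == pytest.approx(ys / n)

    def test_empty_mask_not_applicable(self):
        with pytest.raises(ValueError, match="not applicable"):
            center_of_gravity(_mask(np.zeros((3, 3))))


class TestCogDisplacement:
    def test_identity(self, rng):
        m = _mask(rng.random((9, 9)) > 0.6)
        om = cog_displacement(m, m, area_ref_cm2=2.0)
        assert om.cog_mm == 0.0
        assert om.cog_normalized == 0.0
        assert om.dice == 1.0

    def test_two_voxel_row_shift_at_2mm(self):
        a = np.zeros((10, 10), bool)
        a[2:5, 2:5] = True
        b = np.roll(a, 2, axis=0)
        om = cog_displacement(_mask(a), _mask(b))
        assert om.cog_mm == pytest.approx(4.0)

    def test_normalization_by_sqrt_reference_area(self):
        a = np.zeros((10, 10), bool)
        a[2:4, 2:4] = True
        b = np.roll(a, 2, axis=0)  # 4 mm displacement
        om = cog_displacement(_mask(a), _mask(b), area_ref_cm2=4.0)
        # sqrt(400 mm^2) = 20 mm -> 4 / 20
        assert om.cog_normalized == pytest.approx(0.2)

    def test_translation_invariance_of_dice_and_cog(self, rng):
        arr = np.zeros((20, 20), bool)
        arr[5:9, 6:11] = True
        other = np.roll(arr, (1, 2), axis=(0, 1))
        base = cog_displacement(_mask(arr), _mask(other))
        shifted = cog_displacement(
            _mask(np.roll(arr, 3, axis=0)), _mask(np.roll(other, 3, axis=0))
        )
        assert shifted.dice == base.dice
        assert shifted.cog_mm == pytest.approx(base.cog_mm)

    def test_k_voxel_translate_displacement(self):
        arr = np.zeros((20, 20), bool)
        arr[3:7, 3:7] = True
        for k in (1, 3, 5):
            om = cog_displacement(_mask(arr), _mask(np.roll(arr, k, axis=1)))
            assert om.cog_mm == pytest.approx(k * 2.0)

    def test_empty_mask_flagged(self):
        m = _mask(np.ones((3, 3)))
        om = cog_displacement(m, _mask(np.zeros((3, 3))), area_ref_cm2=1.0)
        assert math.isnan(om.cog_mm)
        assert "cog_not_applicable" in om.flags
        assert om.dice == 0.0


class TestRoiMetrics:
    def test_area_from_voxel_count_and_spacing(self):
        arr = np.zeros((20, 20), bool)
        arr.flat[:100] = True
        rm = roi_metrics(_mask(arr), _adc_fit(np.full((20, 20), 1.0e-3)))
        assert rm.area_cm2 == pytest.approx(4.0)  # 100 * 4 mm^2
        assert rm.n_voxels == 100

    def test_mean_over_constant_field(self, rng):
        arr = rng.random((10, 10)) > 0.5
        rm = roi_metrics(_mask(arr), _adc_fit(np.full((10, 10), 1.2e-3)))
        assert rm.mean_adc == pytest.approx(1.2e-3)

    def test_invalid_voxels_excluded_but_counted_in_area(self):
        arr = np.zeros((5, 5), bool)
        arr[:2, :3] = True  # 6 voxels
        valid = np.ones((5, 5), bool)
        valid[0, :3] = False  # 3 masked voxels invalid
        values = np.full((5, 5), 1.0e-3)
        values[1, :3] = 2.0e-3
        rm = roi_metrics(_mask(arr), _adc_fit(values, valid=valid))
        assert rm.n_voxels == 6
        assert rm.n_valid_adc == 3
        assert rm.mean_adc == pytest.approx(2.0e-3)

    def test_empty_mask_flagged(self):
        rm = roi_metrics(_mask(np.zeros((4, 4))), _adc_fit(np.ones((4, 4))))
        assert rm.area_cm2 == 0.0
        assert math.isnan(rm.mean_adc)
        assert "empty_mask" in rm.flags

    def test_area_additive_over_disjoint_masks(self, rng):
        a = rng.random((12, 12)) > 0.7
        b = (rng.random((12, 12)) > 0.7) & ~a
        adc = _adc_fit(np.full((12, 12), 1e-3), spacing=(2.0, 2.0))
        area_union = roi_metrics(_mask(a | b), adc).area_cm2
        assert area_union == pytest.approx(
            roi_metrics(_mask(a), adc).area_cm2 + roi_metrics(_mask(b), adc).area_cm2
        )
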