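import numpy as np
import pytest

from valvect import (
    CTVolume,
    InputError,
    UNDEFINED_RATIO,
    ValvectError,
    agatston_score,
    classify_predominance,
    mask_volume,
    quantify_valve,
)
from valvect.geometry import ValveSliceStack
from valvect.quantification import CALCIUM_DOMINANT, FIBROSIS_PREDOMINANT
from valvect.segmentation import SliceSegmentation

from .oracles import agatston_slice


def make_stack(n=1, size=40, spacing=0.5, thickness=3.0):
    return ValveSliceStack(
        slices=np.zeros((n, size, size)),
        slice_thickness=thickness,
        in_plane_spacing=spacing,
        origin_offsets=(np.arange(n) + 0.5) * thickness,
        roi_mask=np.ones((n, size, size), dtype=bool),
        centre=np.zeros(3),
        basis_u=np.array([1.0, 0, 0]),
        basis_v=np.array([0, 1.0, 0]),
        normal=np.array([0, 0, 1.0]),
    )


def seg_with_counts(n_calc, n_noncalc, size=40, index=0):
    calc = np.zeros((size, size), dtype=bool)
    noncalc = np.zeros((size, size), dtype=bool)
    calc.ravel()[:n_calc] = True
    noncalc.ravel()[size * size - n_noncalc :] = True
    return SliceSegmentation(calc_mask=calc, noncalc_mask=noncalc, slice_index=index)


class TestMaskVolume:
    def test_empty_masks(self):
        assert mask_volume([np.zeros((5, 5), dtype=bool)], 0.5, 3.0) == 0.0

    def test_pixel_count_arithmetic(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask.ravel()[:100] = True
        assert mask_volume([mask], 0.5, 3.0) == pytest.approx(100 * 0.75)

    def test_additive_across_slices(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        c = np.zeros((20, 20), dtype=bool)
        a.ravel()[:40] = True
        b.ravel()[:60] = True
        c.ravel()[:100] = True
        assert mask_volume([a, b], 0.5, 3.0) == mask_volume([c], 0.5, 3.0)


class TestQuantifyValve:
    def test_cohort_median_single_patient(self):
        # indexed noncalc 79 and calc 82 mm^3/cm^2 on a 3 cm^2 annulus:
        # 316 and 328 analysis columns of 0.75 mm^3
        q = quantify_valve([seg_with_counts(328, 316)], make_stack(), 3.0)
        assert q.indexed_calc == pytest.approx(82.0)
        assert q.indexed_noncalc == pytest.approx(79.0)
        assert q.fibrocalcific_volume == pytest.approx(161.0)
        assert q.fibrocalcific_ratio == pytest.approx(79.0 / 82.0)
        assert q.fibrocalcific_ratio == pytest.approx(0.963, abs=5e-4)

    def test_no_calcium_gives_sentinel_and_flag(self):
        q = quantify_valve([seg_with_counts(0, 100)], make_stack(), 4.0)
        assert q.fibrocalcific_ratio is UNDEFINED_RATIO
        assert "no-calcium" in q.flags
        assert classify_predominance(q) == FIBROSIS_PREDOMINANT

    def test_equal_classes_ratio_exactly_one(self):
        q = quantify_valve([seg_with_counts(200, 200)], make_stack(), 4.0)
        assert q.fibrocalcific_ratio == 1.0
        assert classify_predominance(q) == CALCIUM_DOMINANT

    def test_identities_and_annulus_scaling(self):
        segs = [seg_with_counts(150, 250)]
        q1 = quantify_valve(segs, make_stack(), 2.5)
        q2 = quantify_valve(segs, make_stack(), 5.0)
        assert q1.fibrocalcific_volume == q1.indexed_calc + q1.indexed_noncalc
        assert q2.indexed_calc == pytest.approx(q1.indexed_calc / 2, rel=1e-12)
        assert q2.indexed_noncalc == pytest.approx(q1.indexed_noncalc / 2, rel=1e-12)
        assert q2.fibrocalcific_ratio == pytest.approx(
            q1.fibrocalcific_ratio, rel=1e-12
        )

    def test_zero_annulus_rejected(self):
        with pytest.raises(InputError):
            quantify_valve([seg_with_counts(10, 10)], make_stack(), 0.0)

    def test_undefined_ratio_orders_above_everything(self):
        assert UNDEFINED_RATIO > 1e12
        assert not (UNDEFINED_RATIO < 1e12)
        assert sorted([3.0, UNDEFINED_RATIO, 0.5])[-1] is UNDEFINED_RATIO


class TestClassifyPredominance:
    @pytest.mark.parametrize(
        "calc, noncalc, expected",
        [
            (100, 129, FIBROSIS_PREDOMINANT),  # ratio 1.29, mild-like
            (100, 47, CALCIUM_DOMINANT),  # ratio 0.47, severe-like
            (100, 100, CALCIUM_DOMINANT),  # boundary assigned to <= 1
        ],
    )
    def test_ratio_boundary(self, calc, noncalc, expected):
        q = quantify_valve([seg_with_counts(calc, noncalc)], make_stack(), 4.0)
        assert classify_predominance(q) == expected

    def test_empty_valve_rejected(self):
        q = quantify_valve([seg_with_counts(0, 0)], make_stack(), 4.0)
        with pytest.raises(ValvectError, match="empty valve"):
            classify_predominance(q)


def axial_volume(data, pixel_mm=1.0, thickness_mm=3.0):
    return CTVolume(
        np.asarray(data, dtype=np.float64),
        np.diag([pixel_mm, pixel_mm, thickness_mm, 1.0]),
    )


class TestAgatston:
    def test_no_calcium_scores_zero(self):
        res = agatston_score(axial_volume(np.full((20, 20, 3), 100.0)))
        assert res.score == 0.0 and res.n_lesions == 0

    def test_single_lesion_hand_computed(self):
        data = np.zeros((20, 20, 1))
        data[5:7, 5:7, 0] = 250.0  # 4 mm^2, weight 2
        res = agatston_score(axial_volume(data))
        assert res.score == pytest.approx(8.0)
        assert res.n_lesions == 1

    def test_sub_millimetre_lesion_excluded(self):
        data = np.zeros((20, 20, 1))
        data[5, 5, 0] = 500.0
        res = agatston_score(axial_volume(data, pixel_mm=np.sqrt(0.5)))
        assert res.score == 0.0

    def test_weight_band_edges(self):
        for peak, weight in [(130.0, 1), (199.9, 1), (200.0, 2), (300.0, 3), (400.0, 4)]:
            data = np.zeros((10, 10, 1))
            data[4:6, 4:6, 0] = peak
            res = agatston_score(axial_volume(data))
            assert res.score == pytest.approx(4.0 * weight), peak

    def test_matches_per_pixel_oracle_on_random_slices(self, rng):
        for _ in range(50):
            sl = rng.normal(90.0, 90.0, size=(64, 64))
            vol = axial_volume(sl[:, :, None])
            res = agatston_score(vol)
            assert res.score == pytest.approx(agatston_slice(sl, 1.0))
            assert (res.score == 0) == (res.n_lesions == 0)

    def test_nonstandard_thickness_needs_override(self):
        vol = CTVolume(np.zeros((5, 5, 5)), np.eye(4))
        with pytest.raises(InputError, match="3 mm"):
            agatston_score(vol)
        assert agatston_score(vol, allow_nonstandard_thickness=True).score == 0.0

    def test_roi_restricts_scoring(self):
        data = np.zeros((20, 20, 1))
        data[2:4, 2:4, 0] = 300.0
        data[10:12, 10:12, 0] = 300.0
        roi = np.zeros((20, 20, 1), dtype=bool)
        roi[10:12, 10:12, 0] = True
        res = agatston_score(axial_volume(data), roi=roi)
        assert res.score == pytest.approx(12.0)
        assert res.n_lesions == 1
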