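import math

import numpy as np
import pytest

from mirprio.errors import PreconditionError
from mirprio.quantification import (
    CtQuad, HemisphereVolumes, IntensityImagePair, StandardCurve,
    copies_from_ct, fit_standard_curve, fold_change_ddct,
    lesion_volume_percent, manders_m2, pearson_colocalization,
    shape_descriptors,
)


class TestLesionVolume:
    @pytest.mark.parametrize("vols,expected", [
        ((100, 100, 25), 25.0),   # no edema: reduces to lesion/contra
        ((100, 110, 30), 20.0),   # edema deflates the raw ratio
        ((100, 100, 0), 0.0),
    ])
    def test_worked_values(self, vols, expected):
        assert lesion_volume_percent(HemisphereVolumes(*vols)) == expected

    def test_zero_contra_rejected(self):
        with pytest.raises(PreconditionError):
            lesion_volume_percent(HemisphereVolumes(0, 0, 0))

    def test_linear_in_lesion_volume(self):
        base = lesion_volume_percent(HemisphereVolumes(200, 210, 10))
        bumped = lesion_volume_percent(HemisphereVolumes(200, 210, 10 + 7))
        assert bumped - base == pytest.approx(100 * 7 / 200)


class TestFoldChange:
    def test_no_change_is_one(self):
        assert fold_change_ddct(CtQuad(20, 20, 20, 20)) == 1.0

    def test_one_cycle_earlier_doubles(self):
        assert fold_change_ddct(CtQuad(25, 20, 26, 20)) == 2.0

    def test_two_cycles_later_quarters(self):
        assert fold_change_ddct(CtQuad(27, 20, 25, 20)) == 0.25

    def test_swap_gives_reciprocal(self):
        q = CtQuad(24.3, 19.1, 26.7, 18.2)
        swapped = CtQuad(q.ct_target_control, q.ct_ref_control,
                         q.ct_target_sample, q.ct_ref_sample)
        assert fold_change_ddct(q) * fold_change_ddct(swapped) == \
            pytest.approx(1.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(PreconditionError):
            fold_change_ddct(CtQuad(float("nan"), 20, 20, 20))


class TestStandardCurve:
    def test_doubling_chemistry_slope(self):
        copies = [400.0 * 10 ** i for i in range(5)]  # 400 .. 4e6
        ct = [40 - math.log2(c) for c in copies]
        curve = fit_standard_curve(copies, ct)
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        curve = fit_standard_curve([100, 10000], [30, 24])
        assert curve.r_squared == 1.0
        assert copies_from_ct(curve, 30) == pytest.approx(100, rel=1e-9)

    def test_identical_copies_rejected(self):
        with pytest.raises(PreconditionError):
            fit_standard_curve([100, 100, 100], [30, 30, 30])

    def test_round_trip_inversion(self):
        copies = np.array([400.0 * 10 ** i for i in range(5)])
        ct = 40 - np.log2(copies)
        curve = fit_standard_curve(copies, ct)
        for c, t in zip(copies, ct):
            assert copies_from_ct(curve, t) == pytest.approx(c, rel=1e-6)

    def test_single_copy_at_intercept_ct(self):
        curve = StandardCurve(slope=-3.3219, intercept=40, r_squared=1.0)
        assert copies_from_ct(curve, 40.0) == pytest.approx(1.0)

    def test_dilution_endpoints_scale_linearly(self):
        # 10^4-fold concentration range maps 400 -> 4e6 copies
        assert 400 * (5e-9 / 0.5e-12) == pytest.approx(4e6)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        rng = np.random.default_rng(1)
        ch1 = rng.uniform(0, 255, (16, 16))
        pair = IntensityImagePair(ch1, 2 * ch1 + 5)
        assert pearson_colocalization(pair) == pytest.approx(1.0)

    def test_anticorrelated_channels(self):
        ch1 = np.arange(9, dtype=float).reshape(3, 3)
        assert pearson_colocalization(
            IntensityImagePair(ch1, -ch1)) == pytest.approx(-1.0)

    def test_fixed_3x3_matches_hand_formula(self):
        a = np.array([[1., 2, 3], [4, 5, 6], [7, 8, 10]])
        b = np.array([[2., 1, 4], [3, 6, 5], [9, 7, 11]])
        af, bf = a.ravel(), b.ravel()
        cov = np.mean((af - af.mean()) * (bf - bf.mean()))
        expected = cov / (af.std() * bf.std())
        assert pearson_colocalization(
            IntensityImagePair(a, b)) == pytest.approx(expected, abs=1e-12)

    def test_constant_channel_rejected(self):
        with pytest.raises(PreconditionError):
            pearson_colocalization(
                IntensityImagePair(np.ones((3, 3)), np.arange(9.).reshape(3, 3)))

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, (8, 8))
        b = rng.uniform(0, 100, (8, 8))
        r1 = pearson_colocalization(IntensityImagePair(a, b))
        r2 = pearson_colocalization(IntensityImagePair(3 * a + 7, 0.5 * b + 1))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestMandersM2:
    def test_identical_supports(self):
        a = np.array([[200., 0], [0, 200]])
        b = np.array([[150., 0], [0, 150]])
        assert manders_m2(IntensityImagePair(a, b)) == 1.0

    def test_disjoint_supports(self):
        a = np.array([[200., 0], [0, 0]])
        b = np.array([[0., 150], [150, 0]])
        assert manders_m2(IntensityImagePair(a, b)) == 0.0

    def test_printed_four_pixel_example(self):
        a = np.array([[60., 60, 40, 200]])
        b = np.array([[150., 50, 150, 150]])
        assert manders_m2(IntensityImagePair(a, b)) == pytest.approx(0.8125)

    def test_empty_denominator_is_zero_with_warning(self, caplog):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 200.0)
        assert manders_m2(IntensityImagePair(a, b)) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            IntensityImagePair(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_iba1_scale_invariance_with_coscaled_threshold(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 255, (10, 10))
        b = rng.uniform(0, 255, (10, 10))
        m1 = manders_m2(IntensityImagePair(a, b), 50, 100)
        m2 = manders_m2(IntensityImagePair(a, 4 * b), 50, 400)
        assert m1 == pytest.approx(m2)

    def test_unthresholded_partner_variant(self):
        a = np.array([[60., 60, 40, 200]])
        b = np.array([[150., 50, 150, 150]])
        # numerator over iba1-positive pixels only, denominator total arg1
        expected = (60 + 40 + 200) / (60 + 60 + 40 + 200)
        assert manders_m2(IntensityImagePair(a, b),
                          require_both=False) == pytest.approx(expected)


class TestShapeDescriptors:
    def _square(self, side, canvas=20):
        mask = np.zeros((canvas, canvas), dtype=np.int32)
        mask[2:2 + side, 2:2 + side] = 1
        return mask

    def test_square_closed_forms(self):
        d, = shape_descriptors(self._square(10))
        assert d.area == 100
        assert d.perimeter == 40
        assert d.circularity == pytest.approx(math.pi / 4)
        assert d.equiv_diameter == pytest.approx(math.sqrt(400 / math.pi))
        assert d.eccentricity == pytest.approx(0.0, abs=1e-12)
        assert d.solidity == pytest.approx(1.0)
        assert d.area_perimeter_ratio == pytest.approx(2.5)

    def test_bar_less_circular_than_square(self):
        canvas = np.zeros((10, 110), dtype=np.int32)
        canvas[4, 5:105] = 1  # 1x100 bar, area 100, perimeter 202
        bar, = shape_descriptors(canvas)
        square, = shape_descriptors(self._square(10))
        assert bar.perimeter == 202
        assert bar.circularity == pytest.approx(4 * math.pi * 100 / 202 ** 2)
        assert bar.circularity < square.circularity
        assert bar.eccentricity > square.eccentricity

    def test_convex_region_solidity_one(self):
        d, = shape_descriptors(self._square(7))
        assert d.solidity == pytest.approx(1.0, abs=1e-9)

    def test_multiple_labels_one_record_each(self):
        mask = np.zeros((20, 40), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[2:12, 20:30] = 2
        descs = shape_descriptors(mask)
        assert [d.label for d in descs] == [1, 2]
        assert descs[0].area == 36 and descs[1].area == 100

    def test_non_integer_mask_rejected(self):
        with pytest.raises(PreconditionError):
            shape_descriptors(np.zeros((4, 4)))
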