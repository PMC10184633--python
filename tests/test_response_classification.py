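import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inflamstate.core_model import Condition, Layer, ThresholdConfig
from inflamstate.response_classification import (
    EffectClass,
    ResponseClass,
    ShapeClass,
    additive_expectation,
    assign_response_class,
    classify_dataset,
    classify_effect,
    classify_shape,
    synergy_decomposition,
    timecourse_auc,
    timecourse_correlation,
)


class TestAUC:
    def test_rectangle(self):
        t = np.array([0.0, 24.0])
        assert timecourse_auc((t, np.array([1.0, 1.0]))) == pytest.approx(24.0, abs=1e-12)

    def test_triangle(self):
        t = np.array([0.0, 24.0])
        assert timecourse_auc((t, np.array([0.0, 2.0]))) == pytest.approx(24.0, abs=1e-12)

    def test_piecewise_hand_sum(self):
        t = np.array([0.0, 4.0, 24.0])
        v = np.array([0.0, 2.0, 2.0])
        assert timecourse_auc((t, v)) == pytest.approx(44.0, abs=1e-12)

    def test_signed(self):
        t = np.array([0.0, 24.0])
        assert timecourse_auc((t, np.array([-1.0, -1.0]))) == pytest.approx(-24.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            timecourse_auc((np.array([0.0]), np.array([1.0])))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="interpolate"):
            timecourse_auc((np.array([0.0, 4.0, 24.0]), np.array([0.0, np.nan, 1.0])))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_fine_grid_oracle_on_piecewise_linear(self, seed):
        rng = np.random.default_rng(seed)
        knots = np.sort(rng.uniform(0, 24, size=6))
        knots[0], knots[-1] = 0.0, 24.0
        knots = np.unique(knots)
        vals = rng.uniform(-3, 3, size=knots.size)
        fine_t = np.union1d(np.linspace(0, 24, 100_001), knots)
        fine_v = np.interp(fine_t, knots, vals)
        oracle = np.trapezoid(fine_v, fine_t)
        assert timecourse_auc((knots, vals)) == pytest.approx(oracle, abs=1e-9)


class TestCorrelation:
    def test_identical_courses(self):
        v = np.array([0.0, 1.0, 2.0, 3.0])
        assert timecourse_correlation(v, v) == pytest.approx(1.0)

    def test_negation(self):
        v = np.array([0.0, 1.0, 2.0, 3.0])
        assert timecourse_correlation(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_point_eight(self):
        r = timecourse_correlation(np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 2.0, 1.0, 3.0]))
        assert r == pytest.approx(0.8)

    def test_zero_variance_is_undefined_and_falls_to_none(self):
        r = timecourse_correlation(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))
        assert math.isnan(r)
        assert classify_shape(r, 0.9) is ShapeClass.NONE

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            timecourse_correlation(
                np.array([0.0, 1.0, 2.0]),
                np.array([0.0, 1.0, 2.0]),
                np.array([0.0, 1.0, 2.0]),
                np.array([0.0, 2.0, 4.0]),
            )


class TestShapeClassification:
    @pytest.mark.parametrize(
        "r_tnf,r_ifn,expected",
        [
            (0.9, 0.2, ShapeClass.S1),
            (0.2, 0.9, ShapeClass.S2),
            (0.9, 0.9, ShapeClass.S3),
            (0.1, 0.2, ShapeClass.S4),
            (0.5, 0.5, ShapeClass.NONE),  # in the (0.3, 0.7) gap
            (0.7, 0.7, ShapeClass.NONE),  # boundaries excluded (strict)
            (0.3, 0.3, ShapeClass.NONE),
            (0.9, 0.5, ShapeClass.S1),
            (float("nan"), 0.9, ShapeClass.NONE),
        ],
    )
    def test_rule_table(self, r_tnf, r_ifn, expected):
        assert classify_shape(r_tnf, r_ifn) is expected


class TestEffectClassification:
    @pytest.mark.parametrize(
        "comb,tnf,ifn,expected",
        [
            (10, 8, 1, EffectClass.E1),  # ratios 1.25 and 10
            (10, 1, 8, EffectClass.E2),
            (10, 2, 2, EffectClass.E3),  # both ratios 5 > 2
            (10, 8, 8, EffectClass.NONE),  # both 1.25
            (0, 5, 5, EffectClass.NONE),  # zero combined AUC
            (10, -8, 1, EffectClass.E3),  # sign disagreement forces that ratio to inf
            (10, 0, 8, EffectClass.E2),  # zero TNF single: its ratio is huge, IFN explains the response
        ],
    )
    def test_rule_table(self, comb, tnf, ifn, expected):
        assert classify_effect(comb, tnf, ifn) is expected


class TestFinalAssignment:
    @pytest.mark.parametrize(
        "shape,effect,expected",
        [
            (ShapeClass.S1, EffectClass.NONE, ResponseClass.TNF),
            (ShapeClass.S2, EffectClass.NONE, ResponseClass.IFN),
            (ShapeClass.S3, EffectClass.E1, ResponseClass.TNF),
            (ShapeClass.S3, EffectClass.E2, ResponseClass.IFN),
            (ShapeClass.S3, EffectClass.NONE, ResponseClass.COMMON),
            (ShapeClass.S3, EffectClass.E3, ResponseClass.SYNERGY),
            (ShapeClass.S4, EffectClass.NONE, ResponseClass.SYNERGY),
            (ShapeClass.NONE, EffectClass.E3, ResponseClass.SYNERGY),
            (ShapeClass.NONE, EffectClass.NONE, ResponseClass.NOT_CLASSIFIED),
            (ShapeClass.NONE, EffectClass.E1, ResponseClass.NOT_CLASSIFIED),
        ],
    )
    def test_default_rule_table(self, shape, effect, expected):
        assert assign_response_class(shape, effect) is expected

    def test_alternative_s3_reading(self):
        assert assign_response_class(ShapeClass.S3, EffectClass.NONE, "s3_or_e3") is ResponseClass.SYNERGY
        with pytest.raises(ValueError):
            assign_response_class(ShapeClass.S3, EffectClass.NONE, "bogus")


class TestAdditiveExpectation:
    def test_one_null_input(self):
        t = np.array([0.0, 12.0, 24.0])
        _, s = additive_expectation((t, np.array([0.0, 1.0, 2.0])), (t, np.zeros(3)))
        np.testing.assert_allclose(s, [0, 1, 2])

    def test_sum_and_commutativity(self):
        t = np.array([0.0, 12.0, 24.0])
        a, b = np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0])
        _, s1 = additive_expectation((t, a), (t, b))
        _, s2 = additive_expectation((t, b), (t, a))
        np.testing.assert_allclose(s1, [0, 2, 4])
        np.testing.assert_allclose(s1, s2)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            additive_expectation(
                (np.array([0.0, 24.0]), np.zeros(2)), (np.array([0.0, 12.0]), np.zeros(2))
            )


class TestSynergyDecomposition:
    @pytest.mark.parametrize(
        "tnf,ifn,comb,expected",
        [
            (4, 6, 10, (0.4, 0.6, 0.0)),
            (2, 2, 8, (0.25, 0.25, 0.5)),
            (6, 6, 10, (0.6, 0.6, -0.2)),  # sub-additive
        ],
    )
    def test_arithmetic(self, tnf, ifn, comb, expected):
        d = synergy_decomposition(tnf, ifn, comb)
        assert (d.frac_tnf, d.frac_ifn, d.frac_excess) == pytest.approx(expected)
        assert d.frac_tnf + d.frac_ifn + d.frac_excess == pytest.approx(1.0, abs=1e-9)

    def test_zero_combined_errors(self):
        with pytest.raises(ValueError):
            synergy_decomposition(1, 1, 0)


class TestTimeUnitInvariance:
    def test_classification_invariant_to_rescaling(self, small_dataset):
        """Only correlations and AUC ratios enter the rules, so expressing
        time in minutes instead of hours must not change any call."""
        _, matrices, _ = small_dataset
        m = matrices[Layer.TRANSCRIPT]
        res_h = classify_dataset(m, list(m.data.index[:20]))
        # rebuild the matrix with times in 'minutes' (scaled headers)
        import pandas as pd

        from inflamstate.core_model import OmicsMatrix, parse_sample_key

        def rescale(col):
            s = parse_sample_key(col)
            return f"{s.condition.value}_T{s.time_h * 60:g}h_R{s.replicate}"

        data = m.data.copy()
        data.columns = [rescale(c) for c in data.columns]
        m2 = OmicsMatrix(layer=m.layer, scale=m.scale, data=data)
        res_m = classify_dataset(m2, list(m2.data.index[:20]))
        assert list(res_h["final"]) == list(res_m["final"])
        assert list(res_h["shape"]) == list(res_m["shape"])
        assert list(res_h["effect"]) == list(res_m["effect"])
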