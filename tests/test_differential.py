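import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from inflamstate.core_model import Condition, Layer, OmicsMatrix, Scale, ThresholdConfig
from inflamstate.differential import (
    ModerationFit,
    bh_adjust,
    call_events,
    estimate_effects,
    fit_moderation,
    fit_silac_no_intercept,
    moderated_t,
    run_differential,
)


def _two_arm_matrix(stim, ctrl, time=24):
    cols, vals = [], []
    for cond, arm in (("CTRL", ctrl), ("TNF", stim)):
        for r, v in enumerate(arm, start=1):
            cols.append(f"{cond}_T{time}h_R{r}")
            vals.append(v)
    df = pd.DataFrame([vals], index=["G1"], columns=cols)
    return OmicsMatrix(layer=Layer.PROTEIN, scale=Scale.LOG2_LFQ, data=df)


class TestEstimateEffects:
    def test_exact_arithmetic_no_variance(self):
        m = _two_arm_matrix([3, 3, 3], [1, 1, 1])
        eff = estimate_effects(m, Condition.TNF, 24).loc["G1"]
        assert (eff.log2fc, eff.s2, eff.df) == (2.0, 0.0, 4.0)

    def test_pooled_variance_hand_computation(self):
        # stim (2,4), ctrl (1,3): lfc 1, pooled s2 = ((1)*2 + (1)*2)/2 = 2, df 2
        m = _two_arm_matrix([2, 4], [1, 3])
        eff = estimate_effects(m, Condition.TNF, 24).loc["G1"]
        assert eff.log2fc == 1.0
        assert eff.s2 == pytest.approx(2.0)
        assert eff.df == 2.0

    def test_one_arm_missing_is_untestable(self):
        m = _two_arm_matrix([np.nan, np.nan, 3], [1, 1, 1])
        eff = estimate_effects(m, Condition.TNF, 24).loc["G1"]
        assert not eff.testable and np.isnan(eff.log2fc)


class TestFitModeration:
    def test_identical_variances_give_infinite_prior(self):
        s2 = np.full(50, 0.25)
        df = np.full(50, 4.0)
        fit = fit_moderation(s2, df)
        assert math.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(0.25, rel=1e-6)
        t, _ = moderated_t(np.ones(50), s2, df, fit, np.full(50, 3), np.full(50, 3))
        np.testing.assert_allclose(t, 1.0 / np.sqrt(0.25 * (2 / 3)), rtol=1e-9)

    def test_parameter_recovery_from_scaled_inv_chisq(self):
        rng = np.random.default_rng(12)
        d0_true, s0_true, d = 4.0, 0.09, 4.0
        n = 5000
        # s2 | s_true2 ~ s_true2 * chi2_d / d, with s_true2 ~ s0 * d0 / chi2_{d0}
        strue = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = strue * rng.chisquare(d, size=n) / d
        fit = fit_moderation(s2, np.full(n, d))
        assert abs(fit.d0 - d0_true) / d0_true < 0.25
        assert abs(fit.s0_sq - s0_true) / s0_true < 0.10

    def test_contamination_robustness(self):
        rng = np.random.default_rng(5)
        n = 2000
        s2 = 0.1 * rng.chisquare(4, size=n) / 4
        s2[: n // 10] *= 100.0  # 10% gross contamination
        fit = fit_moderation(s2, np.full(n, 4.0))
        assert np.isfinite(fit.d0)
        bulk = np.median(s2)
        assert bulk / 2 < fit.s0_sq < bulk * 2

    def test_too_few_variances_advises_ordinary_t(self):
        with pytest.raises(ValueError, match="ordinary t"):
            fit_moderation(np.full(5, 0.1), np.full(5, 4.0))


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(0)
        stim, ctrl = rng.normal(1, 1, 3), rng.normal(0, 1, 3)
        lfc = stim.mean() - ctrl.mean()
        s2 = (np.var(stim, ddof=1) + np.var(ctrl, ddof=1)) / 2
        fit = ModerationFit(d0=0.0, s0_sq=1.0)
        t, p = moderated_t(np.array([lfc]), np.array([s2]), np.array([4.0]), fit, np.array([3]), np.array([3]))
        t_ref, p_ref = stats.ttest_ind(stim, ctrl)
        assert t[0] == pytest.approx(t_ref)
        assert p[0] == pytest.approx(p_ref)

    def test_d0_infinite_pins_posterior_variance(self):
        fit = ModerationFit(d0=math.inf, s0_sq=0.5)
        s2 = np.array([0.1, 1.0, 10.0])
        t, _ = moderated_t(np.ones(3), s2, np.full(3, 4.0), fit, np.full(3, 3), np.full(3, 3))
        np.testing.assert_allclose(t, 1.0 / np.sqrt(0.5 * (2 / 3)))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(8)
        n = 1000
        stim = rng.normal(0, 1, (n, 3))
        ctrl = rng.normal(0, 1, (n, 3))
        lfc = stim.mean(1) - ctrl.mean(1)
        s2 = (stim.var(1, ddof=1) + ctrl.var(1, ddof=1)) / 2
        df = np.full(n, 4.0)
        fit = fit_moderation(s2, df)
        _, p = moderated_t(lfc, s2, df, fit, np.full(n, 3), np.full(n, 3))
        assert stats.kstest(p, "uniform").pvalue > 0.01


def _bh_oracle_calls(p, alpha=0.05):
    """Step-up definition: reject the k smallest where k = max{i: p(i) <= i*alpha/m}."""
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    m = len(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBHAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2

    def test_elementwise_geq_input_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_brute_force_oracle_on_short_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(1, 9)
            p = rng.uniform(size=n)
            calls = bh_adjust(p) <= 0.05
            np.testing.assert_array_equal(calls, _bh_oracle_calls(p, 0.05))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariant_and_rank_preserving(self, p_list):
        p = np.array(p_list)
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
        # adjusted values preserve the significance ordering of the raw ones
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCallEvents:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["feature", "condition", "time_h", "log2fc", "p"])

    def test_threshold_rules(self):
        df = self._frame(
            [
                ["A", "TNF", 24.0, 1.5, 0.001],
                ["B", "TNF", 24.0, 0.5, 0.001],
                ["C", "TNF", 24.0, 1.5, 0.9],
            ]
        )
        out = call_events(df, ThresholdConfig(), Layer.PROTEIN)
        assert out.set_index("feature")["significant"].to_dict() == {"A": True, "B": False, "C": False}

    def test_secretome_uses_stricter_alpha(self):
        df = self._frame([["A", "TNF", 24.0, 1.5, 0.04]])
        prot = call_events(df, ThresholdConfig(), Layer.PROTEIN)
        secr = call_events(df, ThresholdConfig(), Layer.SECRETOME)
        assert bool(prot["significant"][0]) is True
        assert bool(secr["significant"][0]) is False

    def test_counts_monotone_in_alpha_and_lfc(self, small_dataset):
        _, matrices, _ = small_dataset
        m = matrices[Layer.TRANSCRIPT]
        counts = []
        for alpha, lfc in [(0.1, 0.5), (0.05, 1.0), (0.01, 1.5)]:
            res = run_differential(m, ThresholdConfig(alpha=alpha, lfc_min=lfc))
            counts.append(int(res["significant"].sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestSilacNoIntercept:
    def test_single_condition_effect_is_mean(self):
        out = fit_silac_no_intercept(pd.DataFrame({"TNF": [1.0, 1.2, 0.8]}))
        assert out.loc[0, "effect"] == pytest.approx(1.0)

    def test_two_conditions_normal_equations(self):
        df = pd.DataFrame({"TNF": [1.0, 2.0, 3.0], "IFN": [0.0, 1.0, 2.0]})
        out = fit_silac_no_intercept(df).set_index("condition")
        assert out.loc["TNF", "effect"] == pytest.approx(2.0)
        assert out.loc["IFN", "effect"] == pytest.approx(1.0)
        assert out.loc["TNF", "df"] == 4  # n - k = 6 - 2

    def test_all_zero_ratios(self):
        out = fit_silac_no_intercept(pd.DataFrame({"TNF": [0.0, 0.0, 0.0]}))
        assert out.loc[0, "effect"] == 0.0
        assert out.loc[0, "t"] == 0.0

    def test_sparse_condition_untestable(self):
        out = fit_silac_no_intercept(pd.DataFrame({"TNF": [1.0, np.nan, np.nan], "IFN": [1.0, 2.0, 1.5]}))
        row = out.set_index("condition").loc["TNF"]
        assert not row.testable
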