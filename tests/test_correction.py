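"""Pseudo-label rate mixing, its inversion, and the direct metric conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from pumetrics import (
    ConfusionMatrix,
    PUContext,
    bacc_from_pu,
    bacc_from_rates,
    correct_rates,
    corrected_metrics,
    estimate_rates,
    mcc_from_pu,
    mcc_from_rates,
    metrics_from_cm,
    prior_from_mixture,
    pu_metrics,
    pu_rates_from_true,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
contexts = st.tuples(
    st.floats(0.0, 0.9, allow_nan=False),   # alpha
    st.floats(0.02, 1.0, allow_nan=False),  # beta
    st.floats(0.01, 0.99, allow_nan=False), # c
).filter(lambda t: t[1] > t[0] + 0.01).map(lambda t: PUContext(*t))


class TestPUContext:
    def test_implied_prior(self):
        ctx = PUContext(alpha=0.25, beta=0.75, c=0.1)
        assert ctx.pi == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "alpha, beta, c, pi",
        [(0.25, 0.75, 0.1, 0.3), (0.0, 1.0, 0.2, 0.2), (0.4, 0.4001, 0.5, 0.40005)],
    )
    def test_prior_from_mixture(self, alpha, beta, c, pi):
        assert prior_from_mixture(alpha, beta, c) == pytest.approx(pi)

    def test_no_enrichment_prior_is_alpha(self):
        assert prior_from_mixture(0.3, 0.3, 0.5) == pytest.approx(0.3)

    def test_inverted_mixture_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            PUContext(alpha=0.6, beta=0.5, c=0.1)


class TestForwardMixing:
    def test_convex_combination_example(self):
        ctx = PUContext(alpha=0.25, beta=0.75, c=0.1)
        gamma_pu, eta_pu = pu_rates_from_true(0.8, 0.1, ctx)
        assert gamma_pu == pytest.approx(0.625)
        assert eta_pu == pytest.approx(0.275)
        # the gap contracts by exactly beta - alpha
        assert gamma_pu - eta_pu == pytest.approx((0.75 - 0.25) * (0.8 - 0.1))

    def test_clean_supervised_limit_is_identity(self):
        ctx = PUContext(alpha=0.0, beta=1.0, c=0.3)
        assert pu_rates_from_true(0.8, 0.1, ctx) == (0.8, 0.1)

    def test_uninformative_classifier_unchanged(self):
        ctx = PUContext(alpha=0.2, beta=0.9, c=0.2)
        assert pu_rates_from_true(0.4, 0.4, ctx) == pytest.approx((0.4, 0.4))


class TestCorrectRates:
    def test_round_trip_example(self):
        cr = correct_rates(0.625, 0.275, c=0.1, alpha_hat=0.25, beta_hat=0.75)
        assert cr.gamma == pytest.approx(0.8)
        assert cr.eta == pytest.approx(0.1)
        assert cr.pi == pytest.approx(0.3)
        assert cr.clipped == ()

    def test_clean_limit_identity(self):
        cr = correct_rates(0.7, 0.2, c=0.3, alpha_hat=0.0, beta_hat=1.0)
        assert (cr.gamma, cr.eta, cr.pi) == (0.7, 0.2, 0.3)

    def test_random_classifier_fixed_point(self):
        cr = correct_rates(0.5, 0.5, c=0.2, alpha_hat=0.1, beta_hat=0.9)
        assert cr.gamma == pytest.approx(0.5)
        assert cr.eta == pytest.approx(0.5)

    def test_non_identifiable_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            correct_rates(0.6, 0.3, c=0.1, alpha_hat=0.5, beta_hat=0.5)

    def test_tiny_gap_rejected_by_floor(self):
        with pytest.raises(ValueError, match="min_gap"):
            correct_rates(0.6, 0.3, c=0.1, alpha_hat=0.5, beta_hat=0.5 + 1e-9)

    def test_noisy_input_clipped_and_flagged(self):
        # gamma_hat > beta would imply gamma > 1: clipped, with a flag
        cr = correct_rates(0.99, 0.0, c=0.1, alpha_hat=0.0, beta_hat=0.9)
        assert cr.gamma == 1.0
        assert "gamma" in cr.clipped

    def test_clipping_can_be_disabled(self):
        cr = correct_rates(0.99, 0.0, c=0.1, alpha_hat=0.0, beta_hat=0.9, clip=False)
        assert cr.gamma == pytest.approx(1.1)


class TestMetricSets:
    def test_pu_all_negative_predictor_majority_baseline(self):
        m = pu_metrics(0.0, 0.0, c=0.1, theta=0.01)
        assert m.acc == pytest.approx(0.9)  # 1 - c: the trivial ceiling

    def test_pu_f_case_study_value(self):
        m = pu_metrics(0.5353, 0.2237, c=0.1, theta=0.2542)
        assert m.f == pytest.approx(0.3022, abs=1e-3)
        assert m.flavor == "pu"

    def test_pu_uninformative(self):
        m = pu_metrics(0.3, 0.3, c=0.1, theta=0.3)
        assert m.bacc == pytest.approx(0.5)
        assert m.mcc == pytest.approx(0.0)

    def test_corrected_hand_evaluated(self):
        m = corrected_metrics(0.8, 0.1, 0.3, 0.31)
        assert m.acc == pytest.approx(0.87)
        assert m.bacc == pytest.approx(0.85)
        assert m.f == pytest.approx(2 * 0.3 * 0.8 / 0.61)
        assert m.mcc == pytest.approx(math.sqrt(0.21 / (0.31 * 0.69)) * 0.7)
        assert m.clipped == ()

    def test_corrected_bacc_clipped_to_half(self):
        m = corrected_metrics(0.2, 0.4, 0.3, 0.35)
        assert m.bacc == 0.5
        assert "bacc" in m.clipped

    def test_corrected_mcc_undefined_for_degenerate_theta(self):
        m = corrected_metrics(0.8, 0.1, 0.3, 0.0)
        assert math.isnan(m.mcc)

    def test_clean_limit_identity_chain(self):
        """With alpha=0, beta=1 the corrected pipeline reproduces the plain
        count metrics on true labels."""
        cm = ConfusionMatrix(40, 10, 20, 30)
        r = estimate_rates(cm)
        cr = correct_rates(r.gamma, r.eta, r.pi, alpha_hat=0.0, beta_hat=1.0)
        corrected = corrected_metrics(cr.gamma, cr.eta, cr.pi, r.theta)
        plain = metrics_from_cm(cm)
        assert corrected.acc == plain.acc
        assert corrected.bacc == plain.bacc
        assert corrected.f == plain.f
        assert corrected.mcc == pytest.approx(plain.mcc, abs=1e-15)


class TestDirectConversions:
    def test_bacc_case_study_value(self):
        # bacc_pu at tau=0 from standard-normal cdfs (independent oracle)
        gamma, eta = norm.sf(-1.0), norm.sf(1.0)
        bacc_pu = (1 + 0.75 * gamma + 0.25 * eta - (0.25 * gamma + 0.75 * eta)) / 2
        assert bacc_from_pu(bacc_pu, 0.25, 0.75) == pytest.approx(norm.cdf(1.0), abs=1e-12)

    def test_bacc_random_fixed_point(self):
        assert bacc_from_pu(0.5, 0.25, 0.75) == pytest.approx(0.5)

    def test_bacc_clean_limit_identity(self):
        assert bacc_from_pu(0.73, 0.0, 1.0) == pytest.approx(0.73)

    def test_bacc_rejects_inverted_mixture(self):
        with pytest.raises(ValueError, match="identifiable"):
            bacc_from_pu(0.6, 0.8, 0.7)

    def test_mcc_case_study_value(self):
        ctx = PUContext(alpha=0.25, beta=0.75, c=0.1)
        assert mcc_from_pu(0.2175, ctx) == pytest.approx(2 * math.sqrt(0.21 / 0.09) * 0.2175)
        assert mcc_from_pu(0.2175, ctx) == pytest.approx(0.6645, abs=1e-3)

    def test_mcc_zero_fixed_point(self):
        assert mcc_from_pu(0.0, PUContext(0.2, 0.9, 0.3)) == 0.0

    def test_mcc_scaling_is_unity_in_supervised_limit(self):
        # alpha=0, beta=1 and c = pi make the scale factor exactly 1
        ctx = PUContext(alpha=0.0, beta=1.0, c=0.3)
        assert ctx.pi == pytest.approx(0.3)
        assert mcc_from_pu(0.42, ctx) == pytest.approx(0.42)


class TestProperties:
    @settings(max_examples=500, deadline=None)
    @given(unit, unit, contexts)
    def test_round_trip_recovers_true_rates(self, gamma, eta, ctx):
        gamma_pu, eta_pu = pu_rates_from_true(gamma, eta, ctx)
        cr = correct_rates(gamma_pu, eta_pu, ctx.c, ctx.alpha, ctx.beta)
        assert cr.gamma == pytest.approx(gamma, abs=1e-10)
        assert cr.eta == pytest.approx(eta, abs=1e-10)
        assert cr.pi == pytest.approx(ctx.pi, abs=1e-12)

    @settings(max_examples=500, deadline=None)
    @given(unit, unit, contexts)
    def test_direct_conversions_agree_with_rate_correction(self, gamma, eta, ctx):
        """Two independent code paths: correct the rates then apply the
        metric formula, vs convert the pseudo metric directly."""
        gamma_pu, eta_pu = pu_rates_from_true(gamma, eta, ctx)
        theta = ctx.pi * gamma + (1 - ctx.pi) * eta
        cr = correct_rates(gamma_pu, eta_pu, ctx.c, ctx.alpha, ctx.beta, clip=False)

        bacc_pu = bacc_from_rates(gamma_pu, eta_pu)
        assert bacc_from_pu(bacc_pu, ctx.alpha, ctx.beta) == pytest.approx(
            bacc_from_rates(np.clip(cr.gamma, 0, 1), np.clip(cr.eta, 0, 1)), abs=1e-10
        )
        if 1e-9 < theta < 1 - 1e-9:
            mcc_pu = mcc_from_rates(gamma_pu, eta_pu, ctx.c, theta)
            expected = mcc_from_rates(
                np.clip(cr.gamma, 0, 1), np.clip(cr.eta, 0, 1), ctx.pi, theta
            )
            assert mcc_from_pu(mcc_pu, ctx) == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=500, deadline=None)
    @given(unit, unit, contexts)
    def test_underestimation_inequalities(self, gamma, eta, ctx):
        """Traditional bacc dominates pseudo bacc above random; traditional
        mcc dominates pseudo mcc in magnitude with the same sign."""
        gamma_pu, eta_pu = pu_rates_from_true(gamma, eta, ctx)
        theta = ctx.pi * gamma + (1 - ctx.pi) * eta
        bacc_pu = bacc_from_rates(gamma_pu, eta_pu)
        if bacc_pu >= 0.5:
            assert bacc_from_pu(bacc_pu, ctx.alpha, ctx.beta) >= bacc_pu - 1e-12
        if 1e-9 < theta < 1 - 1e-9:
            mcc_pu = mcc_from_rates(gamma_pu, eta_pu, ctx.c, theta)
            mcc = mcc_from_pu(mcc_pu, ctx)
            assert np.sign(mcc) * (mcc - mcc_pu) >= -1e-12

    @settings(max_examples=100, deadline=None)
    @given(contexts, st.integers(0, 2**31 - 1))
    def test_monotone_conversion_preserves_argmax(self, ctx, seed):
        """Strictly increasing conversions leave the argmax of any curve
        unchanged, so thresholds tuned on pseudo-label data remain optimal."""
        rng = np.random.default_rng(seed)
        curve = rng.random(50)
        converted = bacc_from_pu(curve, ctx.alpha, ctx.beta)
        assert int(np.argmax(curve)) == int(np.argmax(converted))
        converted_mcc = mcc_from_pu(2 * curve - 1, ctx)
        assert int(np.argmax(curve)) == int(np.argmax(converted_mcc))
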