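"""Loss identities, bounds and the Weibull likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moma.losses import (InstanceLossConfig, WeibullParams, bag_loss,
                         inverted_class_weights, select_extreme_clusters,
                         smooth_hinge, smooth_svm_instance_loss, total_loss,
                         weibull_negative_log_likelihood, weibull_nll_tensor)
from moma.nn import Tensor


class TestInvertedClassWeights:
    @pytest.mark.parametrize("counts,expected", [
        ([50, 50], [1.0, 1.0]),
        ([10, 30], [2.0, 2.0 / 3.0]),
        ([1, 1, 1], [1.0, 1.0, 1.0]),
    ])
    def test_closed_form(self, counts, expected):
        assert np.allclose(inverted_class_weights(counts), expected)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            inverted_class_weights([5, 0])

    def test_weighted_counts_balance(self):
        counts = np.array([7, 19, 4])
        w = inverted_class_weights(counts)
        assert np.allclose(w * counts, counts.sum() / 3.0)


class TestBagLoss:
    def test_perfect_prediction_zero_loss(self):
        assert bag_loss([0.0, 1.0], 1, [1.0, 1.0]) == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_is_ln2(self):
        assert bag_loss([0.5, 0.5], 0, [1.0, 1.0]) == pytest.approx(np.log(2))

    def test_linear_in_weight(self):
        l1 = bag_loss([0.3, 0.7], 1, [1.0, 1.0])
        l2 = bag_loss([0.3, 0.7], 1, [1.0, 2.0])
        assert l2 == pytest.approx(2 * l1)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = bag_loss([1.0, 0.0], 1, [1.0, 1.0])
        assert np.isfinite(loss)

    def test_tensor_path_matches_numpy(self):
        p = Tensor(np.array([0.2, 0.8]), requires_grad=True)
        lt = bag_loss(p, 0, [1.5, 1.0])
        assert float(lt.data) == pytest.approx(bag_loss([0.2, 0.8], 0, [1.5, 1.0]),
                                               abs=1e-9)
        lt.backward()
        assert p.grad is not None


class TestSelectExtremeClusters:
    def test_ranked_by_attention(self):
        attn = [.30, .25, .20, .10, .05, .04, .03, .02, .009, .001]
        top, bottom = select_extreme_clusters(attn)
        assert top == [0, 1, 2]
        assert bottom == [9, 8, 7] or set(bottom) == {7, 8, 9}

    def test_symmetric_reduction_for_four_clusters(self):
        top, bottom = select_extreme_clusters([.4, .3, .2, .1])
        assert len(top) == 2 and len(bottom) == 2
        assert top == [0, 1] and set(bottom) == {2, 3}

    def test_all_equal_attention_index_tie_break(self):
        top, bottom = select_extreme_clusters([0.1] * 10)
        assert top == [0, 1, 2]
        assert set(bottom) == {7, 8, 9}

    def test_selection_disjoint(self):
        top, bottom = select_extreme_clusters([0.2] * 7)
        assert not set(top) & set(bottom)


class TestSmoothHinge:
    def test_unit_margin_value(self):
        assert smooth_hinge(1.0, tau=1.0) == pytest.approx(np.log(2))

    def test_saturated_correct_side(self):
        assert smooth_hinge(10.0, tau=1.0) < 1e-3

    def test_small_tau_approaches_hinge_at_zero(self):
        assert abs(smooth_hinge(0.0, tau=0.01) - 1.0) < 1e-3

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-5, 5), st.floats(0.01, 2.0))
    def test_upper_bounds_hinge(self, z, tau):
        hinge = max(0.0, 1.0 - z)
        val = smooth_hinge(z, tau)
        assert val >= hinge - 1e-12
        if z == 1.0:
            assert val - hinge <= tau * np.log(2) + 1e-12

    def test_gap_at_margin_one_is_tau_ln2(self):
        for tau in (0.1, 0.5, 1.0):
            assert smooth_hinge(1.0, tau) == pytest.approx(tau * np.log(2))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            smooth_hinge(0.0, tau=0.0)


class TestInstanceLoss:
    def test_mean_over_tiles(self):
        scores = np.array([[0.0, 2.0], [0.0, 2.0]])  # margin +2 for label +1
        cfg = InstanceLossConfig(tau=1.0)
        val = smooth_svm_instance_loss(scores, [1, 1], cfg, target_class=1)
        assert val == pytest.approx(smooth_hinge(2.0, 1.0))

    def test_negative_pseudo_label_flips_margin(self):
        scores = np.array([[0.0, 2.0]])
        cfg = InstanceLossConfig(tau=1.0)
        pos = smooth_svm_instance_loss(scores, [1], cfg, target_class=1)
        neg = smooth_svm_instance_loss(scores, [-1], cfg, target_class=1)
        assert neg == pytest.approx(smooth_hinge(-2.0, 1.0))
        assert neg > pos

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            smooth_svm_instance_loss(np.zeros((1, 2)), [0.5],
                                     InstanceLossConfig())


class TestTotalLoss:
    def test_plain_sum(self):
        assert total_loss(0.5, 0.25) == 0.75
        assert total_loss(0.0, 0.0) == 0.0
        assert total_loss(0.25, 0.5) == total_loss(0.5, 0.25)


class TestWeibullNLL:
    def test_unit_exponential_event(self):
        assert weibull_negative_log_likelihood(
            WeibullParams(1.0, 1.0), 1.0, 1) == pytest.approx(1.0)

    def test_censored_is_cumulative_hazard(self):
        assert weibull_negative_log_likelihood(
            WeibullParams(1.0, 1.0), 2.0, 0) == pytest.approx(2.0)

    def test_shape_two_worked_value(self):
        # -[log(2/2) + (2-1) log(1/2) - (1/2)^2] = log 2 + 1/4
        assert weibull_negative_log_likelihood(
            WeibullParams(2.0, 2.0), 1.0, 1) == pytest.approx(0.9431, abs=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            weibull_negative_log_likelihood(WeibullParams(1.0, 1.0), 0.0, 1)
        with pytest.raises(ValueError):
            WeibullParams(-1.0, 1.0)

    def test_tensor_form_matches_scalar(self):
        lam = Tensor(np.array([1.0, 2.0]))
        kappa = Tensor(np.array([1.0, 2.0]))
        mean_nll = weibull_nll_tensor(lam, kappa, [1.0, 1.0], [1, 1])
        expected = 0.5 * (
            weibull_negative_log_likelihood(WeibullParams(1.0, 1.0), 1.0, 1)
            + weibull_negative_log_likelihood(WeibullParams(2.0, 2.0), 1.0, 1))
        assert float(mean_nll.data) == pytest.approx(expected, abs=1e-6)

    def test_mle_matches_reference_fitter(self):
        """Gradient minimization of the summed NLL lands on the same
        (lambda, kappa) as lifelines' Weibull maximum-likelihood fit."""
        from lifelines import WeibullFitter

        from moma.survival import LinearWeibullModel

        rng = np.random.default_rng(4)
        t = 1.7 * rng.weibull(1.4, size=800)
        e = np.ones_like(t)
        ours = LinearWeibullModel(1, seed=0).fit(np.zeros((t.size, 1)), t, e)
        ref = WeibullFitter().fit(t, e)
        assert ours.lambda0 == pytest.approx(ref.lambda_, rel=0.02)
        assert ours.kappa == pytest.approx(ref.rho_, rel=0.02)
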