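import numpy as np
import pytest

from scadapt.attribution import (BaselineSpec, baseline_audit,
                                 dependence_summary, dual_head_attribution,
                                 integrated_gradients, logit_grad_fn,
                                 resistance_probability, top_k_features)


def linear_grad_fn(w):
    w = np.asarray(w, float)

    def fn(x):
        return x @ w, np.tile(w, (x.shape[0], 1))
    return fn


class TestIntegratedGradients:
    def test_exact_on_linear_model(self):
        # F(x) = 2 x1 - x2 at x=(3,4), mean baseline (1,1): attributions
        # (x - x') * w = (4, -3), exact for any step count
        X = np.array([[3.0, 4.0], [-1.0, -2.0]])  # cohort mean (1, 1)
        for n_steps in (8, 16, 64):
            res = integrated_gradients(linear_grad_fn([2.0, -1.0]), X,
                                       BaselineSpec("mean"), n_steps=n_steps)
            np.testing.assert_allclose(res.values[0], [4.0, -3.0],
                                       atol=1e-12)

    def test_input_equal_to_baseline_gives_zero(self):
        X = np.ones((3, 4)) * 2.0
        res = integrated_gradients(linear_grad_fn(np.ones(4)), X,
                                   BaselineSpec("mean"), n_steps=16)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)

    def test_completeness_on_smooth_two_layer_net(self):
        rng = np.random.default_rng(0)
        W1, b1 = rng.standard_normal((5, 8)), rng.standard_normal(8)
        w2 = rng.standard_normal(8)

        def f(x):
            return np.tanh(x @ W1 + b1) @ w2

        def grad_fn(x):
            h = np.tanh(x @ W1 + b1)
            return h @ w2, ((1 - h**2) * w2) @ W1.T

        X = rng.standard_normal((6, 5))
        res = integrated_gradients(grad_fn, X, BaselineSpec("mean"),
                                   n_steps=256)
        baseline = X.mean(axis=0, keepdims=True)
        gap = res.values.sum(axis=1) - (f(X) - f(baseline))
        assert np.max(np.abs(gap)) < 1e-3

    def test_completeness_error_shrinks_with_steps(self):
        rng = np.random.default_rng(1)
        W1, b1 = rng.standard_normal((4, 6)), rng.standard_normal(6)
        w2 = rng.standard_normal(6)

        def f(x):
            return np.tanh(x @ W1 + b1) @ w2

        def grad_fn(x):
            h = np.tanh(x @ W1 + b1)
            return h @ w2, ((1 - h**2) * w2) @ W1.T

        X = rng.standard_normal((5, 4)) * 2
        baseline = X.mean(axis=0, keepdims=True)
        errs = []
        for n in (8, 32, 128):
            res = integrated_gradients(grad_fn, X, BaselineSpec("mean"),
                                       n_steps=n)
            errs.append(np.max(np.abs(res.values.sum(axis=1)
                                      - (f(X) - f(baseline)))))
        assert errs[2] < errs[0]

    def test_random_baselines_are_seeded(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        spec = BaselineSpec("random_k", k=5, seed=9)
        a = integrated_gradients(linear_grad_fn([1.0, 2.0, 3.0]), X, spec, 8)
        b = integrated_gradients(linear_grad_fn([1.0, 2.0, 3.0]), X, spec, 8)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n_baseline_samples == 5


class TestDualHead:
    def test_opposite_linear_heads_give_negated_attributions(
            self, small_classifier, small_two_domain):
        # make the two logits exact negatives of each other
        final = small_classifier.head_.layers[-1]
        final.W.value[1] = -final.W.value[0]
        final.b.value[1] = -final.b.value[0]
        X = small_two_domain.source.values[:8]
        sens, resi = dual_head_attribution(small_classifier, X,
                                           BaselineSpec("mean"), n_steps=16)
        np.testing.assert_allclose(sens.values, -resi.values, atol=1e-8)

    def test_rankings_reproducible(self, small_classifier, small_two_domain):
        X = small_two_domain.source.values[:10]
        r1 = dual_head_attribution(small_classifier, X, n_steps=8)[1]
        r2 = dual_head_attribution(small_classifier, X, n_steps=8)[1]
        np.testing.assert_array_equal(r1.overall_importance,
                                      r2.overall_importance)


class TestBaselineAudit:
    def test_identical_baselines_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        X = np.abs(rng.standard_normal((30, 6))) + 0.1
        grad = linear_grad_fn(rng.standard_normal(6))
        mat, _ = baseline_audit(grad, X, [BaselineSpec("mean"),
                                          BaselineSpec("mean")], n_steps=8)
        assert mat.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_baseline_unidirectional_mean_baseline_mixed(self):
        """With a monotone-increasing model on nonnegative inputs, the zero
        baseline attributes every sample in the same direction per feature,
        while the mean baseline splits by position relative to the mean."""
        rng = np.random.default_rng(4)
        X = np.abs(rng.standard_normal((40, 5))) + 0.05
        w = np.abs(rng.standard_normal(5)) + 0.1  # monotone model
        grad = linear_grad_fn(w)
        zero_res = integrated_gradients(grad, X, BaselineSpec("zero"), 8)
        mean_res = integrated_gradients(grad, X, BaselineSpec("mean"), 8)
        assert np.all(zero_res.values > 0)
        signs_mixed = np.all((mean_res.values.min(axis=0) < 0)
                             & (mean_res.values.max(axis=0) > 0))
        assert signs_mixed

    def test_mean_vs_random_mean_ranks_agree(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 10)) + 2
        w = rng.standard_normal(10)
        mat, _ = baseline_audit(linear_grad_fn(w), X,
                                [BaselineSpec("mean"),
                                 BaselineSpec("random_mean", k=10, seed=6),
                                 BaselineSpec("zero")], n_steps=8)
        assert mat.loc["mean", "random_mean"] >= 0.9

    def test_needs_two_baselines(self):
        with pytest.raises(ValueError):
            baseline_audit(linear_grad_fn([1.0]), np.ones((3, 1)),
                           [BaselineSpec("mean")])


class TestDependence:
    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(6)
        n = 300
        X = rng.standard_normal((n, 4))
        X[:, 1] = np.abs(X[:, 1]) + 0.5  # keep the interactor positive

        def grad_fn(x):
            # F = x0 * x1: dF/dx0 = x1, dF/dx1 = x0
            g = np.zeros_like(x)
            g[:, 0] = x[:, 1]
            g[:, 1] = x[:, 0]
            return x[:, 0] * x[:, 1], g

        attr = integrated_gradients(grad_fn, X, BaselineSpec("mean"), 32)
        df = dependence_summary(attr, X, target_feature=0)
        assert df.attrs["interaction_feature"] == "1"
        assert len(df) == n

    def test_pure_linear_flags_no_interaction(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 3))
        attr = integrated_gradients(linear_grad_fn([1.5, 0.0, 0.0]), X,
                                    BaselineSpec("mean"), 16)
        df = dependence_summary(attr, X, target_feature=0)
        assert df.attrs["interaction_feature"] == "none"

    def test_constant_target_rejected(self):
        X = np.ones((10, 2))
        attr = integrated_gradients(linear_grad_fn([1.0, 1.0]), X,
                                    BaselineSpec("zero"), 8)
        with pytest.raises(ValueError):
            dependence_summary(attr, X, target_feature=0)


class TestScores:
    def test_resistance_probability_minmax(self):
        from scadapt.attribution import AttributionResult
        attr = AttributionResult(np.array([[-2.0], [0.0], [2.0]]),
                                 BaselineSpec("mean"), 8, 1)
        np.testing.assert_allclose(resistance_probability(attr),
                                   [0.0, 0.5, 1.0])
        flat = AttributionResult(np.ones((3, 2)), BaselineSpec("mean"), 8, 1)
        np.testing.assert_allclose(resistance_probability(flat), 0.5)
        shifted = AttributionResult(np.array([[-2.0], [0.0], [2.0]]) + 7.0,
                                    BaselineSpec("mean"), 8, 1)
        np.testing.assert_allclose(resistance_probability(shifted),
                                   [0.0, 0.5, 1.0])

    def test_top_k_ranking_with_stable_ties(self):
        from scadapt.attribution import AttributionResult
        attr = AttributionResult(np.array([[3.0, 1.0, 2.0, 2.0]]),
                                 BaselineSpec("mean"), 8, 1)
        assert top_k_features(attr, k=2) == [0, 2]
        assert top_k_features(attr, k=4) == [0, 2, 3, 1]
        with pytest.raises(ValueError):
            top_k_features(attr, k=10)


def test_classifier_grad_fn_matches_finite_differences(small_classifier,
                                                       small_two_domain):
    X = small_two_domain.source.values[:3].copy()
    fn = logit_grad_fn(small_classifier, head=1)
    vals, grads = fn(X)
    eps = 1e-5
    Xp = X.copy()
    Xp[1, 2] += eps
    vals_p, _ = fn(Xp)
    fd = (vals_p[1] - vals[1]) / eps
    assert grads[1, 2] == pytest.approx(fd, abs=1e-4)
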