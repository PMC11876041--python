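"""Survival heads: Cox PH, random survival forest, discrete-time network."""

import numpy as np
import pandas as pd
import pytest

from dynasurv._nn import Adam, Linear, Tensor, log_softmax, relu, tanh
from dynasurv.survival import (
    CoxPH,
    DiscreteTimeNN,
    FitError,
    SoftmaxHead,
    SurvivalCurves,
    SurvivalForest,
    failure_from_probs,
)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """End-to-end gradient check of the network building blocks."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 3))
        W1 = rng.normal(size=(3, 5)) * 0.5
        b1 = rng.normal(size=5) * 0.1
        W2 = rng.normal(size=(5, 2)) * 0.5

        def loss_value(w1):
            h = np.tanh(x @ w1 + b1)
            h = np.maximum(h @ W2, 0)
            p = h - h.max(axis=1, keepdims=True)
            ls = p - np.log(np.exp(p).sum(axis=1, keepdims=True))
            return -(ls[:, 0]).sum()

        W1_t = Tensor(W1.copy())
        W1_t.requires_grad = True
        h = relu(tanh(Tensor(x) @ W1_t + Tensor(b1)) @ Tensor(W2))
        ls = log_softmax(h)
        loss = -(ls.take(np.arange(4), np.zeros(4, int)).sum())
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (2, 4)]:
            wp = W1.copy(); wp[idx] += eps
            wm = W1.copy(); wm[idx] -= eps
            num = (loss_value(wp) - loss_value(wm)) / (2 * eps)
            assert W1_t.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def _two_group_exponential(n=2000, beta=1.0, seed=0, censor=None):
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(beta * z))
    d = np.ones(n, int)
    if censor is not None:
        c = rng.exponential(censor, n)
        d = (t <= c).astype(int)
        t = np.minimum(t, c)
    Z = pd.DataFrame({"z": z}, index=pd.RangeIndex(n))
    return Z, t, d


class TestCox:
    def test_two_group_log_hazard_ratio_recovery(self):
        Z, t, d = _two_group_exponential(n=2000, beta=1.0, seed=1)
        model = CoxPH().fit(Z, t, d)
        assert model.coef_["z"] == pytest.approx(1.0, abs=0.1)

    def test_breslow_baseline_equals_exp_neg_nelson_aalen(self):
        """With no covariates the Breslow baseline is exp(-Nelson-Aalen)."""
        from lifelines import NelsonAalenFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 300)
        d = (rng.uniform(size=300) < 0.8).astype(int)
        model = CoxPH().fit(pd.DataFrame(index=pd.RangeIndex(300)), t, d)
        naf = NelsonAalenFitter().fit(t, d)
        grid = np.quantile(t[d == 1], [0.1, 0.3, 0.5, 0.7, 0.9])
        expected = np.exp(-naf.cumulative_hazard_at_times(grid).to_numpy())
        np.testing.assert_allclose(model.baseline_survival(grid), expected, atol=1e-10)

    def test_zero_linear_predictor_returns_baseline(self):
        Z, t, d = _two_group_exponential(n=400, seed=3)
        model = CoxPH().fit(Z, t, d)
        grid = np.linspace(0, 2, 9)
        Z0 = pd.DataFrame({"z": [0.0]})
        curves = model.predict_curves(Z0, grid)
        np.testing.assert_allclose(curves.values[0], model.baseline_survival(grid))

    def test_power_law_and_ordering(self):
        Z, t, d = _two_group_exponential(n=400, seed=4)
        model = CoxPH().fit(Z, t, d)
        grid = np.linspace(0.1, 2, 8)
        beta = model.coef_["z"]
        z_val = np.log(2) / beta  # gives Z.beta = log 2
        c = model.predict_curves(pd.DataFrame({"z": [0.0, z_val]}), grid)
        np.testing.assert_allclose(c.values[1], c.values[0] ** 2, atol=1e-12)
        assert (c.values[1] <= c.values[0] + 1e-12).all()

    def test_no_events_rejected(self):
        Z = pd.DataFrame({"z": [0.0, 1.0]})
        with pytest.raises(FitError):
            CoxPH().fit(Z, [1.0, 2.0], [0, 0])

    def test_constant_column_dropped_with_warning(self):
        Z, t, d = _two_group_exponential(n=200, seed=5)
        Z["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = CoxPH().fit(Z, t, d)
        assert "const" not in model.coef_.index

    def test_feature_mismatch_rejected(self):
        Z, t, d = _two_group_exponential(n=200, seed=6)
        model = CoxPH().fit(Z, t, d)
        with pytest.raises(ValueError):
            model.predict_curves(pd.DataFrame({"other": [1.0]}), [1.0])


class TestForest:
    def test_no_split_regime_predicts_training_km(self):
        """Below min_samples_split every tree is one Kaplan-Meier leaf."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        n = 25  # below the default split threshold of 32
        Z = pd.DataFrame({"z": rng.normal(size=n)})
        t = rng.exponential(1.0, n)
        d = (rng.uniform(size=n) < 0.8).astype(int)
        model = SurvivalForest(n_trees=200, seed=0).fit(Z, t, d)
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        pred = model.predict_curves(Z.iloc[:3], grid).values
        km = KaplanMeierFitter().fit(t, d).survival_function_at_times(grid).to_numpy()
        # bootstrap averaging keeps predictions near the training KM
        assert np.abs(pred - km[None, :]).max() < 0.12

    def test_separable_clusters_are_distinguished(self):
        rng = np.random.default_rng(8)
        n = 500
        cluster = rng.integers(0, 2, n)
        Z = pd.DataFrame({"z1": cluster + 0.05 * rng.normal(size=n)})
        t = np.where(cluster == 0, rng.uniform(0.1, 1.0, n), rng.uniform(3.0, 5.0, n))
        d = np.ones(n, int)
        model = SurvivalForest(n_trees=100, seed=1).fit(Z, t, d)
        curves = model.predict_curves(
            pd.DataFrame({"z1": [0.0, 1.0]}), np.array([2.0])
        )
        s_early, s_late = curves.values[:, 0]
        assert s_early < 0.2 and s_late > 0.8

    def test_ensemble_is_mean_of_tree_curves(self):
        rng = np.random.default_rng(9)
        n = 80
        Z = pd.DataFrame({"z": rng.normal(size=n)})
        t = rng.exponential(1.0, n)
        d = np.ones(n, int)
        model = SurvivalForest(n_trees=3, min_samples_split=8, min_samples_leaf=4,
                               seed=2).fit(Z, t, d)
        Xq = Z.iloc[:4].to_numpy()
        per_tree = [est.predict_survival_function(Xq, return_array=True)
                    for est in model._model.estimators_]
        ens = model._model.predict_survival_function(Xq, return_array=True)
        np.testing.assert_allclose(ens, np.mean(per_tree, axis=0), atol=1e-12)

    def test_identical_rows_identical_curves(self):
        rng = np.random.default_rng(10)
        Z = pd.DataFrame({"z": rng.normal(size=100)})
        t = rng.exponential(1.0, 100)
        model = SurvivalForest(n_trees=20, seed=3).fit(Z, t, np.ones(100, int))
        dup = pd.DataFrame({"z": [0.5, 0.5]})
        c = model.predict_curves(dup, np.linspace(0.1, 2, 5))
        np.testing.assert_array_equal(c.values[0], c.values[1])


class TestFailureFromProbs:
    def test_unconditional_normalization(self):
        F, S = failure_from_probs([0.5, 0.3, 0.2], 0)
        np.testing.assert_allclose(F, [0.0, 0.5, 0.8, 1.0])
        assert S[-1] == pytest.approx(0.0)

    def test_conditional_closed_form(self):
        F, S = failure_from_probs([0.5, 0.3, 0.2], 1)
        assert F[2] == pytest.approx(0.3 / 0.5)
        assert F[1] == 0.0  # nothing accrues before the landmark interval

    def test_monotone_for_random_valid_probs(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.dirichlet(np.ones(rng.integers(2, 8)))
            k = int(rng.integers(0, len(p)))
            if p[k:].sum() <= 0:
                continue
            F, S = failure_from_probs(p, k)
            assert (np.diff(F) >= -1e-12).all()
            assert (F >= -1e-12).all() and (F <= 1 + 1e-12).all()

    def test_zero_conditioning_mass_raises(self):
        with pytest.raises(ZeroDivisionError):
            failure_from_probs([1.0, 0.0, 0.0], 1)


class TestDiscreteTimeNN:
    def test_loss_matches_hand_computed_likelihood(self):
        """Frozen weights: the batch loss equals the discrete NLL computed by
        an independent numpy forward pass and formula evaluation."""
        rng = np.random.default_rng(12)
        head = SoftmaxHead(2, 4, rng, n_hidden=3, dropout=0.0)
        X = rng.normal(size=(3, 2))
        ev_idx = np.array([1, 2, 0])
        event = np.array([1, 0, 1])
        rk_idx = np.array([0, 1, 0])
        loss = head.nll(Tensor(X), ev_idx, event, rk_idx,
                        np.random.default_rng(0), train=False)
        # independent forward pass
        h = np.maximum(X @ head.fc1.W.value + head.fc1.b.value, 0)
        logits = h @ head.fc2.W.value + head.fc2.b.value
        p = np.exp(logits - logits.max(1, keepdims=True))
        p = p / p.sum(1, keepdims=True)
        eps = 1e-12
        expected = -(
            np.log(p[0, 1])
            + np.log((p[1, 3:].sum() + eps) / (p[1, 1:].sum() + eps))
            + np.log(p[2, 0])
        ) / 3
        assert float(loss.value) == pytest.approx(expected, rel=1e-10)

    def test_separable_toy_saturates(self):
        """Two feature values with disjoint event intervals: probabilities
        approach indicator vectors and the NLL approaches zero."""
        Z = pd.DataFrame({"z": [0.0] * 20 + [1.0] * 20})
        t = np.array([0.2] * 20 + [1.2] * 20)
        d = np.ones(40, int)
        model = DiscreteTimeNN(interval_width=0.5, epochs=300, dropout=0.0,
                               weight_decay=0.0, seed=0).fit(Z, t, d)
        probs = model.predict_interval_probs(pd.DataFrame({"z": [0.0, 1.0]}))
        assert probs[0, 0] > 0.95  # interval [0, 0.5)
        assert probs[1, 2] > 0.95  # interval [1.0, 1.5)

    def test_all_censored_mass_flows_beyond_observed_range(self):
        Z = pd.DataFrame({"z": np.zeros(30)})
        t = np.full(30, 2.0)
        d = np.zeros(30, int)
        model = DiscreteTimeNN(interval_width=1.0, epochs=200, dropout=0.0,
                               weight_decay=0.0, seed=0).fit(Z, t, d)
        curves = model.predict_curves(Z.iloc[:1], np.array([0.0, 1.0, 2.0]))
        assert (curves.values >= 0.9).all()

    def test_predict_composes_softmax_and_failure(self):
        rng = np.random.default_rng(13)
        Z = pd.DataFrame({"z": rng.normal(size=40)})
        t = rng.uniform(0.2, 3.0, 40)
        d = (rng.uniform(size=40) < 0.7).astype(int)
        model = DiscreteTimeNN(interval_width=1.0, epochs=5, seed=1).fit(Z, t, d)
        l = 1.0
        probs = model.predict_interval_probs(Z.iloc[:3])
        k = int(model.interval_of(l)[0])
        grid = model.boundaries_
        curves = model.predict_curves(Z.iloc[:3], grid, landmark=l)
        for i in range(3):
            _, S = failure_from_probs(probs[i], k)
            # S's final entry is the value at the (unbounded) end of the
            # overflow interval and has no boundary coordinate
            np.testing.assert_allclose(curves.values[i], S[: len(grid)], atol=1e-12)

    def test_survival_is_one_at_first_boundary_and_stepwise(self):
        rng = np.random.default_rng(14)
        Z = pd.DataFrame({"z": rng.normal(size=30)})
        t = rng.uniform(0.2, 2.0, 30)
        model = DiscreteTimeNN(interval_width=1.0, epochs=3, seed=2).fit(
            Z, t, np.ones(30, int)
        )
        c = model.predict_curves(Z.iloc[:2], np.array([0.0, 0.5, 1.0]), landmark=0.0)
        assert (c.values[:, 0] == 1.0).all()
        # constant within the first interval [0, 1)
        np.testing.assert_array_equal(c.values[:, 0], c.values[:, 1])

    def test_event_before_landmark_interval_skipped_with_warning(self):
        Z = pd.DataFrame({"z": [0.0, 1.0, 2.0]})
        t = np.array([0.2, 1.5, 2.5])
        d = np.array([1, 1, 1])
        with pytest.warns(UserWarning, match="skipping"):
            DiscreteTimeNN(interval_width=1.0, epochs=1, seed=0).fit(
                Z, t, d, landmarks=np.array([1.0, 1.0, 1.0])
            )


class TestSurvivalCurvesContract:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurves(np.array([0]), np.array([0.0, 1.0]),
                           np.array([[0.5, 0.8]]))

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurves(np.array([0]), np.array([0.0]), np.array([[1.2]]))

    def test_step_lookup_before_grid_is_one(self):
        c = SurvivalCurves(np.array([0]), np.array([1.0, 2.0]),
                           np.array([[0.9, 0.5]]))
        assert c.at(0.5)[0] == 1.0
        assert c.at(1.5)[0] == 0.9
        assert c.at(2.0)[0] == 0.5
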