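import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacate import metalearners as ml
from metacate.metalearners import (
    TIE, build_interactions, decide_optimal, estimate_propensity, fit_s_learner,
    fit_sx_learner, fit_t_learner, fit_x_learner, linear_spec,
)

from conftest import linear_dgp


def _split(X, y, t, frac=0.5):
    k = int(len(y) * frac)
    return (X[:k], y[:k], t[:k]), (X[k:], y[k:], t[k:])


class TestInteractions:
    def test_column_count_and_blocks(self):
        X = np.arange(12.0).reshape(4, 3)
        t = np.array([0, 1, 0, 1])
        A = build_interactions(X, t)
        assert A.shape == (4, 7)
        np.testing.assert_array_equal(A[t == 0, 4:], 0.0)
        np.testing.assert_array_equal(A[t == 1, 4:], X[t == 1])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            build_interactions(np.ones((2, 2)), np.array([0, 2]))


class TestDecisionRule:
    def test_sign_rule(self):
        np.testing.assert_array_equal(
            decide_optimal([0.3, -0.3, 0.0]), [0, 1, TIE])
        assert (decide_optimal([1e-9, 5.0]) == 0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            decide_optimal([np.nan])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30),
           st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_positive_rescaling(self, tau, k):
        tau = np.asarray(tau)
        np.testing.assert_array_equal(decide_optimal(tau), decide_optimal(k * tau))

    def test_decision_is_argmin_of_predicted_outcomes(self):
        # brute force: for T and S learners, the decision must pick the
        # treatment whose predicted outcome is smaller
        X, y, t, _ = linear_dgp(n=160, seed=5)
        for fit in (fit_t_learner, fit_s_learner):
            model = fit(X, y, t, linear_spec())
            mu0, mu1 = model.predict_outcomes(X)
            dec = model.decide(X)
            expect = np.where(mu1 > mu0, 0, np.where(mu1 < mu0, 1, TIE))
            np.testing.assert_array_equal(dec, expect)


class TestPropensity:
    def test_coin_flip_assignment_estimates_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3000, 3))
        t = rng.integers(0, 2, 3000)
        g = estimate_propensity(X, t, linear_spec()).predict_control_probability(X)
        se = 0.5 / np.sqrt(len(t))
        assert abs(g.mean() - 0.5) < 3 * se + 0.01

    def test_single_arm_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="single"):
            estimate_propensity(X, np.zeros(10, dtype=int))

    def test_clipping_contract(self):
        class Extreme:
            classes_ = [0, 1]
            def predict_proba(self, M):
                return np.column_stack([np.full(len(M), 0.0005),
                                        np.full(len(M), 0.9995)])
        g = ml.PropensityModel(Extreme()).predict_control_probability(np.ones((5, 2)))
        np.testing.assert_allclose(g, 0.01)


class TestExactRecovery:
    """With linear bases, full-rank designs and sigma=0, tau-hat is exact."""

    def test_t_s_x_learners_recover_heterogeneous_tau(self):
        X, y, t, tau = linear_dgp(n=300, heterogeneous=True, seed=1)
        spec = linear_spec()
        for model in (fit_t_learner(X, y, t, spec),
                      fit_s_learner(X, y, t, spec),
                      fit_x_learner(X, y, t, spec)):
            np.testing.assert_allclose(model.predict_cate(X), tau, atol=1e-8)

    def test_sx_learners_recover_tau(self):
        # SXwint handles heterogeneous tau; SX's joint model has no
        # interaction columns, so its exact regime is constant tau
        spec = linear_spec()
        X, y, t, tau = linear_dgp(n=400, heterogeneous=True, seed=2)
        (Xa, ya, ta), (Xb, yb, tb) = _split(X, y, t)
        m = fit_sx_learner(Xa, ya, ta, Xb, yb, tb, spec, interactions=True)
        np.testing.assert_allclose(m.predict_cate(X), tau, atol=1e-8)

        X, y, t, tau = linear_dgp(n=400, heterogeneous=False, seed=3)
        (Xa, ya, ta), (Xb, yb, tb) = _split(X, y, t)
        m = fit_sx_learner(Xa, ya, ta, Xb, yb, tb, spec, interactions=False)
        np.testing.assert_allclose(m.predict_cate(X), tau, atol=1e-8)

    def test_s_learner_recovers_constant_effect_without_interaction_signal(self):
        # zero-interaction DGP: the interaction block's coefficients come
        # back exactly zero, so tau-hat is the constant beta2 everywhere
        X, y, t, tau = linear_dgp(n=300, heterogeneous=False, seed=4)
        model = fit_s_learner(X, y, t, linear_spec())
        np.testing.assert_allclose(model.predict_cate(X), tau[0], atol=1e-8)


class TestEndpoints:
    """Forcing g to 0 (resp. 1) collapses the blend to tau1 (resp. tau0)."""

    @pytest.mark.parametrize("g,component", [(0.0, "tau1"), (1.0, "tau0")])
    def test_x_learner_endpoints(self, g, component):
        X, y, t, _ = linear_dgp(n=200, seed=6)
        m = fit_x_learner(X, y, t, linear_spec(), propensity_override=g)
        np.testing.assert_array_equal(
            m.predict_cate(X), m.components[component].predict(X))

    @pytest.mark.parametrize("interactions", [False, True])
    @pytest.mark.parametrize("g,component", [(0.0, "tau1"), (1.0, "tau0")])
    def test_sx_learner_endpoints(self, interactions, g, component):
        X, y, t, _ = linear_dgp(n=300, seed=7)
        (Xa, ya, ta), (Xb, yb, tb) = _split(X, y, t)
        m = fit_sx_learner(Xa, ya, ta, Xb, yb, tb, linear_spec(),
                           interactions=interactions, propensity_override=g)
        np.testing.assert_array_equal(
            m.predict_cate(X), m.components[component].predict(X))

    def test_sx_equals_sxwint_noiseless_linear_no_interaction(self):
        # with g forced to 0 and a zero-interaction noiseless linear DGP,
        # the interaction coefficients are estimated exactly zero, so the
        # two hybrid learners coincide
        X, y, t, _ = linear_dgp(n=400, heterogeneous=False, seed=8)
        (Xa, ya, ta), (Xb, yb, tb) = _split(X, y, t)
        kw = dict(spec=linear_spec(), propensity_override=0.0)
        m_sx = fit_sx_learner(Xa, ya, ta, Xb, yb, tb, interactions=False, **kw)
        m_wint = fit_sx_learner(Xa, ya, ta, Xb, yb, tb, interactions=True, **kw)
        np.testing.assert_allclose(
            m_sx.predict_cate(X), m_wint.predict_cate(X), atol=1e-8)


class TestErrorsAndContracts:
    def test_s_learner_rejects_missing_interactions(self):
        X, y, t, _ = linear_dgp(n=50, seed=9)
        with pytest.raises(ValueError, match="interaction"):
            fit_s_learner(X, y, t, linear_spec(), interactions=False)

    def test_s_style_fit_without_interactions_is_constant_in_x(self):
        # the very failure mode the guard exists for: a linear joint model
        # on [x, t] can only express a constant effect
        X, y, t, _ = linear_dgp(n=200, heterogeneous=True, seed=10)
        from sklearn.linear_model import LinearRegression
        mu = LinearRegression().fit(ml._joint_design(X, t, False), y)
        tau = (mu.predict(ml._joint_design(X, np.ones(len(X)), False))
               - mu.predict(ml._joint_design(X, np.zeros(len(X)), False)))
        assert np.ptp(tau) < 1e-10

    def test_empty_arm_errors(self):
        X, y, t, _ = linear_dgp(n=60, seed=11)
        t = np.zeros_like(t)
        with pytest.raises(ValueError, match="T=1"):
            fit_t_learner(X, y, t, linear_spec())
        with pytest.raises(ValueError, match="T=1"):
            fit_x_learner(X, y, t, linear_spec())

    def test_sx_overlapping_splits_rejected(self):
        X, y, t, _ = linear_dgp(n=60, seed=12)
        with pytest.raises(ValueError, match="overlap"):
            fit_sx_learner(X[:40], y[:40], t[:40], X[20:], y[20:], t[20:],
                           linear_spec(), train_index=np.arange(40),
                           retrain_index=np.arange(20, 60))

    def test_predictions_deterministic_and_permutation_equivariant(self):
        X, y, t, _ = linear_dgp(n=150, seed=13)
        m1 = fit_x_learner(X, y, t, seed=42)
        m2 = fit_x_learner(X, y, t, seed=42)
        tau1, tau2 = m1.predict_cate(X), m2.predict_cate(X)
        np.testing.assert_array_equal(tau1, tau2)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(m1.predict_cate(X[perm]), tau1[perm])

    def test_schema_mismatch_lists_missing_columns(self):
        import pandas as pd
        X, y, t, _ = linear_dgp(n=80, seed=14)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        m = fit_t_learner(df, y, t, linear_spec())
        with pytest.raises(ValueError, match="d"):
            m.predict_cate(df[["a", "b", "c"]])

    def test_save_load_roundtrip(self, tmp_path):
        X, y, t, _ = linear_dgp(n=100, seed=15)
        m = fit_x_learner(X, y, t, linear_spec(), propensity_override=0.5)
        ml.save_model(m, tmp_path / "m")
        loaded = ml.load_model(tmp_path / "m")
        np.testing.assert_array_equal(loaded.predict_cate(X), m.predict_cate(X))
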