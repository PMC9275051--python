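import itertools

import numpy as np
import pandas as pd
import pytest

from dynpred.learners import (CoxLearner, PenalizedCoxLearner, RSFLearner,
                              SPLSDRLearner, breslow_baseline, breslow_loglik,
                              deviance_residuals, nelson_aalen, vimp)
from dynpred.learners.cox import drop_aliased
from dynpred.learners.spls import _spls_fit


class TestNelsonAalen:
    def test_hand_computed_risk_sets(self):
        """times (1..5), events (1,0,1,0,0): jumps 1/5 at t=1 and 1/3 at
        t=3."""
        na = nelson_aalen([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
        assert np.isclose(na.at(2.5), 1 / 5)
        assert np.isclose(na.at(5.0), 1 / 5 + 1 / 3)
        assert na.at(0.5) == 0.0

    def test_all_censored_is_zero(self):
        with pytest.warns(RuntimeWarning, match="no events"):
            na = nelson_aalen([1.0, 2.0], [0, 0])
        assert na.at(10.0) == 0.0

    def test_single_event(self):
        na = nelson_aalen([1.0], [1])
        assert np.isclose(na.at(1.0), 1.0)

    def test_matches_lifelines(self):
        from lifelines import NelsonAalenFitter

        rng = np.random.default_rng(0)
        t = rng.exponential(1, 80)
        e = (rng.uniform(size=80) < 0.7).astype(int)
        na = nelson_aalen(t, e)
        ref = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        mine = np.atleast_1d(na.at(grid))
        theirs = [float(ref.cumulative_hazard_at_times(g).iloc[0]) for g in grid]
        assert np.allclose(mine, theirs, atol=1e-10)


class TestDevianceResiduals:
    def test_formula_cases(self):
        from dynpred.learners.base import StepFunction

        # delta=1, Lambda=1 -> M=0 -> d=0
        ch = StepFunction([1.0], [1.0])
        assert np.isclose(deviance_residuals([1.5], [1], ch)[0], 0.0)
        # delta=0, Lambda=0 -> d=0
        ch0 = StepFunction([10.0], [1.0])
        assert np.isclose(deviance_residuals([1.0], [0], ch0)[0], 0.0)
        # delta=1, Lambda=0.5 -> sqrt(-2(0.5 + log 0.5)) ~ 0.6215
        ch5 = StepFunction([0.5], [0.5])
        d = deviance_residuals([1.0], [1], ch5)[0]
        assert np.isclose(d, np.sqrt(-2 * (0.5 + np.log(0.5))), atol=1e-12)
        assert np.isclose(d, 0.6215, atol=1e-4)

    def test_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 60)
        e = (rng.uniform(size=60) < 0.6).astype(int)
        na = nelson_aalen(t, e)
        d = deviance_residuals(t, e)
        lam = np.atleast_1d(na.at(t))
        M = e - lam
        expect = np.sign(M) * np.sqrt(
            -2 * (M + np.where(e == 1, np.log(e - M), 0.0)))
        assert np.allclose(d, expect, atol=1e-12)

    def test_event_with_zero_hazard_guard(self):
        from dynpred.learners.base import StepFunction

        with pytest.raises(ValueError, match="martingale"):
            deviance_residuals([1.0], [1], StepFunction([5.0], [1.0]))


def _brute_force_logrank_split(X, times, events):
    """Best (feature, cutpoint) by the two-group log-rank statistic over all
    admissible cutpoints; independent of any tree code."""
    from sksurv.compare import compare_survival
    from sksurv.util import Surv

    y = Surv.from_arrays(events.astype(bool), times)
    best = (-np.inf, None, None)
    for j in range(X.shape[1]):
        for cut in np.unique(X[:, j])[:-1]:
            grp = (X[:, j] > cut).astype(int)
            if grp.min() == grp.max():
                continue
            chi2, _ = compare_survival(y, grp)
            if chi2 > best[0]:
                best = (chi2, j, cut)
    return best


class TestRandomSurvivalForest:
    def test_default_mtry_is_sqrt_p(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, 100)),
                         columns=[f"v{j}" for j in range(100)])
        t = rng.exponential(1, 60)
        e = (rng.uniform(size=60) < 0.7).astype(int)
        f = RSFLearner("default", n_estimators=5, seed=0).fit(X, t, e)
        assert f.mtry_ == 10

    def test_single_node_tree_predicts_marginal_nelson_aalen(self):
        rng = np.random.default_rng(3)
        n = 30
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        f = RSFLearner("default", n_estimators=1, nodesize=n, seed=0)
        f.fit(X, t, e)
        # ntree=1, nodesize=n and bootstrap aggregation over one tree built on
        # a bootstrap sample: force the stump on the original data instead
        from sksurv.ensemble import RandomSurvivalForest
        from sksurv.util import Surv

        stump = RandomSurvivalForest(n_estimators=1, min_samples_leaf=n,
                                     max_features=None, bootstrap=False,
                                     random_state=0)
        stump.fit(X.to_numpy(), Surv.from_arrays(e.astype(bool), t))
        f.forest_ = stump
        f.feature_names_ = ["x"]
        na = nelson_aalen(t, e)
        t_hor = np.median(t)
        expect = 1 - np.exp(-na.at(t_hor))
        pred = f.predict_probability(X, t_hor)
        assert np.allclose(pred, expect, atol=1e-10)

    def test_depth_one_split_matches_bruteforce_logrank(self):
        """A single depth-1 tree grown without bootstrap and with all
        features picks the same split as exhaustive log-rank search."""
        from sksurv.ensemble import RandomSurvivalForest
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        for trial in range(3):
            n = 8
            X = rng.normal(size=(n, 2))
            t = rng.exponential(1, n) + 0.1
            e = np.ones(n, dtype=int)
            tree = RandomSurvivalForest(
                n_estimators=1, max_depth=1, min_samples_leaf=1,
                min_samples_split=2, max_features=None, bootstrap=False,
                random_state=trial).fit(
                X, Surv.from_arrays(e.astype(bool), t))
            est = tree.estimators_[0]
            feat = est.tree_.feature[0]
            thr = est.tree_.threshold[0]
            chi2, j, cut = _brute_force_logrank_split(X, t, e)
            assert feat == j
            # sklearn thresholds at the midpoint of adjacent values
            vals = np.sort(np.unique(X[:, j]))
            lo = vals[vals <= cut].max()
            hi = vals[vals > cut].min()
            assert lo < thr <= hi

    def test_vimp_zero_for_unused_predictor(self):
        rng = np.random.default_rng(5)
        n = 80
        X = pd.DataFrame({
            "signal": rng.normal(size=n),
            "constant": np.zeros(n),
        })
        lp = 1.5 * X["signal"].to_numpy()
        T = rng.exponential(np.exp(-lp))
        C = rng.exponential(2, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        f = RSFLearner("default", n_estimators=30, nodesize=5, seed=0)
        f.fit(X, t, e)
        imp = vimp(f.forest_, X, t, e, seed=0)
        assert imp["constant"] == 0.0
        assert imp["signal"] > 0.0

    def test_vimp_null_centered_on_zero(self):
        rng = np.random.default_rng(6)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=[f"n{j}" for j in range(4)])
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        f = RSFLearner("default", n_estimators=50, nodesize=10, seed=1)
        f.fit(X, t, e)
        imp = vimp(f.forest_, X, t, e, seed=1)
        assert abs(imp.mean()) < 0.02


class TestCox:
    def test_log_hr_recovery(self, survival_toy):
        X, t, e = survival_toy
        fit = CoxLearner().fit(X, t, e)
        se = 1 / np.sqrt(e.sum())
        assert abs(fit.coef_["x1"] - 1.0) < 3 * se

    def test_null_model_predicts_constant(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(index=range(50))       # no predictors
        t = rng.exponential(1, 50)
        e = np.ones(50, dtype=int)
        fit = CoxLearner().fit(X, t, e)
        p = fit.predict_probability(X, np.median(t))
        assert np.allclose(p, p[0])

    def test_backward_selection_deterministic_and_drops_noise(self):
        rng = np.random.default_rng(8)
        n = 300
        X = pd.DataFrame({"signal": rng.normal(size=n),
                          "noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        T = rng.exponential(np.exp(-1.2 * X["signal"].to_numpy()))
        C = rng.exponential(2, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        sel1 = CoxLearner(select=True).fit(X, t, e).feature_names_
        sel2 = CoxLearner(select=True).fit(X, t, e).feature_names_
        assert sel1 == sel2                      # deterministic given data
        assert "signal" in sel1

    def test_aliased_columns_dropped(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2 * X["a"] + 1.0               # exact alias
        keep = drop_aliased(X)
        assert keep == ["a"]

    def test_breslow_baseline_reduces_to_nelson_aalen_at_zero_lp(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(1, 40)
        e = (rng.uniform(size=40) < 0.6).astype(int)
        bl = breslow_baseline(t, e, np.zeros(40))
        na = nelson_aalen(t, e)
        grid = np.quantile(t, [0.3, 0.6, 0.9])
        assert np.allclose(np.atleast_1d(bl.at(grid)),
                           np.atleast_1d(na.at(grid)), atol=1e-12)


class TestPenalizedCox:
    def test_huge_penalty_zeroes_all_coefficients(self, survival_toy):
        X, t, e = survival_toy
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e4])
        m.fit(((X - X.mean()) / X.std()).to_numpy(),
              Surv.from_arrays(e.astype(bool), t))
        assert np.allclose(m.coef_, 0.0)

    def test_ridge_small_penalty_matches_unpenalized(self, survival_toy):
        X, t, e = survival_toy
        cox = CoxLearner().fit(X, t, e)
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        ridge = CoxPHSurvivalAnalysis(alpha=1e-8, ties="breslow")
        ridge.fit(X.to_numpy(), Surv.from_arrays(e.astype(bool), t))
        assert np.allclose(ridge.coef_, cox.coef_.to_numpy(), atol=1e-4)

    def test_duplicated_predictor_ridge_symmetry(self):
        rng = np.random.default_rng(11)
        n = 150
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        T = rng.exponential(np.exp(-x))
        C = rng.exponential(2, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        fit = PenalizedCoxLearner("ridge", n_folds=4, seed=0).fit(X, t, e)
        assert np.isclose(fit.coef_["a"], fit.coef_["b"], atol=1e-6)

    def test_lasso_selects_signal(self, survival_toy):
        X, t, e = survival_toy
        fit = PenalizedCoxLearner("lasso", n_folds=5, seed=0).fit(X, t, e)
        assert "x1" in fit.selected_


class TestSPLSDR:
    def test_first_direction_proportional_to_covariances(self):
        """Without sparsity the first PLS1 loading is X'y normalized."""
        rng = np.random.default_rng(12)
        n = 100
        X = rng.normal(size=(n, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = 0.8 * X[:, 0] - 0.1 * X[:, 1] + rng.normal(0, 0.1, n)
        W, P = _spls_fit(X, y, 1, 0.0, False)
        expect = X.T @ y
        expect = expect / np.linalg.norm(expect)
        assert np.allclose(np.abs(W[:, 0]), np.abs(expect), atol=1e-10)

    def test_max_sparsity_one_nonzero_loading_per_component(self, survival_toy):
        X, t, e = survival_toy
        fit = SPLSDRLearner("max", max_components=2, n_folds=4, seed=0)
        fit.fit(X, t, e)
        assert all((fit.W_[:, c] != 0).sum() == 1
                   for c in range(fit.W_.shape[1]))

    def test_zero_variance_predictor_dropped(self, survival_toy):
        X, t, e = survival_toy
        X = X.copy()
        X["flat"] = 1.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit = SPLSDRLearner("none", max_components=2, n_folds=4,
                                seed=0).fit(X, t, e)
        assert "flat" not in fit.feature_names_

    def test_null_predictors_give_near_marginal_predictions(self):
        rng = np.random.default_rng(13)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"z{j}" for j in range(5)])
        t = rng.exponential(1, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        fit = SPLSDRLearner("none", max_components=3, n_folds=5, seed=0)
        fit.fit(X, t, e)
        p = fit.predict_probability(X, float(np.median(t)))
        marginal = 1 - np.exp(-nelson_aalen(t, e).at(float(np.median(t))))
        assert np.std(p) < 0.1
        assert abs(np.mean(p) - marginal) < 0.1


class TestPredictProbability:
    def test_closed_forms(self, survival_toy):
        X, t, e = survival_toy
        fit = CoxLearner().fit(X, t, e)
        from dynpred.learners.base import StepFunction

        fit.baseline_hazard_ = StepFunction([], [])      # Lambda0 = 0
        assert np.allclose(fit.predict_probability(X, 1.0), 0.0)
        fit.baseline_hazard_ = StepFunction([0.5], [np.log(2.0)])
        fit.coef_[:] = 0.0
        fit.model_.coef_[:] = 0.0
        p = fit.predict_probability(X, 1.0)
        assert np.allclose(p, 0.5)               # 1 - exp(-ln 2)

    def test_rank_preserving_in_linear_predictor(self, survival_toy):
        X, t, e = survival_toy
        fit = PenalizedCoxLearner("lasso", n_folds=4, seed=0).fit(X, t, e)
        lp = fit.linear_predictor(X)
        p = fit.predict_probability(X, 1.0)
        order = np.argsort(lp)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_probability_monotone_in_horizon(self, survival_toy):
        X, t, e = survival_toy
        for learner in (CoxLearner(),
                        PenalizedCoxLearner("lasso", n_folds=4, seed=0),
                        RSFLearner("default", n_estimators=20, seed=0)):
            learner.fit(X, t, e)
            horizons = np.quantile(t, [0.2, 0.4, 0.6, 0.8])
            P = np.stack([learner.predict_probability(X, h) for h in horizons])
            assert np.all(np.diff(P, axis=0) >= -1e-12)

    def test_unseen_columns_rejected(self, survival_toy):
        X, t, e = survival_toy
        fit = CoxLearner().fit(X, t, e)
        with pytest.raises(KeyError, match="missing"):
            fit.predict_probability(X[["x1"]], 1.0)


def test_breslow_loglik_matches_lifelines_partial_likelihood():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(14)
    n = 120
    df = pd.DataFrame({"x": rng.normal(size=n)})
    T = rng.exponential(np.exp(-0.8 * df["x"].to_numpy()))
    df["t"] = T + rng.uniform(0, 1e-9, n)        # break ties
    df["e"] = 1
    cf = CoxPHFitter().fit(df, "t", "e")
    lp = (df[["x"]].to_numpy() @ cf.params_.to_numpy())
    mine = breslow_loglik(lp, df["t"].to_numpy(), df["e"].to_numpy())
    assert np.isclose(mine, cf.log_likelihood_, rtol=1e-6)
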