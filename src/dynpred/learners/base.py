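"""Shared survival machinery: step functions, Nelson-Aalen and Breslow
estimators, the Breslow partial likelihood, and the learner contract.

Every learner maps the landmark feature matrix to an individual probability
of the event within the horizon window. Regression-type learners do so
through ``pi = 1 - exp(-Lambda0(t_Hor) * exp(lp))`` with a Breslow baseline
cumulative hazard (the Nelson-Aalen estimator generalized to a non-zero
linear predictor); the forest averages leaf Nelson-Aalen cumulative hazards.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "StepFunction",
    "nelson_aalen",
    "breslow_baseline",
    "breslow_loglik",
    "SurvivalLearner",
    "RegressionSurvivalLearner",
]


class StepFunction:
    """Right-continuous step function with jumps at ``times``.

    ``values`` are the post-jump values; before the first jump the function
    equals ``initial`` (0 for cumulative hazards). ``at(t, side="left")``
    evaluates the left limit, needed for IPCW weights at event times.
    """

    def __init__(self, times, values, initial: float = 0.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.initial = float(initial)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("step times must be strictly increasing")

    def at(self, t, side: str = "right"):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            out = np.full(t.shape, self.initial)
        else:
            idx = np.searchsorted(self.times, t,
                                  side="right" if side == "right" else "left")
            out = np.where(idx == 0, self.initial,
                           self.values[np.maximum(idx - 1, 0)])
        return out if out.size > 1 else float(out[0])

    def __call__(self, t):
        return self.at(t, side="right")


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative-hazard estimator ``sum_{t_j <= t} d_j / Y_j``.

    ``d_j`` is the number of events and ``Y_j`` the size of the risk set at
    the j-th distinct event time. With no events the function is identically
    zero (with a warning).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if events.sum() == 0:
        warnings.warn("no events observed; Nelson-Aalen estimate is zero",
                      RuntimeWarning)
        return StepFunction([], [])
    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=float)
    d = np.array([((times == t) & (events == 1)).sum() for t in event_times],
                 dtype=float)
    return StepFunction(event_times, np.cumsum(d / at_risk))


def breslow_baseline(times, events, lp) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard of a proportional
    hazards model with linear predictor ``lp``:
    ``Lambda0(t) = sum_{t_j <= t} d_j / sum_{l in R(t_j)} exp(lp_l)``.
    Reduces to Nelson-Aalen when ``lp`` is identically zero."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lp = np.asarray(lp, dtype=float)
    if events.sum() == 0:
        warnings.warn("no events observed; baseline hazard is zero", RuntimeWarning)
        return StepFunction([], [])
    risk = np.exp(lp)
    event_times = np.unique(times[events == 1])
    denom = np.array([risk[times >= t].sum() for t in event_times])
    d = np.array([((times == t) & (events == 1)).sum() for t in event_times],
                 dtype=float)
    return StepFunction(event_times, np.cumsum(d / denom))


def breslow_loglik(lp, times, events) -> float:
    """Breslow-approximation Cox partial log-likelihood at linear predictor
    ``lp`` (used for AIC model selection and cross-validated deviance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lp = np.asarray(lp, dtype=float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        d = tied.sum()
        ll += lp[tied].sum() - d * np.log(np.exp(lp[times >= t]).sum())
    return float(ll)


def cv_deviance(fit_lp, X, times, events, n_folds=10, rng=None):
    """Verweij & Van Houwelingen cross-validated partial-likelihood deviance.

    ``fit_lp(X_train, t_train, e_train) -> callable(X) -> lp``. The fold-k
    contribution is ``-2 [ ll_all(beta_-k) - ll_-k(beta_-k) ]``, which avoids
    degenerate within-fold risk sets.
    """
    rng = np.random.default_rng(rng)
    n = len(times)
    folds = rng.permutation(n) % n_folds
    dev = 0.0
    for k in range(n_folds):
        tr = folds != k
        predict = fit_lp(X[tr], times[tr], events[tr])
        lp_all = predict(X)
        dev += -2.0 * (breslow_loglik(lp_all, times, events)
                       - breslow_loglik(lp_all[tr], times[tr], events[tr]))
    return dev


class SurvivalLearner:
    """Common fit/predict contract for all survival prediction methods."""

    name: str = "base"

    def fit(self, X: pd.DataFrame, times, events) -> "SurvivalLearner":
        raise NotImplementedError

    def predict_probability(self, X: pd.DataFrame, t_hor: float) -> np.ndarray:
        """Individual probability of the event within ``t_hor`` of landmark."""
        raise NotImplementedError

    def fit_landmark(self, ld) -> "SurvivalLearner":
        return self.fit(ld.features, ld.time, ld.event)

    def _check_columns(self, X: pd.DataFrame):
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise KeyError(f"prediction data missing columns: {missing[:5]}")
        return X[self.feature_names_]


class RegressionSurvivalLearner(SurvivalLearner):
    """Learners with a linear predictor and a Breslow baseline hazard."""

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def _store_baseline(self, X, times, events):
        self.baseline_hazard_ = breslow_baseline(
            times, events, self.linear_predictor(X))

    def predict_probability(self, X, t_hor):
        lp = self.linear_predictor(X)
        lam0 = self.baseline_hazard_.at(t_hor)
        pi = 1.0 - np.exp(-lam0 * np.exp(lp))
        return np.clip(pi, 0.0, 1.0)
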