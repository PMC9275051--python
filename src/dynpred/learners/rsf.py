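"""Random survival forest learner with OOB tuning and permutation VIMP.

Trees are grown on bootstrap samples with log-rank best splits over a random
subset of ``M`` predictors per node (scikit-survival); leaves carry
Nelson-Aalen cumulative hazard curves, and the individual event probability
is ``1 - exp(-mean_b Lambda_b(t_Hor))`` over the ``B`` trees.

The out-of-bag (OOB) error is defined as one minus Harrell's concordance of
the OOB ensemble risk predictions. The ``optimize`` variant grid-searches
``(M, S)`` (subset size, minimal node size) on that error; ``select``
additionally refits on the variables with positive permutation importance.
VIMP for predictor ``p`` is the mean over trees of the increase in the
tree's OOB error after permuting ``p`` within the tree's OOB sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .base import SurvivalLearner

__all__ = ["RSFLearner", "oob_error", "vimp"]

NODESIZE_GRID = (3, 5, 10, 15, 20)


def _oob_indices(forest, n):
    """Per-tree out-of-bag row indices (sklearn bootstrap bookkeeping)."""
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)
    try:
        nsb = _get_n_samples_bootstrap(n, forest.max_samples, None)
    except TypeError:  # older sklearn signature without sample_weight
        nsb = _get_n_samples_bootstrap(n, forest.max_samples)
    out = []
    for est in forest.estimators_:
        try:
            idx = _generate_unsampled_indices(est.random_state, n, nsb, None)
        except TypeError:
            idx = _generate_unsampled_indices(est.random_state, n, nsb)
        out.append(np.asarray(idx))
    return out


def _cindex_error(times, events, risk):
    c = concordance_index_censored(events.astype(bool), times, risk)[0]
    return 1.0 - c


def oob_error(forest, X, times, events) -> float:
    """1 - Harrell C of the OOB ensemble risk predictions."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    oob = _oob_indices(forest, n)
    risk_sum = np.zeros(n)
    counts = np.zeros(n)
    for est, idx in zip(forest.estimators_, oob):
        if idx.size == 0:
            continue
        risk_sum[idx] += est.predict(X[idx])
        counts[idx] += 1
    have = counts > 0
    return _cindex_error(times[have], events[have], risk_sum[have] / counts[have])


def vimp(forest, X, times, events, seed: int = 0) -> pd.Series:
    """Permutation variable importance.

    For each predictor: mean over trees of (tree OOB error after permuting
    the predictor within the OOB sample) minus (tree OOB error). Predictors
    constant within every OOB sample get VIMP 0.
    """
    Xv = np.asarray(X, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(Xv.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rng = np.random.default_rng(seed)
    n, p = Xv.shape
    oob = _oob_indices(forest, n)
    total = np.zeros(p)
    n_used = np.zeros(p)
    for est, idx in zip(forest.estimators_, oob):
        if idx.size < 3 or events[idx].sum() == 0 or events[idx].sum() == idx.size:
            continue
        Xo = Xv[idx]
        base = _cindex_error(times[idx], events[idx], est.predict(Xo))
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        for j in used:
            col = Xo[:, j]
            if np.all(col == col[0]):
                continue
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(col)
            total[j] += _cindex_error(times[idx], events[idx], est.predict(Xp)) - base
            n_used[j] += 1
        # predictors never split on contribute 0 for this tree
        n_used[np.setdiff1d(np.arange(p), used)] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(n_used > 0, total / np.maximum(n_used, 1), 0.0)
    return pd.Series(imp, index=names)


class RSFLearner(SurvivalLearner):
    """Random survival forest.

    ``tune``: ``"default"`` (M = sqrt(P) rounded down, S = 15),
    ``"optimize"`` (grid search (M, S) on the OOB error) or ``"select"``
    (optimize, then refit on predictors with VIMP > 0).
    """

    def __init__(self, tune: str = "default", n_estimators: int = 500,
                 mtry: int | None = None, nodesize: int = 15, seed: int = 0,
                 n_estimators_tune: int | None = None):
        if tune not in ("default", "optimize", "select"):
            raise ValueError(f"unknown tune mode {tune!r}")
        self.tune = tune
        self.n_estimators = n_estimators
        self.mtry = mtry
        self.nodesize = nodesize
        self.seed = seed
        self.n_estimators_tune = n_estimators_tune or max(100, n_estimators // 5)
        self.name = f"rsf_{tune}"

    def _make(self, mtry, nodesize, n_estimators):
        return RandomSurvivalForest(
            n_estimators=n_estimators,
            max_features=mtry,
            min_samples_leaf=nodesize,
            min_samples_split=max(2, 2 * nodesize),
            random_state=self.seed,
            n_jobs=1,
        )

    def _grid(self, p):
        root = max(1, int(np.sqrt(p)))
        ms = sorted({max(1, root // 2), root, min(p, 2 * root), max(1, p // 3)})
        return [(m, s) for m in ms for s in NODESIZE_GRID]

    def fit(self, X: pd.DataFrame, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if events.sum() < 2:
            raise ValueError("need at least 2 events to grow a survival forest")
        self.feature_names_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        y = Surv.from_arrays(events.astype(bool), times)
        p = Xv.shape[1]
        mtry = self.mtry if self.mtry is not None else max(1, int(np.sqrt(p)))
        nodesize = self.nodesize

        if self.tune in ("optimize", "select"):
            best = (np.inf, mtry, nodesize)
            for m, s in self._grid(p):
                f = self._make(m, s, self.n_estimators_tune).fit(Xv, y)
                err = oob_error(f, Xv, times, events)
                if err < best[0]:
                    best = (err, m, s)
            _, mtry, nodesize = best

        self.mtry_, self.nodesize_ = mtry, nodesize
        self.forest_ = self._make(mtry, nodesize, self.n_estimators).fit(Xv, y)
        self.oob_error_ = oob_error(self.forest_, Xv, times, events)

        if self.tune == "select":
            self.vimp_ = vimp(self.forest_, X, times, events, seed=self.seed)
            keep = [c for c, v in self.vimp_.items() if v > 0]
            if keep and len(keep) < p:
                self.feature_names_ = keep
                Xv = X[keep].to_numpy(dtype=float)
                m2 = min(mtry, len(keep))
                self.forest_ = self._make(m2, nodesize, self.n_estimators).fit(Xv, y)
                self.oob_error_ = oob_error(self.forest_, Xv, times, events)
        else:
            self.vimp_ = None
        return self

    def predict_probability(self, X, t_hor):
        Xs = self._check_columns(X).to_numpy(dtype=float)
        chf = self.forest_.predict_cumulative_hazard_function(Xs, return_array=True)
        grid = self.forest_.unique_times_
        pos = np.searchsorted(grid, t_hor, side="right") - 1
        lam = chf[:, pos] if pos >= 0 else np.zeros(len(Xs))
        return np.clip(1.0 - np.exp(-lam), 0.0, 1.0)
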