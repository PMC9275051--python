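"""Multi-layer cross-validation and the Brier-minimizing superlearner.

The outer layer assesses predictive accuracy on held-out folds with the
whole pipeline — marker mixed models included — refitted inside each
training fold, so held-out subjects' summaries always come from models that
never saw their outcomes. The superlearner layer runs a second
cross-validation inside each training sample to obtain out-of-fold member
predictions, finds the convex weights minimizing the IPCW Brier score of
the blend, and refits the members on the full training sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax

from .data import LandmarkConfig, LongitudinalDataset, SurvivalTable
from .learners import LearnerSpec, make_learner
from .metrics import brier_ipcw
from .summaries import build_summary_matrix, fit_marker_model

logger = logging.getLogger("dynpred")

__all__ = ["CVPlan", "make_folds", "fit_all_markers", "run_nested_cv",
           "optimize_weights", "SuperLearner"]


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation layout: outer assessment folds, inner superlearner
    folds, number of repetitions, master seed."""

    n_outer: int = 10
    n_inner: int = 9
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_outer < 2 or self.n_inner < 2 or self.n_reps < 1:
            raise ValueError("need >= 2 folds per layer and >= 1 repetition")


def make_folds(events, n_folds, rng, max_tries: int = 50) -> np.ndarray:
    """Random fold labels such that every fold and every training complement
    contains at least one event; refolds with a fresh draw otherwise."""
    events = np.asarray(events, dtype=int)
    n = len(events)
    if events.sum() == 0:
        raise ValueError("cannot fold a sample with no events")
    for attempt in range(max_tries):
        folds = rng.permutation(n) % n_folds
        ok = all(events[folds == k].sum() >= 1 for k in range(n_folds))
        if ok:
            if attempt:
                logger.info("refolded %d times to get events in every fold",
                            attempt)
            return folds
    logger.warning("could not balance events across folds; using last draw")
    return folds


def fold_balance_diagnostic(times, events, folds) -> pd.DataFrame:
    """Two-sample log-rank p-value of each fold against the rest (a check
    that event-time distributions are comparable across folds)."""
    from lifelines.statistics import logrank_test

    rows = []
    for k in np.unique(folds):
        m = folds == k
        res = logrank_test(times[m], times[~m], events[m], events[~m])
        rows.append({"fold": int(k), "n": int(m.sum()),
                     "events": int(events[m].sum()),
                     "logrank_p": float(res.p_value)})
    diag = pd.DataFrame(rows)
    logger.info("fold balance (log-rank p vs rest): %s",
                np.round(diag["logrank_p"].to_numpy(), 3))
    return diag


def fit_all_markers(long: LongitudinalDataset, marker_specs: dict) -> dict:
    """Fit one mixed model per marker. ``marker_specs`` maps marker name to
    keyword arguments of :func:`fit_marker_model`."""
    return {m: fit_marker_model(long, m, **kw) for m, kw in marker_specs.items()}


def _split_tables(surv: SurvivalTable, ids):
    f = surv.frame
    return SurvivalTable(f[f["id"].isin(set(ids))].copy())


def run_nested_cv(long: LongitudinalDataset, surv: SurvivalTable,
                  cfg: LandmarkConfig, marker_specs: dict,
                  learner_specs, plan: CVPlan):
    """Outer cross-validation with full pipeline refits per training fold.

    Returns a list (one entry per repetition) of dicts with the fold labels,
    the out-of-fold prediction DataFrame (index = subject id, one column per
    method), and the observed landmark-scale ``time``/``event`` arrays
    aligned to it.
    """
    from .data import apply_landmark

    _, at_risk = apply_landmark(long, surv, cfg)
    ids = at_risk.frame["id"].to_numpy()
    times = at_risk.frame["time"].to_numpy(dtype=float) - cfg.t_landmark
    events = at_risk.frame["event"].to_numpy(dtype=int)
    results = []
    for rep in range(plan.n_reps):
        rng = np.random.default_rng(plan.seed + 1000 * rep)
        folds = make_folds(events, plan.n_outer, rng)
        fold_balance_diagnostic(times, events, folds)
        preds = pd.DataFrame(
            np.nan, index=pd.Index(ids, name="id"),
            columns=[s.method for s in learner_specs])
        for k in range(plan.n_outer):
            tr_ids, te_ids = ids[folds != k], ids[folds == k]
            surv_tr = _split_tables(surv, tr_ids)
            surv_te = _split_tables(surv, te_ids)
            lf = long.frame
            long_tr = LongitudinalDataset(
                lf[lf["id"].isin(set(tr_ids))].copy(), dict(long.families))
            models = fit_all_markers(long_tr, marker_specs)
            ld_tr = build_summary_matrix(models, long_tr, surv_tr, cfg)
            ld_te = build_summary_matrix(models, long, surv_te, cfg)
            for spec in learner_specs:
                learner = make_learner(spec).fit_landmark(ld_tr)
                preds.loc[te_ids, spec.method] = learner.predict_probability(
                    ld_te.features, cfg.t_horizon)
        assert not preds.isna().any().any(), "missing out-of-fold predictions"
        results.append({"rep": rep, "folds": folds, "predictions": preds,
                        "time": times, "event": events})
    return results


def run_feature_cv(ld, learner_specs, n_folds: int = 10, seed: int = 0,
                   n_reps: int = 1):
    """K-fold cross-validation at the feature level: the landmark feature
    matrix is taken as fixed (no marker-model refits). Appropriate when the
    features are raw baseline values; the full pipeline uses
    :func:`run_nested_cv` instead."""
    times, events = ld.time, ld.event
    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + 1000 * rep)
        folds = make_folds(events, n_folds, rng)
        preds = pd.DataFrame(np.nan, index=ld.features.index,
                             columns=[s.method for s in learner_specs])
        for k in range(n_folds):
            tr = np.where(folds != k)[0]
            te = np.where(folds == k)[0]
            ld_tr = ld.subset(tr)
            for spec in learner_specs:
                learner = make_learner(spec).fit_landmark(ld_tr)
                preds.iloc[te, preds.columns.get_loc(spec.method)] = \
                    learner.predict_probability(ld.features.iloc[te],
                                                ld.config.t_horizon)
        out.append({"rep": rep, "folds": folds, "predictions": preds,
                    "time": times, "event": events})
    return out


def optimize_weights(member_predictions, times, events, t_hor,
                     tie_ridge: float = 1e-8) -> np.ndarray:
    """Convex weights minimizing the IPCW Brier score of the blended
    prediction. A vanishing ridge on ||w||^2 breaks flat objectives toward
    the most uniform minimizer (two identical members get 0.5 each).
    Deterministic given its inputs (softmax parametrization, fixed
    multi-starts, dense-grid fallback for very small member sets)."""
    P = np.asarray(member_predictions, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n, M = P.shape
    if M == 0:
        raise ValueError("need at least one member")
    if M == 1:
        return np.ones(1)

    def objective(z):
        w = softmax(z)
        return brier_ipcw(P @ w, times, events, t_hor) + tie_ridge * (w @ w)

    starts = [np.zeros(M)] + [4.0 * np.eye(M)[j] for j in range(M)]
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 400 * M, "xatol": 1e-8,
                                "fatol": 1e-12})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    w = softmax(best.x)
    # clean tiny components and renormalize
    w[w < 1e-10] = 0.0
    return w / w.sum()


class SuperLearner:
    """Brier-score-minimizing convex combination of survival learners.

    ``fit`` runs the inner cross-validation (marker models refitted per
    inner fold), optimizes the weights on the out-of-fold member
    predictions, then refits every member and the marker models on the full
    training sample.
    """

    def __init__(self, learner_specs, n_inner: int = 9, seed: int = 0):
        self.learner_specs = list(learner_specs)
        self.n_inner = n_inner
        self.seed = seed

    def fit(self, long: LongitudinalDataset, surv: SurvivalTable,
            cfg: LandmarkConfig, marker_specs: dict):
        plan = CVPlan(n_outer=self.n_inner, n_inner=2, n_reps=1, seed=self.seed)
        inner = run_nested_cv(long, surv, cfg, marker_specs,
                              self.learner_specs, plan)[0]
        P = inner["predictions"].to_numpy()
        self.weights_ = optimize_weights(P, inner["time"], inner["event"],
                                         cfg.t_horizon)
        self.cv_brier_ = brier_ipcw(P @ self.weights_, inner["time"],
                                    inner["event"], cfg.t_horizon)
        self.member_cv_brier_ = {
            s.method: brier_ipcw(P[:, j], inner["time"], inner["event"],
                                 cfg.t_horizon)
            for j, s in enumerate(self.learner_specs)}
        self.marker_models_ = fit_all_markers(long, marker_specs)
        ld = build_summary_matrix(self.marker_models_, long, surv, cfg)
        self.members_ = [make_learner(s).fit_landmark(ld)
                         for s in self.learner_specs]
        self.config_ = cfg
        return self

    def fit_weights_only(self, member_predictions, times, events, t_hor):
        """Weight estimation from precomputed out-of-fold predictions (used
        when members are fitted and cross-validated externally)."""
        self.weights_ = optimize_weights(member_predictions, times, events,
                                         t_hor)
        return self

    def predict_probability(self, features: pd.DataFrame, t_hor=None) -> np.ndarray:
        t_hor = t_hor if t_hor is not None else self.config_.t_horizon
        member = np.column_stack([
            m.predict_probability(features, t_hor) for m in self.members_])
        return member @ self.weights_

    @staticmethod
    def blend(member_predictions, weights) -> np.ndarray:
        """Weighted mean of member predictions (the stacking rule)."""
        P = np.asarray(member_predictions, dtype=float)
        return P @ np.asarray(weights, dtype=float)
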