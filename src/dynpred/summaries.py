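"""Per-marker mixed models and trajectory summaries.

Step one of the landmark pipeline fits one generalized mixed model per marker
on the history up to the landmark time; step two condenses each subject's
fitted trajectory into a small vector of summaries:

* the predicted random effects ``b_hat`` (the subject's deviation from the
  population trajectory),
* the error-free level ``Y*(t_LM)`` and slope ``dY*/dt (t_LM)`` at landmark,
* the cumulative error-free level over a trailing window.

For binary markers all summaries live on the linear-predictor (logit) scale,
so they can feed linear survival predictors directly. The concatenation over
markers plus the baseline covariates forms the feature matrix handed to the
survival learners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import glmm, lmm
from .basis import PolynomialBasis, TimeBasis
from .data import (LandmarkConfig, LandmarkDataset, LongitudinalDataset,
                   SurvivalTable, apply_landmark)

__all__ = [
    "MarkerModel",
    "fit_marker_model",
    "rank_inverse_normal",
    "build_summary_matrix",
    "summary_names",
]


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform for skewed continuous
    markers: maps value ranks to standard-normal quantiles."""
    values = np.asarray(values, dtype=float)
    ranks = pd.Series(values).rank(method="average").to_numpy()
    return norm.ppf((ranks - offset) / (len(values) - 2 * offset + 1))


def normalize_markers(long: LongitudinalDataset, markers) -> LongitudinalDataset:
    """Pre-transform: replace the listed continuous markers' values by their
    rank-based inverse-normal transform (computed over all measurements of
    the marker). Applied once before model fitting so fitted models and
    downstream summaries see the same scale."""
    f = long.frame.copy()
    for m in markers:
        sel = f["marker"] == m
        f.loc[sel, "value"] = rank_inverse_normal(f.loc[sel, "value"].to_numpy())
    return LongitudinalDataset(f, families=dict(long.families))


@dataclass
class MarkerModel:
    """A fitted generalized mixed model for one marker."""

    marker: str
    family: str                      # "gaussian" | "binary"
    fixed_basis: TimeBasis
    random_basis: TimeBasis
    beta: np.ndarray
    cov_re: np.ndarray
    sigma: float | None              # residual SD, gaussian only
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        B = self.cov_re
        if not np.allclose(B, B.T, atol=1e-8):
            raise ValueError("random-effect covariance must be symmetric")
        if np.linalg.eigvalsh(B).min() < -1e-8:
            raise ValueError("random-effect covariance must be PSD")
        if self.family == "gaussian" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("gaussian family requires sigma > 0")

    @property
    def q(self) -> int:
        return self.cov_re.shape[0]

    # -- individual prediction ------------------------------------------------

    def predict_random_effects(self, times, values) -> np.ndarray:
        """Predicted random effects from one subject's history (BLUP for
        gaussian markers, posterior mode for binary ones); the empty history
        returns the prior mean 0."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size == 0:
            return np.zeros(self.q)
        X = self.fixed_basis.design(times)
        Z = self.random_basis.design(times)
        if self.family == "gaussian":
            fit = lmm.LMMFit(self.beta, self.cov_re, self.sigma, np.nan, True, 0, 0)
            return lmm.blup(fit, values, X, Z)
        gfit = glmm.GLMMFit(self.beta, float(np.sqrt(self.cov_re[0, 0])),
                            np.nan, True, 0, 0)
        return glmm.posterior_mode(gfit, values, X)

    def error_free_level(self, b, u, t_max=None) -> float:
        """Linear-predictor-scale trajectory value at time ``u``."""
        if t_max is not None and u > t_max + 1e-9:
            raise ValueError(f"u={u} beyond supported history (t <= {t_max})")
        x = self.fixed_basis.design([u])[0]
        z = self.random_basis.design([u])[0]
        return float(x @ self.beta + z @ np.asarray(b))

    def error_free_slope(self, b, u) -> float:
        """Analytic time derivative of the error-free trajectory at ``u``."""
        x = self.fixed_basis.deriv([u])[0]
        z = self.random_basis.deriv([u])[0]
        return float(x @ self.beta + z @ np.asarray(b))

    def cumulative_level(self, b, t_landmark, window) -> float:
        """Exact integral of the error-free trajectory over
        ``[t_landmark - window, t_landmark]``."""
        if window <= 0:
            raise ValueError("window must be > 0")
        a = t_landmark - window
        ix = self.fixed_basis.integral(a, t_landmark)
        iz = self.random_basis.integral(a, t_landmark)
        return float(ix @ self.beta + iz @ np.asarray(b))

    def summary_vector(self, times, values, t_landmark, window) -> np.ndarray:
        b = self.predict_random_effects(times, values)
        return np.concatenate([
            b,
            [self.error_free_level(b, t_landmark),
             self.error_free_slope(b, t_landmark),
             self.cumulative_level(b, t_landmark, window)],
        ])


def summary_names(marker: str, q: int) -> list:
    return [f"{marker}.b{j + 1}" for j in range(q)] + [
        f"{marker}.level", f"{marker}.slope", f"{marker}.cumul"]


def fit_marker_model(long: LongitudinalDataset, marker: str,
                     family: str | None = None,
                     fixed_basis: TimeBasis | None = None,
                     random_basis: TimeBasis | None = None) -> MarkerModel:
    """Fit a generalized mixed model to one marker's history.

    Gaussian markers use the profiled-ML linear mixed model; binary markers a
    logistic random-intercept model by adaptive Gauss-Hermite quadrature.
    Skewed continuous markers should be pre-transformed with
    :func:`normalize_markers`. Default bases are linear in time for both
    fixed and random parts.
    """
    family = family or long.family(marker)
    fixed_basis = fixed_basis or PolynomialBasis(1)
    random_basis = random_basis or PolynomialBasis(1)
    f = long.frame
    sub = f[f["marker"] == marker]
    if len(sub) == 0:
        raise ValueError(f"no measurements for marker {marker!r}")
    y = sub["value"].to_numpy(dtype=float)
    t = sub["time"].to_numpy(dtype=float)
    groups = sub["id"].to_numpy()
    X = fixed_basis.design(t)
    Z = random_basis.design(t)
    if family == "gaussian":
        fit = lmm.fit_lmm(y, X, Z, groups)
        return MarkerModel(marker, "gaussian", fixed_basis, random_basis,
                           fit.beta, fit.cov_re, fit.sigma,
                           loglik=fit.loglik, converged=fit.converged)
    if family == "binary":
        if random_basis.n_terms != 1:
            raise NotImplementedError(
                "binary markers support a random intercept only")
        gfit = glmm.fit_logistic_glmm(y, X, groups)
        return MarkerModel(marker, "binary", fixed_basis, random_basis,
                           gfit.beta, gfit.cov_re, None,
                           loglik=gfit.loglik, converged=gfit.converged)
    raise ValueError(f"unknown family {family!r}")


def _gaussian_blups_batched(model: MarkerModel, sub: pd.DataFrame, subjects):
    """BLUPs for many subjects at once, batched by visit count."""
    q = model.q
    out = {sid: np.zeros(q) for sid in subjects}
    if len(sub) == 0:
        return out
    grouped = sub.groupby("id", sort=False)
    by_ni: dict = {}
    for sid, g in grouped:
        by_ni.setdefault(len(g), []).append((sid, g))
    for ni, items in by_ni.items():
        t = np.stack([g["time"].to_numpy(dtype=float) for _, g in items])
        yv = np.stack([g["value"].to_numpy(dtype=float) for _, g in items])
        flat = t.ravel()
        X = model.fixed_basis.design(flat).reshape(len(items), ni, -1)
        Z = model.random_basis.design(flat).reshape(len(items), ni, -1)
        V = Z @ model.cov_re @ np.swapaxes(Z, 1, 2) \
            + model.sigma ** 2 * np.eye(ni)
        resid = yv - X @ model.beta
        sol = np.linalg.solve(V, resid[:, :, None])[:, :, 0]
        b = np.einsum("ab,mib,mi->ma", model.cov_re, Z, sol)
        for (sid, _), bi in zip(items, b):
            out[sid] = bi
    return out


def build_summary_matrix(models: dict, long: LongitudinalDataset,
                         surv: SurvivalTable, cfg: LandmarkConfig) -> LandmarkDataset:
    """Assemble the landmark feature matrix: per at-risk subject the
    concatenated marker summaries followed by the baseline covariates.

    ``models`` maps marker name -> fitted :class:`MarkerModel`. Landmark
    truncation is applied first (idempotent), so histories after ``t_LM``
    never leak into the summaries. Subjects with no measurements for a marker
    get the prior-mean random effects (zero), i.e. population summaries.
    """
    trunc, at_risk = apply_landmark(long, surv, cfg)
    window = cfg.cumulative_window
    if window is None:
        tmin = trunc.frame["time"].min() if len(trunc.frame) else 0.0
        window = max(cfg.t_landmark - float(tmin), 1e-6)
    subjects = at_risk.frame["id"].tolist()
    t_lm = cfg.t_landmark

    cols = {}
    col_order = []
    for marker, model in models.items():
        sub = trunc.frame[trunc.frame["marker"] == marker]
        if model.family == "gaussian":
            bmap = _gaussian_blups_batched(model, sub, subjects)
        else:
            bmap = {}
            grouped = dict(tuple(sub.groupby("id", sort=False)))
            for sid in subjects:
                g = grouped.get(sid)
                if g is None:
                    bmap[sid] = np.zeros(model.q)
                else:
                    bmap[sid] = model.predict_random_effects(
                        g["time"].to_numpy(), g["value"].to_numpy())
        bmat = np.stack([bmap[sid] for sid in subjects])        # (N, q)
        x_lm = model.fixed_basis.design([t_lm])[0]
        z_lm = model.random_basis.design([t_lm])[0]
        xd = model.fixed_basis.deriv([t_lm])[0]
        zd = model.random_basis.deriv([t_lm])[0]
        ix = model.fixed_basis.integral(t_lm - window, t_lm)
        iz = model.random_basis.integral(t_lm - window, t_lm)
        level = x_lm @ model.beta + bmat @ z_lm
        slope = xd @ model.beta + bmat @ zd
        cumul = ix @ model.beta + bmat @ iz
        names = summary_names(marker, model.q)
        block = np.column_stack([bmat, level, slope, cumul])
        if not np.isfinite(block).all():
            bad = subjects[int(np.argwhere(~np.isfinite(block))[0][0])]
            raise ValueError(
                f"non-finite summary for subject {bad!r}, marker {marker!r}")
        for j, name in enumerate(names):
            cols[name] = block[:, j]
            col_order.append(name)

    summary_cols = list(col_order)
    covariate_cols = at_risk.covariates.copy()
    covariate_cols = [c for c in covariate_cols if c != "event_orig"]
    features = pd.DataFrame(cols, index=pd.Index(subjects, name="id"))
    for c in covariate_cols:
        features[c] = at_risk.frame.set_index("id").loc[subjects, c].to_numpy()

    return LandmarkDataset(
        features=features,
        time=at_risk.frame["time"].to_numpy(dtype=float) - t_lm,
        event=at_risk.frame["event"].to_numpy(dtype=int),
        config=cfg,
        summary_columns=summary_cols,
        covariate_columns=covariate_cols,
    )
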