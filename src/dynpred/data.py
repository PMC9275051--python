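"""Data model for landmark dynamic prediction.

Longitudinal marker measurements live in long format (subject, time, marker,
value); survival information is one row per subject with a right-censored
observed time, an event indicator and baseline covariates. The landmark
operation restricts both to the subjects still event-free at the landmark
time ``t_LM`` and to measurements taken no later than ``t_LM``, and recodes
the event indicator to the prediction window ``(t_LM, t_LM + t_Hor]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dynpred")

__all__ = [
    "LongitudinalDataset",
    "SurvivalTable",
    "LandmarkConfig",
    "LandmarkDataset",
    "SchemaError",
    "read_longitudinal",
    "read_survival",
    "apply_landmark",
]


class SchemaError(ValueError):
    """A table does not match the declared schema or violates an invariant."""


@dataclass
class LongitudinalDataset:
    """Long-format repeated marker measurements.

    ``frame`` has columns ``id``, ``time``, ``marker``, ``value``.
    ``families`` maps each marker name to ``"gaussian"`` or ``"binary"``;
    markers absent from the mapping default to gaussian.
    """

    frame: pd.DataFrame
    families: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"id", "time", "marker", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"longitudinal table missing columns: {sorted(missing)}")
        f = self.frame
        times = pd.to_numeric(f["time"], errors="coerce")
        if times.isna().any() or not np.isfinite(times).all():
            raise SchemaError("non-numeric or non-finite measurement times")
        values = pd.to_numeric(f["value"], errors="coerce")
        n_missing = int(values.isna().sum())
        if n_missing:
            logger.info("dropping %d rows with missing marker values", n_missing)
        f = f.assign(time=times, value=values).dropna(subset=["value"])
        if f.duplicated(subset=["id", "marker", "time"]).any():
            raise SchemaError("duplicate (subject, marker, time) measurements")
        for marker, fam in self.families.items():
            if fam not in ("gaussian", "binary"):
                raise SchemaError(f"unknown marker family {fam!r} for {marker!r}")
            if fam == "binary":
                vals = f.loc[f["marker"] == marker, "value"]
                if not vals.isin([0.0, 1.0]).all():
                    raise SchemaError(
                        f"binary marker {marker!r} has values outside {{0, 1}}"
                    )
        self.frame = f.reset_index(drop=True)

    @property
    def markers(self):
        return list(pd.unique(self.frame["marker"]))

    @property
    def subjects(self):
        return list(pd.unique(self.frame["id"]))

    def family(self, marker) -> str:
        return self.families.get(marker, "gaussian")

    def subject_history(self, subject, marker) -> pd.DataFrame:
        f = self.frame
        return f[(f["id"] == subject) & (f["marker"] == marker)].sort_values("time")

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


@dataclass
class SurvivalTable:
    """One row per subject: observed time, event indicator, baseline covariates.

    ``frame`` has columns ``id``, ``time``, ``event`` plus any covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"id", "time", "event"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"survival table missing columns: {sorted(missing)}")
        f = self.frame
        if f["id"].duplicated().any():
            raise SchemaError("duplicate subject ids in survival table")
        if not (pd.to_numeric(f["time"], errors="coerce") > 0).all():
            raise SchemaError("observed times must be positive and numeric")
        if not f["event"].isin([0, 1]).all():
            raise SchemaError("event indicator must be 0/1")
        self.frame = f.reset_index(drop=True)

    @property
    def covariates(self):
        return [c for c in self.frame.columns if c not in ("id", "time", "event")]

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class LandmarkConfig:
    """Landmark time, horizon (measured from the landmark) and the window
    over which the cumulative marker level is integrated, all in years."""

    t_landmark: float
    t_horizon: float
    cumulative_window: float | None = None

    def __post_init__(self):
        if self.t_landmark < 0:
            raise ValueError("t_landmark must be >= 0")
        if self.t_horizon <= 0:
            raise ValueError("t_horizon must be > 0")
        if self.cumulative_window is not None and self.cumulative_window <= 0:
            raise ValueError("cumulative_window must be > 0")

    @property
    def t_end(self) -> float:
        return self.t_landmark + self.t_horizon


@dataclass
class LandmarkDataset:
    """At-risk subjects after landmark truncation, with the summary matrix.

    ``features``: one row per at-risk subject (index = subject id), columns =
    marker summaries followed by baseline covariates. ``time`` is the observed
    time since the landmark, ``event`` the window-recoded indicator
    ``1(T < min(C, t_LM + t_Hor))``, and ``status`` the horizon survival
    status ``D(t_LM, t_Hor)`` in {0, 1} or NaN when censored before horizon.
    """

    features: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    config: LandmarkConfig
    summary_columns: list = field(default_factory=list)
    covariate_columns: list = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValueError("times since landmark must be positive (at-risk only)")

    def __len__(self):
        return len(self.features)

    @property
    def status(self) -> np.ndarray:
        """Horizon status D: 1 event in window, 0 survived past horizon,
        NaN censored before the horizon."""
        d = np.full(len(self), np.nan)
        d[self.event == 1] = 1.0
        d[self.time > self.config.t_horizon - 1e-12] = 0.0
        return d

    def subset(self, idx) -> "LandmarkDataset":
        idx = np.asarray(idx)
        return LandmarkDataset(
            features=self.features.iloc[idx],
            time=self.time[idx],
            event=self.event[idx],
            config=self.config,
            summary_columns=list(self.summary_columns),
            covariate_columns=list(self.covariate_columns),
        )


def read_longitudinal(path, families: dict | None = None,
                      id_col="id", time_col="time",
                      marker_col="marker", value_col="value") -> LongitudinalDataset:
    """Read a longitudinal CSV, in long or wide layout.

    Long layout has columns ``id,time,marker,value``; wide layout has
    ``id,time,<marker1>,...,<markerK>`` and is melted to long form. Missing
    values (empty or NA) are dropped with a logged count.
    """
    df = pd.read_csv(path, na_values=["NA", ""])
    cols = set(df.columns)
    if id_col not in cols or time_col not in cols:
        raise SchemaError(f"longitudinal file must have {id_col!r} and {time_col!r} columns")
    if marker_col in cols and value_col in cols:
        long = df[[id_col, time_col, marker_col, value_col]].rename(
            columns={id_col: "id", time_col: "time",
                     marker_col: "marker", value_col: "value"})
    else:  # wide
        markers = [c for c in df.columns if c not in (id_col, time_col)]
        if not markers:
            raise SchemaError("wide longitudinal file has no marker columns")
        long = df.melt(id_vars=[id_col, time_col], value_vars=markers,
                       var_name="marker", value_name="value").rename(
            columns={id_col: "id", time_col: "time"})
    if not np.issubdtype(pd.to_numeric(long["time"], errors="coerce").dtype, np.number) \
            or pd.to_numeric(long["time"], errors="coerce").isna().any():
        raise SchemaError("non-numeric measurement time")
    return LongitudinalDataset(long, families=families or {})


def read_survival(path, id_col="id", time_col="time", event_col="event") -> SurvivalTable:
    """Read a one-row-per-subject survival CSV with baseline covariates."""
    df = pd.read_csv(path, na_values=["NA", ""])
    for c in (id_col, time_col, event_col):
        if c not in df.columns:
            raise SchemaError(f"survival file missing column {c!r}")
    df = df.rename(columns={id_col: "id", time_col: "time", event_col: "event"})
    return SurvivalTable(df)


def apply_landmark(long: LongitudinalDataset, surv: SurvivalTable,
                   cfg: LandmarkConfig):
    """Landmark truncation.

    Keeps subjects strictly at risk at ``t_LM`` (``T* > t_LM``), drops
    measurements after ``t_LM``, and recodes the event indicator to
    ``1(event and T* < t_LM + t_Hor)``. Returns the truncated longitudinal
    dataset and the at-risk survival table (event column recoded, original
    kept as ``event_orig``).
    """
    sf = surv.frame
    at_risk = sf[sf["time"] > cfg.t_landmark].copy()
    if len(at_risk) == 0:
        raise ValueError(f"no subjects at risk at landmark t={cfg.t_landmark}")
    ids = set(at_risk["id"])
    lf = long.frame
    keep = lf["id"].isin(ids) & (lf["time"] <= cfg.t_landmark + 1e-12)
    truncated = LongitudinalDataset(lf[keep].copy(), families=dict(long.families))

    if "event_orig" not in at_risk.columns:
        at_risk["event_orig"] = at_risk["event"]
    at_risk["event"] = (
        (at_risk["event_orig"] == 1) & (at_risk["time"] < cfg.t_end)
    ).astype(int)
    return truncated, SurvivalTable(at_risk)
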