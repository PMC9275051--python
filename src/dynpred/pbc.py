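"""Primary biliary cholangitis (PBC) application.

The classic Mayo PBC trial follow-up data (312 protocol patients, repeated
labs and exams, death as the event with transplantation treated as
censoring) ship with R's ``survival`` package as ``pbcseq``; the widely
used ``pbc2`` table of the joint-modelling packages is the same data with
days converted to years and death recoded. :func:`load_pbc2` rebuilds that
table at run time through ``Rscript`` — no data file is bundled.

Eleven repeated markers are used: 7 continuous (serum bilirubin, serum
cholesterol, albumin, alkaline phosphatase, SGOT/AST, platelets,
prothrombin time) and 4 binary (ascites, hepatomegaly, spiders, any
edema), plus three baseline covariates (age at entry, sex, treatment arm).
The landmark analysis predicts death within 3 years for the patients still
alive 4 years after enrollment.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import NaturalSplineBasis, PolynomialBasis
from .data import LandmarkConfig, LongitudinalDataset, SurvivalTable

__all__ = ["load_pbc2", "pbc_marker_specs", "baseline_feature_matrix",
           "PBC_CONFIG", "CONTINUOUS_MARKERS", "BINARY_MARKERS",
           "BASELINE_COVARIATES"]

PBC_CONFIG = LandmarkConfig(t_landmark=4.0, t_horizon=3.0, cumulative_window=4.0)

CONTINUOUS_MARKERS = ("serBilir", "serChol", "albumin", "alkaline",
                      "SGOT", "platelets", "prothrombin")
BINARY_MARKERS = ("ascites", "hepatomegaly", "spiders", "edema")
BASELINE_COVARIATES = ("age", "sex", "drug")

_RENAME = {"bili": "serBilir", "chol": "serChol", "alk.phos": "alkaline",
           "ast": "SGOT", "platelet": "platelets", "protime": "prothrombin",
           "hepato": "hepatomegaly"}

_R_EXPORT = """
library(survival)
d <- pbcseq
write.csv(d, file = commandArgs(trailingOnly = TRUE)[1], row.names = FALSE)
"""


def _export_pbcseq() -> pd.DataFrame:
    if shutil.which("Rscript") is None:
        raise RuntimeError(
            "Rscript not found: the PBC data are rebuilt from R's survival "
            "package at run time")
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "pbcseq.csv"
        script = Path(tmp) / "export.R"
        script.write_text(_R_EXPORT)
        subprocess.run(["Rscript", str(script), str(out)], check=True,
                       capture_output=True)
        return pd.read_csv(out)


def load_pbc2():
    """Rebuild the pbc2-style tables.

    Returns ``(LongitudinalDataset, SurvivalTable)``: long-format marker
    measurements in years since enrollment, and one row per subject with
    observed years, death indicator (transplant = censored) and the three
    baseline covariates (age in years, sex 1 = female, drug 1 =
    D-penicillamine).
    """
    raw = _export_pbcseq()
    raw["years"] = raw["day"] / 365.25

    base = raw.drop_duplicates("id", keep="first")
    surv = pd.DataFrame({
        "id": base["id"],
        "time": base["futime"] / 365.25,
        "event": (base["status"] == 2).astype(int),
        "age": base["age"],
        "sex": (base["sex"] == "f").astype(int),
        "drug": (base["trt"] == 1).astype(int),
    })

    frames = []
    for raw_name, name in [("bili", "serBilir"), ("chol", "serChol"),
                           ("albumin", "albumin"), ("alk.phos", "alkaline"),
                           ("ast", "SGOT"), ("platelet", "platelets"),
                           ("protime", "prothrombin"), ("ascites", "ascites"),
                           ("hepato", "hepatomegaly"), ("spiders", "spiders"),
                           ("edema", "edema")]:
        v = raw[raw_name]
        if name == "edema":  # 0 / 0.5 / 1 coding -> any edema
            v = (v > 0).astype(float)
        frames.append(pd.DataFrame({"id": raw["id"], "time": raw["years"],
                                    "marker": name, "value": v}))
    long = pd.concat(frames, ignore_index=True)
    families = {m: "gaussian" for m in CONTINUOUS_MARKERS}
    families.update({m: "binary" for m in BINARY_MARKERS})
    return LongitudinalDataset(long, families=families), SurvivalTable(surv)


def baseline_feature_matrix(long: LongitudinalDataset, surv,
                            cfg: LandmarkConfig = PBC_CONFIG):
    """Landmark dataset whose features are only the enrollment (first
    measured) value of each marker plus the baseline covariates — the
    comparison tool that ignores the post-baseline marker history.

    Missing baseline values (e.g. cholesterol) are imputed with the marker's
    at-risk sample mean.
    """
    from .data import apply_landmark
    from .data import LandmarkDataset

    trunc, at_risk = apply_landmark(long, surv, cfg)
    subjects = at_risk.frame["id"].tolist()
    f = trunc.frame.sort_values("time")
    first = f.groupby(["id", "marker"], sort=False).first().reset_index()
    wide = first.pivot(index="id", columns="marker", values="value")
    wide = wide.reindex(subjects)
    wide = wide.fillna(wide.mean())
    wide.columns = [f"{c}.baseline" for c in wide.columns]
    covars = [c for c in at_risk.covariates if c != "event_orig"]
    features = wide.join(at_risk.frame.set_index("id")[covars])
    return LandmarkDataset(
        features=features,
        time=at_risk.frame["time"].to_numpy(dtype=float) - cfg.t_landmark,
        event=at_risk.frame["event"].to_numpy(dtype=int),
        config=cfg,
        summary_columns=list(wide.columns),
        covariate_columns=covars,
    )


def pbc_marker_specs(long: LongitudinalDataset,
                     markers=None,
                     t_landmark: float = 4.0,
                     splines: bool = True) -> dict:
    """fit_marker_model settings for the PBC markers.

    Continuous markers (pre-transform them with
    :func:`dynpred.summaries.normalize_markers` first): natural cubic spline
    of time (one interior knot at the median observed visit time) for the
    fixed part, random intercept + slope. Binary markers: linear fixed part
    on the logit scale, random intercept.
    """
    markers = markers or (CONTINUOUS_MARKERS + BINARY_MARKERS)
    specs = {}
    f = long.frame
    for m in markers:
        times = f.loc[f["marker"] == m, "time"].to_numpy()
        if m in CONTINUOUS_MARKERS:
            if splines and np.unique(np.quantile(times, [0, .5, 1])).size == 3:
                fixed = NaturalSplineBasis.from_quantiles(times, 1)
            else:
                fixed = PolynomialBasis(1, center=t_landmark)
            specs[m] = {"family": "gaussian", "fixed_basis": fixed,
                        "random_basis": PolynomialBasis(1, center=t_landmark)}
        else:
            specs[m] = {"family": "binary",
                        "fixed_basis": PolynomialBasis(1, center=t_landmark),
                        "random_basis": PolynomialBasis(0)}
    return specs
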