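"""Age-expected biomarker values, residuals and classifier feature sets.

For every subject-visit the expected value of each retained ROI is the
subject's intercept extrapolated along the null model's fixed effects,

    yhat_ijr = y0_ir + beta_a_r * age_ij + beta_e_r * educ_i,

and the residual is the deviation of the observation from it,
e_ijr = y_ijr - yhat_ijr. For a healthy subject the residuals scatter
around zero; disease shows up as a systematic (negative) deviation in the
affected variant ROIs. Residuals for all ROIs form the matrix E; the
retained submatrix E_v keeps every variant column plus any quasi-variant
column that is not identically zero (qvr residuals vanish exactly for
subjects whose intercept was estimated from a single visit).

Feature sets for classification: F1 = E_v columns + age; F2 = F1 + CDR
global score + MMSE.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .null_model import LMEFit, RoiClassification

__all__ = [
    "predict_expected",
    "compute_residuals",
    "build_Ev",
    "assemble_features",
    "METADATA_KEEP",
    "coarse_class",
]

log = logging.getLogger(__name__)

#: observation metadata carried alongside residual rows
METADATA_KEEP = ["subject_id", "gender", "visit_month", "age_years",
                 "dx_age", "mmse", "cdr_global"]

_COARSE_AGE = {"NL": "HC", "MCI": "MCI", "Dementia": "AD"}
_COARSE_LAST = {"sHC": "HC", "sMCI": "MCI", "cMCI": "MCI", "sAD": "AD", "cAD": "AD"}


def coarse_class(label: str) -> str:
    """Map a per-visit diagnosis or a trajectory class to HC/MCI/AD."""
    if label in _COARSE_AGE:
        return _COARSE_AGE[label]
    return _COARSE_LAST[label]


def predict_expected(y0: pd.DataFrame, cohort: pd.DataFrame,
                     fits: dict[str, LMEFit]) -> pd.DataFrame:
    """Expected ROI values per observation row of ``cohort``.

    ``y0`` is a subject x ROI intercept table (qvr estimated from the
    subject's own data, vr inferred through the PLSR map). Rows of subjects
    without an intercept get missing cells.
    """
    rois = [r for r in y0.columns if r in fits]
    age = cohort["age_years"].to_numpy(float)
    educ = cohort["educ_years"].to_numpy(float)
    y0_rows = y0.reindex(cohort["subject_id"])
    out = {}
    for roi in rois:
        fit = fits[roi]
        out[roi] = y0_rows[roi].to_numpy(float) + fit.beta_age * age + fit.beta_educ * educ
    expected = pd.DataFrame(out, index=cohort.index)
    return expected


def compute_residuals(observed: pd.DataFrame, expected: pd.DataFrame,
                      metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Elementwise observed - expected; missing in either side stays missing.

    Returns the residual matrix E with metadata columns prepended when given.
    """
    if observed.shape != expected.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs expected {expected.shape}")
    E = observed[expected.columns] - expected
    if metadata is not None:
        E = pd.concat([metadata.reset_index(drop=True),
                       E.reset_index(drop=True)], axis=1)
    return E


def build_Ev(E: pd.DataFrame, classifications: list[RoiClassification],
             tol: float = 1e-12) -> pd.DataFrame:
    """Retained residual submatrix E_v.

    Keeps every variant column; keeps a quasi-variant column only if some
    residual exceeds ``tol`` in magnitude; drops excluded-ROI columns.
    """
    labels = {c.roi_id: c.label for c in classifications}
    keep: list[str] = []
    for col in E.columns:
        lab = labels.get(col)
        if lab == "vr":
            keep.append(col)
        elif lab == "qvr":
            vals = E[col].to_numpy(float)
            if np.nanmax(np.abs(vals), initial=0.0) > tol:
                keep.append(col)
    meta = [c for c in E.columns if c not in labels]
    return E[meta + keep]


def assemble_features(Ev: pd.DataFrame, labels: pd.DataFrame,
                      variant: str = "F1", label_mode: str = "current") -> pd.DataFrame:
    """Build a classification table: one row per observation.

    ``Ev`` must carry the metadata columns of :data:`METADATA_KEEP`.
    ``variant`` 'F1' adds age to the residual columns; 'F2' additionally adds
    CDRGLOBAL and MMSE (rows lacking them are dropped, logged).
    ``label_mode`` 'current' labels rows with the coarse class of the visit
    diagnosis dx_age; 'last' labels every row of a subject with the coarse
    class of their trajectory label dx_last, so a converter's pre-conversion
    visits carry their *future* class.

    Returns a DataFrame with columns: subject_id, age_years, dx_age, label,
    and the feature columns (residuals + age [+ cdr_global, mmse]).
    """
    if variant not in ("F1", "F2"):
        raise ValueError(f"unknown feature variant {variant!r}")
    if label_mode not in ("current", "last"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    resid_cols = [c for c in Ev.columns if c not in METADATA_KEEP]
    df = Ev.copy()
    if label_mode == "current":
        df["label"] = df["dx_age"].map(coarse_class)
    else:
        dx_last = labels["dx_last"].reindex(df["subject_id"]).to_numpy()
        if pd.isna(dx_last).any():
            raise ValueError("dx_last missing for some subjects in Ev")
        df["label"] = [coarse_class(v) for v in dx_last]
    feature_cols = resid_cols + ["age_years"]
    cols = ["subject_id", "age_years", "dx_age", "label"] + resid_cols
    if variant == "F2":
        feature_cols = feature_cols + ["cdr_global", "mmse"]
        cols = cols + ["cdr_global", "mmse"]
        n_before = len(df)
        df = df.dropna(subset=["cdr_global", "mmse"])
        if len(df) < n_before:
            log.warning("dropped %d rows lacking MMSE/CDR for F2", n_before - len(df))
    df = df.dropna(subset=resid_cols)
    out = df[cols].copy()
    out.attrs["feature_cols"] = feature_cols
    out.attrs["variant"] = variant
    out.attrs["label_mode"] = label_mode
    return out.reset_index(drop=True)
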