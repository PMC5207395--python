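"""Normative ("null") model of healthy brain aging.

On the null cohort (stable, CSF-normal controls) each regional biomarker is
standardized to zero mean and unit variance over the pooled observations and
then modelled with a random-intercept linear mixed-effects model

    y_ijr = beta1_r + beta_a_r * age_ij + beta_e_r * educ_i + u_ir + eps_ijr,

with u_ir ~ N(0, psi_r) the subject-specific intercept deviation and
eps ~ N(0, sigma2_r) i.i.d. within subject. Age enters raw in years so the
intercept is literally the age-0 extrapolation y0.

ROIs are then split by the fitted annual change: *variant* (vr) if
|beta_a| exceeds 1% of the ROI's SD per year AND the Wald p-value is <= 0.05;
*quasi-variant* (qvr) if |beta_a| <= 1%/year. ROIs with a large but
non-significant slope satisfy neither definition and are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_cohort import ROI_PREFIX

__all__ = [
    "StandardizationParams",
    "LMEFit",
    "RoiClassification",
    "fit_standardization",
    "apply_standardization",
    "fit_lme",
    "fit_all_rois",
    "classify_rois",
    "extract_intercepts",
    "VR_THRESHOLD",
    "ALPHA",
]

log = logging.getLogger(__name__)

#: |beta_a| boundary, SD units / year (1% of the ROI's SD per year)
VR_THRESHOLD = 0.01
ALPHA = 0.05


@dataclass
class StandardizationParams:
    """Per-ROI pooled mean/SD from the null cohort; constant ROIs dropped."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def rois(self) -> list[str]:
        return list(self.mean.index)


def roi_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(ROI_PREFIX)]


def fit_standardization(null_cohort: pd.DataFrame) -> StandardizationParams:
    """Pooled mean and sample SD per ROI over all null-cohort observations."""
    cols = roi_columns(null_cohort)
    if len(null_cohort) == 0 or not cols:
        raise ValueError("null cohort is empty or has no ROI columns")
    mean = null_cohort[cols].mean()
    sd = null_cohort[cols].std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    for roi in dropped:
        log.warning("ROI %s has zero variance on the null cohort; dropped", roi)
    keep = [c for c in cols if c not in dropped]
    return StandardizationParams(mean=mean[keep], sd=sd[keep], dropped=dropped)


def apply_standardization(cohort: pd.DataFrame,
                          params: StandardizationParams) -> pd.DataFrame:
    """Standardize a cohort's ROI block with the *null-cohort* mean/SD.

    New cohorts are always scaled with the null cohort's constants, never
    their own, so deviations from healthy aging survive the transform.
    """
    out = cohort.drop(columns=params.dropped, errors="ignore").copy()
    out[params.rois] = (cohort[params.rois] - params.mean) / params.sd
    return out


@dataclass
class LMEFit:
    """One ROI's random-intercept fit on the (standardized) null cohort."""

    roi_id: str
    beta_intercept: float
    beta_age: float
    beta_educ: float
    psi: float                     # random-intercept variance
    sigma2: float                  # residual variance
    se_age: float
    p_age: float
    intercepts: pd.Series          # y0_ir = beta1 + BLUP(u_ir) per subject
    n_subjects: int
    n_observations: int
    converged: bool = True

    @property
    def fixed_effects(self) -> np.ndarray:
        return np.array([self.beta_intercept, self.beta_age, self.beta_educ])


def fit_lme(data: pd.DataFrame, roi: str) -> LMEFit:
    """REML random-intercept fit of one ROI.

    ``data`` needs columns ``subject_id``, ``age_years``, ``educ_years`` and
    the ROI column; rows with a missing ROI value are ignored, so unbalanced
    visit schedules are handled naturally.
    """
    d = data[["subject_id", "age_years", "educ_years", roi]].dropna(subset=[roi])
    # inclusion rule: a ROI must be observed at >= 2 distinct times overall
    if d["age_years"].nunique() < 2 or d["subject_id"].nunique() < 2:
        raise ValueError(f"ROI {roi}: insufficient data for a mixed model")
    exog = sm.add_constant(d[["age_years", "educ_years"]])
    model = sm.MixedLM(d[roi], exog, groups=d["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    converged = bool(getattr(res, "converged", True))
    beta1, beta_a, beta_e = (float(res.params["const"]),
                             float(res.params["age_years"]),
                             float(res.params["educ_years"]))
    se_a = float(res.bse["age_years"])
    # Wald z-test against the standard normal
    p_a = float(2.0 * stats.norm.sf(abs(beta_a / se_a))) if se_a > 0 else np.nan
    blups = pd.Series({g: float(re.iloc[0]) for g, re in res.random_effects.items()})
    intercepts = (beta1 + blups).sort_index()
    intercepts.name = roi
    return LMEFit(
        roi_id=roi, beta_intercept=beta1, beta_age=beta_a, beta_educ=beta_e,
        psi=float(res.cov_re.iloc[0, 0]), sigma2=float(res.scale),
        se_age=se_a, p_age=p_a, intercepts=intercepts,
        n_subjects=int(d["subject_id"].nunique()), n_observations=len(d),
        converged=converged,
    )


def fit_all_rois(std_null_cohort: pd.DataFrame,
                 rois: list[str] | None = None) -> dict[str, LMEFit]:
    """Fit every ROI; non-convergent or degenerate fits are dropped with a
    warning (they enter neither the vr nor the qvr set)."""
    rois = rois if rois is not None else roi_columns(std_null_cohort)
    fits: dict[str, LMEFit] = {}
    for roi in rois:
        try:
            fit = fit_lme(std_null_cohort, roi)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("ROI %s: fit failed (%s); excluded", roi, exc)
            continue
        if not fit.converged:
            log.warning("ROI %s: mixed model did not converge; excluded", roi)
            continue
        fits[roi] = fit
    return fits


@dataclass(frozen=True)
class RoiClassification:
    roi_id: str
    label: str      # 'vr' | 'qvr' | 'excluded'
    beta_age: float
    p_value: float


def classify_rois(fits: dict[str, LMEFit], threshold: float = VR_THRESHOLD,
                  alpha: float = ALPHA) -> list[RoiClassification]:
    """vr iff |beta_a| > threshold and p <= alpha; qvr iff |beta_a| <=
    threshold; the gap case (large but non-significant slope) is excluded."""
    out = []
    for roi, fit in fits.items():
        if abs(fit.beta_age) > threshold and fit.p_age <= alpha:
            label = "vr"
        elif abs(fit.beta_age) <= threshold:
            label = "qvr"
        else:
            label = "excluded"
            log.warning("ROI %s: |beta_a|=%.4g > %.3g but p=%.3g > %.3g; "
                        "excluded from both sets", roi, abs(fit.beta_age),
                        threshold, fit.p_age, alpha)
        out.append(RoiClassification(roi_id=roi, label=label,
                                     beta_age=fit.beta_age, p_value=fit.p_age))
    return out


def extract_intercepts(fits: dict[str, LMEFit],
                       rois: list[str] | None = None) -> pd.DataFrame:
    """Subject x ROI table of y0 = fixed intercept + predicted random effect.

    A subject absent from some ROI's fit yields a missing cell (flagged).
    """
    rois = rois if rois is not None else list(fits)
    table = pd.DataFrame({roi: fits[roi].intercepts for roi in rois})
    table.index.name = "subject_id"
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        log.warning("intercept table has %d missing cells", n_missing)
    return table.sort_index()
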