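"""Time-invariant diagnosis variables and the CSF normal/abnormal profile.

From each subject's visit history this module derives:

* ``dx_last`` — the longitudinal trajectory class: stable healthy control
  (sHC), stable MCI (sMCI), converted to MCI (cMCI), stable AD (sAD) or
  converted to AD (cAD);
* the CSF profile — ``normal`` iff *every* available measurement satisfies
  amyloid-beta >= 192 pg/mL and total tau <= 93 pg/mL (both boundaries
  inclusive), ``abnormal`` if any measurement violates either condition,
  ``unknown`` with no measurements;
* ``dx_csf`` — the coarse class (HC/MCI/AD) crossed with the CSF profile.

The cohort is then partitioned into the null-model cohort (stable controls
with a normal CSF profile, used to fit the normative aging model) and the
early-prediction cohort (everyone else).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import DX_DEM, DX_MCI, DX_NL

__all__ = [
    "ABETA_CUTOFF",
    "TAU_CUTOFF",
    "SubjectLabel",
    "classify_csf_profile",
    "derive_dx_last",
    "derive_dx_csf",
    "label_cohort",
    "split_cohorts",
    "EmptyNullCohortError",
]

log = logging.getLogger(__name__)

#: autopsy-validated cut-offs, pg/mL
ABETA_CUTOFF = 192.0
TAU_CUTOFF = 93.0

VALID_DX = {DX_NL, DX_MCI, DX_DEM}
COARSE = {"sHC": "HC", "sMCI": "MCI", "cMCI": "MCI", "sAD": "AD", "cAD": "AD"}


class EmptyNullCohortError(RuntimeError):
    """No normal-HCcsf subjects: the null model cannot be built."""


@dataclass(frozen=True)
class SubjectLabel:
    subject_id: str
    dx_last: str
    csf_profile: str
    dx_csf: str


def classify_csf_profile(abeta: list[float], tau: list[float],
                         abeta_cutoff: float = ABETA_CUTOFF,
                         tau_cutoff: float = TAU_CUTOFF) -> str:
    """Classify a subject's CSF profile over all available measurements.

    ``abeta`` and ``tau`` are paired per-visit concentrations (pg/mL); NaNs
    are treated as unavailable measurements. A single violating visit makes
    the whole profile abnormal.
    """
    if abeta_cutoff <= 0 or tau_cutoff <= 0:
        raise ValueError("CSF cut-offs must be positive")
    ab = np.asarray(abeta, dtype=float)
    tv = np.asarray(tau, dtype=float)
    if ab.shape != tv.shape:
        raise ValueError("abeta and tau must be paired per visit")
    present = ~(np.isnan(ab) | np.isnan(tv))
    if np.any((ab[present] <= 0) | (tv[present] <= 0)):
        raise ValueError("CSF concentrations must be positive")
    if not present.any():
        return "unknown"
    ok = (ab[present] >= abeta_cutoff) & (tv[present] <= tau_cutoff)
    return "normal" if ok.all() else "abnormal"


def derive_dx_last(dx_sequence: list[str], subject_id: str = "?") -> str:
    """Trajectory class from the chronologically ordered per-visit diagnoses.

    sHC: all visits NL. cMCI: starts NL, reaches MCI, never Dementia.
    sMCI: starts MCI, never Dementia. cAD: reaches Dementia from NL or MCI.
    sAD: Dementia at every visit (including the first).
    """
    if len(dx_sequence) == 0:
        raise ValueError("empty diagnosis sequence")
    bad = set(dx_sequence) - VALID_DX
    if bad:
        raise ValueError(f"invalid diagnosis label(s) {sorted(bad)} "
                         f"for subject {subject_id}")
    seq = list(dx_sequence)
    if DX_DEM in seq:
        first_dem = seq.index(DX_DEM)
        if any(d != DX_DEM for d in seq[first_dem:]):
            log.warning("subject %s: non-Dementia visit after Dementia; "
                        "classified by presence of Dementia", subject_id)
        return "sAD" if seq[0] == DX_DEM else "cAD"
    if seq[0] == DX_NL:
        return "sHC" if all(d == DX_NL for d in seq) else "cMCI"
    return "sMCI"


def derive_dx_csf(dx_last: str, csf_profile: str) -> str:
    """Cross the coarse diagnosis class with the CSF profile."""
    if csf_profile == "unknown":
        return "unknown"
    return f"{csf_profile}-{COARSE[dx_last]}csf"


def label_cohort(cohort: pd.DataFrame,
                 abeta_cutoff: float = ABETA_CUTOFF,
                 tau_cutoff: float = TAU_CUTOFF) -> pd.DataFrame:
    """Derive per-subject labels (dx_last, csf_profile, dx_csf) from a
    long-format cohort table. Visits are sorted by month before use, so row
    order in the input is irrelevant."""
    out = []
    for sid, sub in cohort.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit_month")
        dx_last = derive_dx_last(list(sub["dx_age"]), subject_id=str(sid))
        profile = classify_csf_profile(sub["csf_abeta"].tolist(),
                                       sub["csf_tau"].tolist(),
                                       abeta_cutoff, tau_cutoff)
        out.append(dict(subject_id=sid, dx_last=dx_last, csf_profile=profile,
                        dx_csf=derive_dx_csf(dx_last, profile)))
    return pd.DataFrame(out).set_index("subject_id")


def split_cohorts(cohort: pd.DataFrame,
                  labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (null_model_cohort, early_prediction_cohort).

    The null-model cohort holds every visit of subjects labelled
    normal-HCcsf; the early-prediction cohort holds everyone else. The two
    are disjoint and their union is the input.
    """
    ids = cohort["subject_id"].unique()
    missing = set(ids) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for subjects: {sorted(missing)[:5]} ...")
    null_ids = set(labels.index[labels["dx_csf"] == "normal-HCcsf"]) & set(ids)
    if not null_ids:
        raise EmptyNullCohortError(
            "no normal-HCcsf subjects in cohort; cannot build a null model")
    in_null = cohort["subject_id"].isin(null_ids)
    return cohort[in_null].copy(), cohort[~in_null].copy()
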