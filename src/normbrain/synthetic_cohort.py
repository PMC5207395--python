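"""Synthetic ADNI-like longitudinal cohorts with known ground truth.

Generates subject-visit tables that mimic the structure of a multi-centre
Alzheimer's study: an eight-visit schedule with monotone dropout, one row per
subject-visit, demographic covariates (age, years of education), per-visit
clinical diagnosis (NL / MCI / Dementia), cognitive scores (MMSE, CDR global),
baseline CSF amyloid-beta and total-tau concentrations, and a block of
MRI-derived regional biomarkers ("ROIs").

Each ROI follows a random-intercept linear model on the standardized scale,

    y_ijr = y0_ir + beta_a^r * age_ij + beta_e^r * educ_i + eps_ijr,

where the subject intercepts are built from shared latent factors,
y0_i = L f_i + noise, so that a linear map from the slowly-changing
("quasi-variant") ROIs' intercepts to the age-varying ("variant") ROIs'
intercepts exists by construction. Diseased subjects additionally receive a
negative offset and an accelerated atrophy slope on an affected subset of the
variant ROIs, starting at their (possibly pre-clinical) biomarker onset visit.

The returned :class:`GroundTruth` carries every generative parameter so that
downstream estimation stages can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "RoiParams",
    "ConfigError",
    "SchemaError",
    "CohortParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "GROUPS",
    "GENDERS",
    "ROI_PREFIX",
    "METADATA_COLUMNS",
]

GROUPS = ("sHC", "sMCI", "cMCI", "sAD", "cAD")
GENDERS = ("F", "M")
ROI_PREFIX = "roi_"

#: mandatory non-ROI columns of the long-format cohort table
METADATA_COLUMNS = [
    "subject_id",
    "gender",
    "visit_month",
    "age_years",
    "educ_years",
    "dx_age",
    "mmse",
    "cdr_global",
    "csf_abeta",
    "csf_tau",
]

# Per-visit diagnosis labels used throughout the pipeline.
DX_NL, DX_MCI, DX_DEM = "NL", "MCI", "Dementia"


class ConfigError(ValueError):
    """A GeneratorConfig invariant is violated."""


class SchemaError(ValueError):
    """A cohort file is missing a mandatory column."""


class CohortParseError(ValueError):
    """A cohort file contains an unparseable cell."""


def _default_csf_params() -> dict:
    # Mixture of a "normal" and an "abnormal" CSF component per diagnosis
    # trajectory group. The component indicator is shared between amyloid-beta
    # and tau, which produces the bimodal Abeta distribution seen in elderly
    # cohorts. Units: pg/mL. Means/SDs chosen so that stable controls
    # predominantly satisfy the normal profile (Abeta >= 192, tau <= 93).
    hc = dict(w_normal=0.95, abeta_normal=(247.0, 20.0), abeta_abnormal=(145.0, 25.0),
              tau_normal=(55.0, 15.0), tau_abnormal=(115.0, 25.0))
    mci = dict(w_normal=0.45, abeta_normal=(235.0, 25.0), abeta_abnormal=(150.0, 30.0),
               tau_normal=(70.0, 18.0), tau_abnormal=(110.0, 30.0))
    ad = dict(w_normal=0.15, abeta_normal=(225.0, 25.0), abeta_abnormal=(140.0, 25.0),
              tau_normal=(68.0, 18.0), tau_abnormal=(125.0, 35.0))
    return {"sHC": hc, "sMCI": dict(mci), "cMCI": dict(mci),
            "sAD": dict(ad), "cAD": dict(ad)}


@dataclass
class GeneratorConfig:
    """Generative parameters for one synthetic cohort.

    All biomarker-scale quantities are in SD units of the standardized scale
    on which ROIs are generated; slopes are SD units per year of age.
    """

    #: subjects per diagnosis-trajectory group, applied to each gender
    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 40 for g in GROUPS})
    n_vr_rois: int = 15
    n_qvr_rois: int = 12
    visit_months: Sequence[int] = (0, 6, 12, 18, 24, 36, 48, 60)
    dropout_prob: float = 0.08
    #: interval for |annual slope| of variant ROIs (must stay above 0.01)
    slope_vr_range: tuple[float, float] = (0.02, 0.08)
    #: upper bound for |annual slope| of quasi-variant ROIs (<= 0.005)
    slope_qvr_max: float = 0.003
    educ_effect_range: tuple[float, float] = (0.0, 0.01)
    latent_dim: int = 3
    intercept_noise_sd: float = 0.1
    obs_noise_sd: float = 0.12
    #: additional (negative-going) intercept shift on affected ROIs, SD units
    disease_offset: float = 1.0
    #: additional atrophy slope on affected ROIs, SD units / year
    disease_slope_accel: float = 0.05
    #: MCI disease effect as a fraction of the AD effect
    mci_severity: float = 0.5
    #: number of visits by which biomarker onset precedes the clinical
    #: diagnosis change of converters (0 = onset at the conversion visit)
    biomarker_lead_visits: int = 0
    csf_params: Mapping[str, Mapping] = field(default_factory=_default_csf_params)
    #: probability that a subject has CSF measured at all (subjects without
    #: CSF have an unknown profile and always fall in the early-prediction
    #: cohort, mirroring the partial CSF coverage of real studies)
    csf_available_prob: float = 0.6
    #: when True, ROIs are exported on a per-ROI affine (non-SD) scale so the
    #: pipeline's standardization step has real work to do
    destandardize: bool = False
    seed: int = 0

    def validate(self) -> None:
        vm = list(self.visit_months)
        if len(vm) == 0 or vm[0] != 0:
            raise ConfigError("visit_months must start at 0")
        if any(b <= a for a, b in zip(vm, vm[1:])):
            raise ConfigError("visit_months must be strictly increasing")
        for g in GROUPS:
            if g not in self.n_subjects_per_group:
                raise ConfigError(f"n_subjects_per_group missing group {g!r}")
            if self.n_subjects_per_group[g] < 0:
                raise ConfigError(f"n_subjects_per_group[{g!r}] must be >= 0")
        if self.n_vr_rois < 1 or self.n_qvr_rois < 1:
            raise ConfigError("n_vr_rois and n_qvr_rois must be >= 1")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ConfigError("dropout_prob must lie in [0, 1)")
        lo, hi = self.slope_vr_range
        if not (0.01 < lo <= hi):
            raise ConfigError(
                "slope_vr_range must satisfy 0.01 < lo <= hi so that true "
                "variant ROIs exceed the 1%/year boundary")
        if not (0.0 <= self.slope_qvr_max <= 0.005):
            raise ConfigError("slope_qvr_max must lie in [0, 0.005]")
        if self.latent_dim < 1 or self.latent_dim > self.n_qvr_rois:
            raise ConfigError("latent_dim must lie in [1, n_qvr_rois]")
        for name in ("intercept_noise_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mci_severity < 0:
            raise ConfigError("mci_severity must be >= 0")
        if self.biomarker_lead_visits < 0:
            raise ConfigError("biomarker_lead_visits must be >= 0")
        if not (0.0 <= self.csf_available_prob <= 1.0):
            raise ConfigError("csf_available_prob must lie in [0, 1]")
        for g in GROUPS:
            if g not in self.csf_params:
                raise ConfigError(f"csf_params missing group {g!r}")

    @property
    def n_rois(self) -> int:
        return self.n_vr_rois + self.n_qvr_rois

    @property
    def roi_names(self) -> list[str]:
        return [f"{ROI_PREFIX}{i:03d}" for i in range(self.n_rois)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_subjects_per_group"] = dict(self.n_subjects_per_group)
        d["visit_months"] = list(self.visit_months)
        d["slope_vr_range"] = list(self.slope_vr_range)
        d["educ_effect_range"] = list(self.educ_effect_range)
        d["csf_params"] = {g: dict(p) for g, p in self.csf_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("visit_months", "slope_vr_range", "educ_effect_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RoiParams:
    """Per-gender generative ROI parameters (indices over all ROIs)."""

    slopes: np.ndarray            # (n_rois,) beta_a, SD units / year
    educ_effects: np.ndarray      # (n_rois,) beta_e
    loadings: np.ndarray          # (n_rois, latent_dim) L
    vr_index: np.ndarray          # indices of true variant ROIs
    qvr_index: np.ndarray         # indices of true quasi-variant ROIs
    affected_index: np.ndarray    # indices of disease-affected ROIs (subset of vr)
    qvr_to_vr_map: np.ndarray     # (n_qvr, n_vr): y0_vr = y0_qvr @ map (noise-free)
    destd_scale: np.ndarray       # (n_rois,) affine export scale
    destd_offset: np.ndarray      # (n_rois,) affine export offset


@dataclass
class GroundTruth:
    """Everything the generator knows that estimators must recover."""

    config: GeneratorConfig
    params: dict[str, RoiParams]                 # keyed by gender
    intercepts: pd.DataFrame                     # subjects x ROIs true y0
    subjects: pd.DataFrame                       # per-subject metadata
    #: conversion month per converter subject (NaN for stable subjects)
    conversion_month: pd.Series
    #: month at which the disease effect starts (NaN for sHC)
    onset_month: pd.Series


def _draw_signs(rng: np.random.Generator, n: int, p_negative: float = 0.75) -> np.ndarray:
    # Aging predominantly shrinks regions; a minority (ventricle-like) expand.
    return np.where(rng.random(n) < p_negative, -1.0, 1.0)


def _simulate_roi_params(cfg: GeneratorConfig, rng: np.random.Generator) -> RoiParams:
    n = cfg.n_rois
    vr_idx = np.arange(cfg.n_vr_rois)
    qvr_idx = np.arange(cfg.n_vr_rois, n)
    slopes = np.empty(n)
    slopes[vr_idx] = rng.uniform(*cfg.slope_vr_range, size=cfg.n_vr_rois) \
        * _draw_signs(rng, cfg.n_vr_rois)
    slopes[qvr_idx] = rng.uniform(0.0, cfg.slope_qvr_max, size=cfg.n_qvr_rois) \
        * _draw_signs(rng, cfg.n_qvr_rois, p_negative=0.5)
    educ = rng.uniform(*cfg.educ_effect_range, size=n)
    # Loadings: random direction per ROI, row norm fixed so Var(L f) = 0.5
    # exactly for every ROI (comparable subject spread across regions).
    loadings = rng.normal(size=(n, cfg.latent_dim))
    loadings *= np.sqrt(0.5) / np.linalg.norm(loadings, axis=1, keepdims=True)
    l_vr = loadings[vr_idx]
    l_qvr = loadings[qvr_idx]
    # Exact (noise-free) linear map qvr-intercepts -> vr-intercepts.
    qvr_to_vr = np.linalg.pinv(l_qvr.T) @ l_vr.T  # (n_qvr, n_vr)
    affected = vr_idx.copy()
    # drawn unconditionally so toggling destandardize leaves the rest of the
    # random stream (hence the underlying SD-scale data) unchanged
    scale = rng.uniform(0.5, 3.0, size=n)
    offset = rng.uniform(-2.0, 5.0, size=n)
    if not cfg.destandardize:
        scale = np.ones(n)
        offset = np.zeros(n)
    return RoiParams(slopes=slopes, educ_effects=educ, loadings=loadings,
                     vr_index=vr_idx, qvr_index=qvr_idx, affected_index=affected,
                     qvr_to_vr_map=qvr_to_vr, destd_scale=scale, destd_offset=offset)


def _realized_visits(cfg: GeneratorConfig, rng: np.random.Generator,
                     require_two: bool) -> list[int]:
    """Monotone dropout: baseline always observed; each later visit is reached
    only if the previous one was."""
    for _ in range(1000):
        visits = [cfg.visit_months[0]]
        for m in cfg.visit_months[1:]:
            if rng.random() < cfg.dropout_prob:
                break
            visits.append(m)
        if not require_two or len(visits) >= 2:
            return visits
    # dropout_prob < 1 makes this unreachable in practice
    return list(cfg.visit_months[:2])


def _dx_sequence(group: str, visits: list[int], conv_month: float | None) -> list[str]:
    seq = []
    for m in visits:
        if group == "sHC":
            seq.append(DX_NL)
        elif group == "sMCI":
            seq.append(DX_MCI)
        elif group == "sAD":
            seq.append(DX_DEM)
        elif group == "cMCI":
            seq.append(DX_MCI if m >= conv_month else DX_NL)
        elif group == "cAD":
            seq.append(DX_DEM if m >= conv_month else DX_MCI)
    return seq


def _cognitive_scores(dx: str, rng: np.random.Generator) -> tuple[float, float]:
    if dx == DX_NL:
        mmse = np.clip(round(rng.normal(29.0, 0.8)), 24, 30)
        cdr = 0.0 if rng.random() < 0.9 else 0.5
    elif dx == DX_MCI:
        mmse = np.clip(round(rng.normal(27.0, 1.5)), 20, 30)
        cdr = 0.5
    else:
        mmse = np.clip(round(rng.normal(22.0, 2.0)), 10, 28)
        cdr = 1.0 if rng.random() < 0.8 else 2.0
    return float(mmse), float(cdr)


def _draw_csf(group: str, cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[float, float]:
    p = cfg.csf_params[group]
    comp = "normal" if rng.random() < p["w_normal"] else "abnormal"
    ab = max(rng.normal(*p[f"abeta_{comp}"]), 1.0)
    tau = max(rng.normal(*p[f"tau_{comp}"]), 1.0)
    return ab, tau


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal cohort; deterministic given ``config.seed``.

    Returns the long-format subject-visit table (one row per realized visit)
    and the :class:`GroundTruth` oracle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roi_names = config.roi_names

    params: dict[str, RoiParams] = {}
    rows: list[dict] = []
    subj_meta: list[dict] = []
    y0_rows: dict[str, np.ndarray] = {}
    conv_months: dict[str, float] = {}
    onset_months: dict[str, float] = {}

    for gender in GENDERS:
        gp = _simulate_roi_params(config, rng)
        params[gender] = gp
        for group in GROUPS:
            severity = {"sHC": 0.0, "sMCI": config.mci_severity,
                        "cMCI": config.mci_severity, "sAD": 1.0, "cAD": 1.0}[group]
            converter = group in ("cMCI", "cAD")
            for k in range(config.n_subjects_per_group[group]):
                sid = f"{gender}_{group}_{k:03d}"
                base_age = rng.uniform(60.0, 90.0)
                educ = float(rng.integers(8, 21))
                visits = _realized_visits(config, rng, require_two=converter)
                if converter:
                    conv_month = float(rng.choice(visits[1:]))
                    conv_idx = visits.index(conv_month)
                    onset_idx = max(conv_idx - config.biomarker_lead_visits, 0)
                    onset_month: float | None = float(visits[onset_idx])
                elif group == "sHC":
                    conv_month, onset_month = np.nan, None
                else:  # stable patients: affected from baseline
                    conv_month, onset_month = np.nan, 0.0
                conv_months[sid] = conv_month
                onset_months[sid] = np.nan if onset_month is None else onset_month

                f = rng.normal(size=config.latent_dim)
                y0 = gp.loadings @ f + rng.normal(0.0, config.intercept_noise_sd,
                                                  size=config.n_rois)
                y0_rows[sid] = y0
                dx_seq = _dx_sequence(group, visits, conv_month)
                ab, tau = _draw_csf(group, config, rng)
                if rng.random() >= config.csf_available_prob:
                    ab = tau = np.nan
                subj_meta.append(dict(subject_id=sid, gender=gender, group=group,
                                      base_age=base_age, educ_years=educ,
                                      n_visits=len(visits)))
                onset_age = None if onset_month is None else base_age + onset_month / 12.0
                for m, dx in zip(visits, dx_seq):
                    age = base_age + m / 12.0
                    y = y0 + gp.slopes * age + gp.educ_effects * educ
                    if severity > 0 and onset_age is not None and age >= onset_age - 1e-9:
                        dt = age - onset_age
                        y[gp.affected_index] -= severity * (
                            config.disease_offset + config.disease_slope_accel * dt)
                    if config.obs_noise_sd > 0:
                        y = y + rng.normal(0.0, config.obs_noise_sd, size=config.n_rois)
                    y = gp.destd_offset + gp.destd_scale * y
                    mmse, cdr = _cognitive_scores(dx, rng)
                    row = dict(subject_id=sid, gender=gender, visit_month=int(m),
                               age_years=age, educ_years=educ, dx_age=dx,
                               mmse=mmse, cdr_global=cdr,
                               csf_abeta=ab if m == 0 else np.nan,
                               csf_tau=tau if m == 0 else np.nan)
                    row.update({name: v for name, v in zip(roi_names, y)})
                    rows.append(row)

    cohort = pd.DataFrame(rows, columns=METADATA_COLUMNS + roi_names)
    subjects = pd.DataFrame(subj_meta).set_index("subject_id")
    intercepts = pd.DataFrame.from_dict(y0_rows, orient="index", columns=roi_names)
    intercepts.index.name = "subject_id"
    truth = GroundTruth(
        config=config, params=params, intercepts=intercepts, subjects=subjects,
        conversion_month=pd.Series(conv_months, name="conversion_month"),
        onset_month=pd.Series(onset_months, name="onset_month"),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# I/O

def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 config: GeneratorConfig | None = None) -> None:
    """Write the cohort as CSV; optionally a sidecar YAML with the config."""
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.17g")
    if config is not None:
        sidecar = path.with_suffix(".yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"generator_config": config.to_dict()}, fh)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and numeric columns.

    Raises :class:`SchemaError` naming the first missing mandatory column and
    :class:`CohortParseError` citing the 1-based data row of the first
    non-numeric cell in a numeric column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file {path} is missing mandatory column {col!r}")
    roi_cols = [c for c in df.columns if c.startswith(ROI_PREFIX)]
    numeric = ["visit_month", "age_years", "educ_years", "mmse", "cdr_global",
               "csf_abeta", "csf_tau"] + roi_cols
    out = df.copy()
    for col in numeric:
        vals = df[col].replace("", np.nan)
        probe = pd.to_numeric(vals, errors="coerce")
        bad = probe.isna() & vals.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CohortParseError(
                f"non-numeric value {vals.iloc[row - 1]!r} in column {col!r} "
                f"at data row {row}")
        # astype(float) round-trips %.17g exactly; to_numeric's fast parser
        # can be off by one ulp
        out[col] = vals.astype(float)
    out["visit_month"] = out["visit_month"].astype(int)
    return out


def cohort_to_csv_bytes(cohort: pd.DataFrame) -> bytes:
    """Canonical CSV serialization, used for bit-identity checks."""
    buf = io.StringIO()
    cohort.to_csv(buf, index=False, float_format="%.17g")
    return buf.getvalue().encode()
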