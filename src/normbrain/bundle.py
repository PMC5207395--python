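"""Serialization of a fitted null model to a directory of text artifacts.

A bundle holds, per gender: the standardization constants, every ROI's mixed
-model fixed effects and variance components, the vr/qvr/excluded labels,
the null-cohort subject intercept table and the fitted PLSR map. All files
are CSV/YAML so runs can be diffed and rebuilt stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intercept_inference import PlsrModel
from .null_model import LMEFit, RoiClassification, StandardizationParams

__all__ = ["NullModelBundle"]

_FLOAT = "%.17g"


@dataclass
class NullModelBundle:
    gender: str
    standardization: StandardizationParams
    fits: dict[str, LMEFit]
    classifications: list[RoiClassification]
    intercepts: pd.DataFrame
    plsr: PlsrModel

    @property
    def vr_rois(self) -> list[str]:
        return [c.roi_id for c in self.classifications if c.label == "vr"]

    @property
    def qvr_rois(self) -> list[str]:
        return [c.roi_id for c in self.classifications if c.label == "qvr"]

    @property
    def retained_rois(self) -> list[str]:
        return self.vr_rois + self.qvr_rois

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"mean": self.standardization.mean,
                      "sd": self.standardization.sd}).rename_axis("roi_id") \
            .to_csv(d / "standardization.csv", float_format=_FLOAT)
        labels = {c.roi_id: c.label for c in self.classifications}
        rows = []
        for roi, f in self.fits.items():
            rows.append(dict(roi_id=roi, beta_intercept=f.beta_intercept,
                             beta_age=f.beta_age, beta_educ=f.beta_educ,
                             psi=f.psi, sigma2=f.sigma2, se_age=f.se_age,
                             p_age=f.p_age, n_subjects=f.n_subjects,
                             n_observations=f.n_observations,
                             label=labels.get(roi, "excluded")))
        pd.DataFrame(rows).to_csv(d / "roi_fits.csv", index=False,
                                  float_format=_FLOAT)
        self.intercepts.to_csv(d / "intercepts.csv", float_format=_FLOAT)
        for name, arr in (("rotations", self.plsr.rotations),
                          ("x_loadings", self.plsr.x_loadings),
                          ("y_loadings", self.plsr.y_loadings)):
            np.savetxt(d / f"plsr_{name}.csv", arr, delimiter=",", fmt=_FLOAT)
        meta = dict(
            gender=self.gender,
            dropped_rois=list(self.standardization.dropped),
            plsr=dict(
                predictor_rois=self.plsr.predictor_rois,
                response_rois=self.plsr.response_rois,
                x_mean=[float(v) for v in self.plsr.x_mean],
                y_mean=[float(v) for v in self.plsr.y_mean],
                n_components=int(self.plsr.n_components),
                loo_rmsep=[float(v) for v in self.plsr.loo_rmsep],
            ),
        )
        with open(d / "bundle.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "NullModelBundle":
        d = Path(directory)
        with open(d / "bundle.yaml") as fh:
            meta = yaml.safe_load(fh)
        std_df = pd.read_csv(d / "standardization.csv", index_col="roi_id")
        std = StandardizationParams(mean=std_df["mean"], sd=std_df["sd"],
                                    dropped=list(meta["dropped_rois"]))
        intercepts = pd.read_csv(d / "intercepts.csv", index_col="subject_id")
        fits_df = pd.read_csv(d / "roi_fits.csv")
        fits: dict[str, LMEFit] = {}
        classifications = []
        for _, r in fits_df.iterrows():
            roi = r["roi_id"]
            icol = intercepts[roi] if roi in intercepts.columns else pd.Series(dtype=float)
            fits[roi] = LMEFit(
                roi_id=roi, beta_intercept=r["beta_intercept"],
                beta_age=r["beta_age"], beta_educ=r["beta_educ"],
                psi=r["psi"], sigma2=r["sigma2"], se_age=r["se_age"],
                p_age=r["p_age"], intercepts=icol,
                n_subjects=int(r["n_subjects"]),
                n_observations=int(r["n_observations"]))
            classifications.append(RoiClassification(
                roi_id=roi, label=r["label"], beta_age=r["beta_age"],
                p_value=r["p_age"]))
        pm = meta["plsr"]
        plsr = PlsrModel(
            predictor_rois=list(pm["predictor_rois"]),
            response_rois=list(pm["response_rois"]),
            x_mean=np.array(pm["x_mean"], float),
            y_mean=np.array(pm["y_mean"], float),
            rotations=np.atleast_2d(np.loadtxt(d / "plsr_rotations.csv", delimiter=",", ndmin=2)),
            x_loadings=np.loadtxt(d / "plsr_x_loadings.csv", delimiter=",", ndmin=2),
            y_loadings=np.loadtxt(d / "plsr_y_loadings.csv", delimiter=",", ndmin=2),
            n_components=int(pm["n_components"]),
            loo_rmsep=np.array(pm["loo_rmsep"], float),
        )
        return cls(gender=meta["gender"], standardization=std, fits=fits,
                   classifications=classifications, intercepts=intercepts,
                   plsr=plsr)
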