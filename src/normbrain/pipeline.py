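"""End-to-end orchestration: generate -> label -> split -> fit null models ->
infer intercepts -> residuals -> classify/evaluate, run separately per gender.

Every threshold of the method (CSF cut-offs 192/93 pg/mL, the 1%/year
variant-ROI boundary, alpha = 0.05, SVM cost C = 1, 60/40 grouped splits) is
a configuration default, never a hard-coded constant in a stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifier as clf
from . import diagnosis_labeling as dxl
from . import intercept_inference as infer
from . import null_model as nm
from . import residual_engine as resid
from .bundle import NullModelBundle
from .synthetic_cohort import GENDERS, GeneratorConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "fit_null_bundle", "residuals_for_cohort"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genders: tuple[str, ...] = GENDERS
    abeta_cutoff: float = dxl.ABETA_CUTOFF
    tau_cutoff: float = dxl.TAU_CUTOFF
    vr_threshold: float = nm.VR_THRESHOLD
    alpha: float = nm.ALPHA
    max_components: int = 8
    svm_cost: float = 1.0
    n_repeats: int = 10
    train_fraction: float = 0.6
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: (tuple(v) if k == "genders" else v) for k, v in raw.items()})
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen)
        return cfg

    def to_dict(self) -> dict:
        d = dict(genders=list(self.genders), abeta_cutoff=self.abeta_cutoff,
                 tau_cutoff=self.tau_cutoff, vr_threshold=self.vr_threshold,
                 alpha=self.alpha, max_components=self.max_components,
                 svm_cost=self.svm_cost, n_repeats=self.n_repeats,
                 train_fraction=self.train_fraction, seed=self.seed,
                 generator=self.generator.to_dict())
        return d


def fit_null_bundle(null_cohort: pd.DataFrame, gender: str,
                    vr_threshold: float = nm.VR_THRESHOLD,
                    alpha: float = nm.ALPHA,
                    max_components: int = 8) -> NullModelBundle:
    """Stage B for one gender: standardize, fit LMEs, classify ROIs and fit
    the qvr -> vr PLSR intercept map on the null cohort."""
    sub = null_cohort[null_cohort["gender"] == gender]
    if len(sub) == 0:
        raise RuntimeError(f"null cohort has no {gender} subjects")
    std = nm.fit_standardization(sub)
    sub_std = nm.apply_standardization(sub, std)
    fits = nm.fit_all_rois(sub_std, std.rois)
    classes = nm.classify_rois(fits, vr_threshold, alpha)
    vr = [c.roi_id for c in classes if c.label == "vr"]
    qvr = [c.roi_id for c in classes if c.label == "qvr"]
    if not vr or not qvr:
        raise RuntimeError(
            f"gender {gender}: need both vr ({len(vr)}) and qvr ({len(qvr)}) ROIs")
    intercepts = nm.extract_intercepts(fits)
    plsr = infer.fit_plsr(intercepts[qvr], intercepts[vr], max_components)
    return NullModelBundle(gender=gender, standardization=std, fits=fits,
                           classifications=classes, intercepts=intercepts,
                           plsr=plsr)


def residuals_for_cohort(cohort: pd.DataFrame,
                         bundle: NullModelBundle) -> pd.DataFrame:
    """Stage C residuals for a (same-gender) cohort against a null bundle.

    qvr intercepts come from the subject's own adjusted observations; vr
    intercepts are inferred through the PLSR map. Returns the E matrix with
    observation metadata columns."""
    std_cohort = nm.apply_standardization(cohort, bundle.standardization)
    qvr, vr = bundle.qvr_rois, bundle.vr_rois
    null_means = bundle.intercepts.mean()
    y0_qvr = infer.estimate_qvr_intercepts(std_cohort, bundle.fits, qvr,
                                           impute_means=null_means)
    y0_vr = infer.infer_vr_intercepts(bundle.plsr, y0_qvr)
    y0 = pd.concat([y0_qvr, y0_vr], axis=1)
    std_cohort = std_cohort[std_cohort["subject_id"].isin(y0.index)]
    expected = resid.predict_expected(y0, std_cohort, bundle.fits)
    observed = std_cohort[expected.columns]
    meta = std_cohort[resid.METADATA_KEEP]
    return resid.compute_residuals(observed, expected, metadata=meta)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 cohort: pd.DataFrame | None = None) -> dict:
    """Run the full workflow; returns a results dict and (optionally) writes
    every intermediate artifact under ``out_dir``.

    Stages: generate (unless ``cohort`` is given) -> derive labels -> split
    null/early cohorts -> per gender: fit null bundle, compute residuals for
    the early-prediction cohort, assemble F1/F2 features, run the three
    binary experiments in both label modes, and compute the advancement of
    the early prediction.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    truth = None
    if cohort is None:
        cohort, truth = generate_cohort(config.generator)
        if out is not None:
            write_cohort(cohort, out / "cohort.csv", config.generator)

    labels = dxl.label_cohort(cohort, config.abeta_cutoff, config.tau_cutoff)
    null_cohort, early_cohort = dxl.split_cohorts(cohort, labels)
    if out is not None:
        labels.to_csv(out / "labels.csv")
        pd.Series(sorted(null_cohort["subject_id"].unique())).to_csv(
            out / "null_subjects.csv", index=False, header=["subject_id"])

    results: dict = {"labels": labels, "truth": truth,
                     "n_null_subjects": null_cohort["subject_id"].nunique(),
                     "genders": {}}
    report_rows = []
    for gender in config.genders:
        gres: dict = {}
        bundle = fit_null_bundle(null_cohort, gender, config.vr_threshold,
                                 config.alpha, config.max_components)
        gres["bundle"] = bundle
        if out is not None:
            bundle.save(out / f"null_bundle_{gender}")
        early_g = early_cohort[early_cohort["gender"] == gender]
        E = residuals_for_cohort(early_g, bundle)
        gres["residuals"] = E
        if out is not None:
            E.to_csv(out / f"residuals_{gender}.csv", index=False,
                     float_format="%.10g")
        Ev = resid.build_Ev(E, bundle.classifications)
        gres["experiments"] = {}
        gres["advancement"] = {}
        for mode in ("current", "last"):
            for variant in ("F1", "F2"):
                feats = resid.assemble_features(Ev, labels, variant=variant,
                                                label_mode=mode)
                for pair_idx, pair in enumerate(clf.PAIRS):
                    spec = clf.ExperimentSpec(
                        pair=pair, label_mode=mode, feature_variant=variant,
                        gender=gender, cost=config.svm_cost,
                        n_repeats=config.n_repeats,
                        train_fraction=config.train_fraction,
                        seed=config.seed + 1000 * (mode == "last") + 10 * pair_idx)
                    try:
                        rep = clf.train_eval(spec, feats, labels["dx_last"],
                                             keep_predictions=(mode == "last"))
                    except clf.ExperimentSkipped as exc:
                        log.warning("%s %s %s %s: skipped (%s)", gender, mode,
                                    variant, pair, exc)
                        continue
                    gres["experiments"][(mode, variant, pair)] = rep
                    report_rows.append(dict(
                        gender=gender, mode=mode, variant=variant, pair=pair,
                        acc=rep.acc_mean, acc_sd=rep.acc_sd,
                        sen=rep.sen_mean, spe=rep.spe_mean,
                        n_subjects=rep.n_subjects,
                        n_observations=rep.n_observations))
                    if mode == "last" and rep.predictions is not None:
                        adv = clf.compute_advancement(rep.predictions,
                                                      labels["dx_last"])
                        gres["advancement"][(variant, pair)] = adv
        results["genders"][gender] = gres
    report = pd.DataFrame(report_rows)
    results["report"] = report
    if out is not None and len(report):
        report.to_csv(out / "report.csv", index=False, float_format="%.4f")
    return results
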