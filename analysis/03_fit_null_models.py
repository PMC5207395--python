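#!/usr/bin/env python
"""Fit the per-gender normative ("null") models of healthy brain aging.

On the null cohort each ROI is standardized to zero mean/unit SD and fitted
with a random-intercept mixed model (age and education as fixed effects).
ROIs are then classified: *variant* when the fitted annual change exceeds 1%
of the ROI's SD and is significant (Wald p <= 0.05), *quasi-variant* when it
does not exceed 1%. A kernel-PLSR map from quasi-variant to variant subject
intercepts (components chosen by leave-one-out error) completes the model.

Reads:  results/cohort.csv, results/labels.csv
Writes: results/null_bundle_F/, results/null_bundle_M/, results/roi_summary.csv
"""

from pathlib import Path

import pandas as pd

from normbrain.diagnosis_labeling import split_cohorts
from normbrain.pipeline import fit_null_bundle
from normbrain.synthetic_cohort import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    labels = pd.read_csv(RESULTS / "labels.csv", index_col="subject_id")
    null_c, _ = split_cohorts(cohort, labels)

    rows = []
    for gender in ("F", "M"):
        bundle = fit_null_bundle(null_c, gender)
        bundle.save(RESULTS / f"null_bundle_{gender}")
        n_excluded = sum(c.label == "excluded" for c in bundle.classifications)
        print(f"{gender}: {null_c[null_c.gender == gender]['subject_id'].nunique()}"
              f" null subjects; {len(bundle.vr_rois)} variant, "
              f"{len(bundle.qvr_rois)} quasi-variant, {n_excluded} excluded ROIs;"
              f" PLSR components = {bundle.plsr.n_components} "
              f"(LOO RMSEP {bundle.plsr.loo_rmsep[bundle.plsr.n_components - 1]:.3f})")
        for c in bundle.classifications:
            fit = bundle.fits[c.roi_id]
            rows.append(dict(gender=gender, roi_id=c.roi_id, label=c.label,
                             beta_age=fit.beta_age, se_age=fit.se_age,
                             p_age=fit.p_age, beta_educ=fit.beta_educ,
                             psi=fit.psi, sigma2=fit.sigma2))
    pd.DataFrame(rows).to_csv(RESULTS / "roi_summary.csv", index=False,
                              float_format="%.6g")
    print(f"wrote {RESULTS / 'roi_summary.csv'}")


if __name__ == "__main__":
    main()
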