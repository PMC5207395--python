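#!/usr/bin/env python
"""Compute deviation scores (residuals) for the early-prediction cohort.

For every subject-visit the null model predicts the value each ROI *should*
have under healthy aging: quasi-variant intercepts are estimated from the
subject's own observations, variant intercepts are inferred through the PLSR
map, and both are extrapolated along the fitted age/education effects.
Residual = observed - expected; systematic negative residuals in variant
ROIs are the disease signal.

Reads:  results/cohort.csv, results/labels.csv, results/null_bundle_{F,M}/
Writes: results/residuals_F.csv, results/residuals_M.csv
"""

from pathlib import Path

import pandas as pd

from normbrain.bundle import NullModelBundle
from normbrain.diagnosis_labeling import split_cohorts
from normbrain.pipeline import residuals_for_cohort
from normbrain.synthetic_cohort import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    labels = pd.read_csv(RESULTS / "labels.csv", index_col="subject_id")
    _, early_c = split_cohorts(cohort, labels)

    for gender in ("F", "M"):
        bundle = NullModelBundle.load(RESULTS / f"null_bundle_{gender}")
        E = residuals_for_cohort(early_c[early_c["gender"] == gender], bundle)
        E.to_csv(RESULTS / f"residuals_{gender}.csv", index=False,
                 float_format="%.8g")
        vr = [c for c in bundle.vr_rois if c in E.columns]
        E = E.merge(labels["dx_last"], left_on="subject_id", right_index=True)
        summary = E.groupby("dx_last")[vr].mean().mean(axis=1)
        print(f"{gender}: mean variant-ROI residual by trajectory class "
              f"(SD units):")
        print("  " + summary.round(3).to_string().replace("\n", "\n  "))
    print(f"wrote {RESULTS}/residuals_{{F,M}}.csv")


if __name__ == "__main__":
    main()
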