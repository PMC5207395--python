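#!/usr/bin/env python
"""Derive diagnosis variables and split the cohorts.

For every subject: the trajectory class dx_last (sHC/sMCI/cMCI/sAD/cAD) from
the visit-by-visit diagnoses, the CSF profile (normal iff amyloid-beta >= 192
pg/mL and tau <= 93 pg/mL at every measurement), and their cross dx_csf.
Stable controls with a normal CSF profile form the null-model cohort; every
other subject goes to the early-prediction cohort.

Reads:  results/cohort.csv
Writes: results/labels.csv, results/null_subjects.csv
"""

from pathlib import Path

import pandas as pd

from normbrain.diagnosis_labeling import label_cohort, split_cohorts
from normbrain.synthetic_cohort import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    labels = label_cohort(cohort)
    labels.to_csv(RESULTS / "labels.csv")
    null_c, early_c = split_cohorts(cohort, labels)
    null_ids = sorted(null_c["subject_id"].unique())
    pd.Series(null_ids, name="subject_id").to_csv(
        RESULTS / "null_subjects.csv", index=False)

    print("subjects per dx_csf class:")
    print(labels["dx_csf"].value_counts().to_string())
    print(f"\nnull-model cohort: {len(null_ids)} subjects "
          f"({len(null_c)} visits); early-prediction cohort: "
          f"{early_c['subject_id'].nunique()} subjects ({len(early_c)} visits)")
    print(f"wrote {RESULTS / 'labels.csv'}")


if __name__ == "__main__":
    main()
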