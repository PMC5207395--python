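#!/usr/bin/env python
"""Subject classification from residuals (labels = diagnosis at the visit).

Three binary experiments (HC-vs-AD, HC-vs-MCI, MCI-vs-AD) with radial-kernel
SVMs (C = 1) on the residual feature sets F1 (residuals + age) and F2
(+ MMSE, CDR global), evaluated over 10 subject-grouped 60/40 splits.

Reads:  results/cohort.csv, results/labels.csv, results/null_bundle_{F,M}/,
        results/residuals_{F,M}.csv
Writes: results/classification.csv
"""

from pathlib import Path

import pandas as pd

import normbrain.classifier as clf
import normbrain.residual_engine as resid
from normbrain.bundle import NullModelBundle

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 77


def main() -> None:
    labels = pd.read_csv(RESULTS / "labels.csv", index_col="subject_id")
    rows = []
    for gender in ("F", "M"):
        bundle = NullModelBundle.load(RESULTS / f"null_bundle_{gender}")
        E = pd.read_csv(RESULTS / f"residuals_{gender}.csv")
        Ev = resid.build_Ev(E, bundle.classifications)
        for variant in ("F1", "F2"):
            feats = resid.assemble_features(Ev, labels, variant=variant,
                                            label_mode="current")
            for pair in clf.PAIRS:
                spec = clf.ExperimentSpec(pair=pair, feature_variant=variant,
                                          gender=gender, seed=SEED)
                try:
                    rep = clf.train_eval(spec, feats, labels["dx_last"])
                except clf.ExperimentSkipped as exc:
                    print(f"{gender} {variant} {pair}: skipped ({exc})")
                    continue
                rows.append(dict(gender=gender, variant=variant, pair=pair,
                                 acc=rep.acc_mean, acc_sd=rep.acc_sd,
                                 sen=rep.sen_mean, spe=rep.spe_mean,
                                 n_subjects=rep.n_subjects,
                                 n_observations=rep.n_observations))
    report = pd.DataFrame(rows)
    report.to_csv(RESULTS / "classification.csv", index=False,
                  float_format="%.2f")
    print("subject classification, mean over 10 grouped 60/40 splits (%):")
    print(report.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    avg = report.groupby(["variant", "pair"])["acc"].mean().round(1)
    print("\naccuracy averaged over genders:")
    print(avg.to_string())
    print(f"\nwrote {RESULTS / 'classification.csv'}")


if __name__ == "__main__":
    main()
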