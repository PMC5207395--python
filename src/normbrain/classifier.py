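"""Residual-based SVM classification and early-prediction advancement.

Three binary experiments (HC-vs-AD, HC-vs-MCI, MCI-vs-AD) are run on the
residual feature sets in two labelling modes: *current* (labels are the
visit diagnosis, a plain classification problem) and *last* (every row of a
subject carries their final trajectory class, so the classifier learns to
predict the future outcome from the present visit). Under the *last* mode
the MCI-vs-AD pair contrasts stable MCI (sMCI) against MCI-to-AD converters
(cAD) — the prodromal-AD discrimination.

Evaluation uses repeated random subject-grouped splits: on each of the 10
repeats, 60% of the *subjects* (stratified by class) go to training and 40%
to test, so no subject contributes observations to both sides. The SVM is a
Gaussian radial kernel with misclassification cost C = 1; features are
scaled to training-split statistics only. Sensitivity/specificity treat the
disease class of each pair as positive.

The *advancement* of the early prediction is, for each converter, the time
by which the classifier's first correct (pre-conversion) prediction of the
final class precedes the clinical diagnosis change, averaged within
gender x five-year age strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .residual_engine import coarse_class

__all__ = [
    "ExperimentSpec",
    "EvaluationReport",
    "ExperimentSkipped",
    "PAIRS",
    "grouped_splits",
    "train_eval",
    "compute_advancement",
    "age_group_label",
]

log = logging.getLogger(__name__)

#: binary pair -> (negative class, positive/disease class)
PAIRS = {
    "HC-vs-AD": ("HC", "AD"),
    "HC-vs-MCI": ("HC", "MCI"),
    "MCI-vs-AD": ("MCI", "AD"),
}

MIN_SUBJECTS_PER_CLASS = 5


class ExperimentSkipped(RuntimeError):
    """Too few subjects in a class to evaluate the experiment."""


@dataclass(frozen=True)
class ExperimentSpec:
    pair: str = "HC-vs-AD"
    label_mode: str = "current"          # 'current' | 'last'
    feature_variant: str = "F1"          # informational; features are prebuilt
    gender: str | None = None
    age_group: str | None = None         # e.g. '70-74', filters on age at visit
    cost: float = 1.0
    n_repeats: int = 10
    train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.pair not in PAIRS:
            raise ValueError(f"unknown experiment pair {self.pair!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.label_mode not in ("current", "last"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")


@dataclass
class EvaluationReport:
    spec: ExperimentSpec
    acc_mean: float
    acc_sd: float
    sen_mean: float
    sen_sd: float
    spe_mean: float
    spe_sd: float
    confusion: dict = field(default_factory=dict)   # summed TP/FP/TN/FN
    n_repeats_used: int = 0
    n_subjects: int = 0
    n_observations: int = 0
    #: per-repeat test-set predictions (repeat, subject_id, age_years,
    #: dx_age, label, predicted)
    predictions: pd.DataFrame | None = None


def age_group_label(age: float, width: int = 5) -> str:
    lo = int(np.floor(age / width) * width)
    return f"{lo}-{lo + width - 1}"


def _in_age_group(age: pd.Series, group: str) -> pd.Series:
    lo, hi = (int(x) for x in group.split("-"))
    return (age >= lo) & (age <= hi + 1 - 1e-9)


def grouped_splits(subject_ids: np.ndarray, subject_classes: np.ndarray,
                   n_repeats: int = 10, train_fraction: float = 0.6,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random subject-level splits, stratified by class.

    Returns ``n_repeats`` pairs (train_subjects, test_subjects). Every subject
    falls wholly on one side of each split. Raises :class:`ExperimentSkipped`
    if a class has fewer than 5 subjects.
    """
    subject_ids = np.asarray(subject_ids)
    subject_classes = np.asarray(subject_classes)
    classes, counts = np.unique(subject_classes, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < MIN_SUBJECTS_PER_CLASS:
            raise ExperimentSkipped(
                f"class {cls!r} has only {cnt} subjects (< {MIN_SUBJECTS_PER_CLASS})")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        train: list[np.ndarray] = []
        test: list[np.ndarray] = []
        for cls in classes:
            ids = subject_ids[subject_classes == cls].copy()
            rng.shuffle(ids)
            n_train = int(round(train_fraction * len(ids)))
            n_train = min(max(n_train, 1), len(ids) - 1)
            train.append(ids[:n_train])
            test.append(ids[n_train:])
        splits.append((np.concatenate(train), np.concatenate(test)))
    return splits


def _subject_classes(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """One class per subject: the label at their last visit within the
    experiment's rows (constant anyway under the 'last' mode)."""
    last = rows.sort_values("age_years").groupby("subject_id")["label"].last()
    return last.index.to_numpy(), last.to_numpy()


def _filter_rows(features: pd.DataFrame, spec: ExperimentSpec,
                 dx_last: pd.Series | None) -> pd.DataFrame:
    neg, pos = PAIRS[spec.pair]
    rows = features[features["label"].isin([neg, pos])]
    if spec.label_mode == "last":
        if dx_last is None:
            raise ValueError("dx_last labels required for label_mode='last'")
        sub_last = dx_last.reindex(rows["subject_id"]).to_numpy()
        if spec.pair == "MCI-vs-AD":
            # prodromal-AD pair: stable MCI vs MCI-to-AD converters
            rows = rows[np.isin(sub_last, ["sMCI", "cAD"])]
        elif spec.pair == "HC-vs-MCI":
            rows = rows[np.isin(sub_last, ["sHC", "sMCI", "cMCI"])]
        else:
            rows = rows[np.isin(sub_last, ["sHC", "sAD", "cAD"])]
    if spec.age_group is not None:
        rows = rows[_in_age_group(rows["age_years"], spec.age_group)]
    return rows


def train_eval(spec: ExperimentSpec, features: pd.DataFrame,
               dx_last: pd.Series | None = None,
               keep_predictions: bool = False) -> EvaluationReport:
    """Fit and evaluate the radial-kernel SVM over repeated grouped splits.

    ``features`` is an :func:`~normbrain.residual_engine.assemble_features`
    table (its label_mode must match the spec's). ``dx_last`` maps
    subject_id -> trajectory class, required for the 'last' mode.
    """
    if features.attrs.get("label_mode", spec.label_mode) != spec.label_mode:
        raise ValueError("features were assembled with a different label_mode")
    feature_cols = features.attrs.get(
        "feature_cols",
        [c for c in features.columns
         if c not in ("subject_id", "age_years", "dx_age", "label")])
    neg, pos = PAIRS[spec.pair]
    rows = _filter_rows(features, spec, dx_last)
    if len(rows) == 0:
        raise ExperimentSkipped("no observations left after filtering")
    ids, classes = _subject_classes(rows)
    splits = grouped_splits(ids, classes, spec.n_repeats, spec.train_fraction,
                            spec.seed)
    X = rows[feature_cols].to_numpy(float)
    y = (rows["label"] == pos).to_numpy()
    sid = rows["subject_id"].to_numpy()
    accs, sens, spes = [], [], []
    conf = dict(TP=0, FP=0, TN=0, FN=0)
    pred_frames = []
    for rep, (train_ids, test_ids) in enumerate(splits):
        tr = np.isin(sid, train_ids)
        te = np.isin(sid, test_ids)
        y_tr = y[tr]
        if y_tr.all() or not y_tr.any():
            log.warning("%s repeat %d: single-class training split discarded",
                        spec.pair, rep)
            continue
        # scale with training statistics only
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="rbf", C=spec.cost, gamma="scale")
        clf.fit((X[tr] - mu) / sd, y_tr)
        y_hat = clf.predict((X[te] - mu) / sd)
        y_te = y[te]
        tp = int(np.sum(y_hat & y_te))
        tn = int(np.sum(~y_hat & ~y_te))
        fp = int(np.sum(y_hat & ~y_te))
        fn = int(np.sum(~y_hat & y_te))
        conf["TP"] += tp; conf["TN"] += tn; conf["FP"] += fp; conf["FN"] += fn
        accs.append(100.0 * (tp + tn) / max(tp + tn + fp + fn, 1))
        sens.append(100.0 * tp / max(tp + fn, 1))
        spes.append(100.0 * tn / max(tn + fp, 1))
        if keep_predictions:
            pf = rows.loc[te, ["subject_id", "age_years", "dx_age", "label"]].copy()
            pf["predicted"] = np.where(y_hat, pos, neg)
            pf["repeat"] = rep
            pred_frames.append(pf)
    if not accs:
        raise ExperimentSkipped("every repeat had a degenerate training split")
    return EvaluationReport(
        spec=spec,
        acc_mean=float(np.mean(accs)), acc_sd=float(np.std(accs)),
        sen_mean=float(np.mean(sens)), sen_sd=float(np.std(sens)),
        spe_mean=float(np.mean(spes)), spe_sd=float(np.std(spes)),
        confusion=conf, n_repeats_used=len(accs),
        n_subjects=len(ids), n_observations=len(rows),
        predictions=pd.concat(pred_frames, ignore_index=True) if pred_frames else None,
    )


def compute_advancement(predictions: pd.DataFrame, dx_last: pd.Series,
                        age_group_width: int = 5) -> pd.DataFrame:
    """Advancement in years of the early prediction, per five-year age group.

    ``predictions`` is the per-repeat test-set prediction table from
    :func:`train_eval` run with ``label_mode='last'``. Eligible subjects are
    converters: those with some visit whose diagnosis differs from their
    final class. For each such subject and repeat,

        advancement = age at first clinical visit with dx_age equal to the
                      final class  -  age at earliest visit predicted as the
                      final class while dx_age is still pre-conversion,

    counted only when such an earlier correct prediction exists. Subject
    values (mean over their test repeats) are averaged within age groups of
    the clinical conversion age. Returns a table indexed by age group with
    columns ``advancement_years`` and ``n_subjects``; groups without eligible
    subjects are absent (N/A).
    """
    per_subject: dict[str, tuple[float, float]] = {}
    for sid, sub in predictions.groupby("subject_id"):
        final = coarse_class(dx_last[sid])
        sub = sub.copy()
        sub["dx_coarse"] = sub["dx_age"].map(coarse_class)
        converted = sub[sub["dx_coarse"] == final]
        pre = sub[sub["dx_coarse"] != final]
        if len(converted) == 0 or len(pre) == 0:
            continue  # not an observed converter
        conv_age = float(converted["age_years"].min())
        vals = []
        for _, rep_rows in pre.groupby("repeat"):
            hit = rep_rows[(rep_rows["predicted"] == final)
                           & (rep_rows["age_years"] < conv_age)]
            if len(hit):
                vals.append(conv_age - float(hit["age_years"].min()))
        if vals:
            per_subject[sid] = (float(np.mean(vals)), conv_age)
    if not per_subject:
        log.warning("no eligible converter subjects for advancement")
        return pd.DataFrame(columns=["advancement_years", "n_subjects"])
    df = pd.DataFrame(
        [(age_group_label(conv_age, age_group_width), adv)
         for adv, conv_age in per_subject.values()],
        columns=["age_group", "advancement_years"])
    out = df.groupby("age_group")["advancement_years"].agg(["mean", "count"])
    out.columns = ["advancement_years", "n_subjects"]
    return out
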