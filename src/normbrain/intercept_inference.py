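"""PLSR transfer of subject intercepts from quasi-variant to variant ROIs.

The identification idea: quasi-variant (qvr) ROIs barely change with age and
are assumed undistorted by disease, so a subject's qvr intercepts y0 can be
estimated from their own observations alone. On the healthy null cohort the
qvr and vr intercepts are strongly correlated (they share latent anatomy), so
a partial least squares regression (PLSR) fitted on the null cohort maps any
subject's qvr intercepts to the vr intercepts *they would have if healthy*.

PLSR is computed with the cross-product ("kernel") algorithm, which works on
X'Y rather than iterating over X and Y, and is algebraically equivalent to
NIPALS PLS2. The number of latent components is chosen by leave-one-out
cross-validation, minimizing the root-mean-squared prediction error pooled
over all vr responses (one shared component count for the whole map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .null_model import LMEFit

__all__ = [
    "PlsrModel",
    "kernel_pls",
    "fit_plsr",
    "loo_rmsep_curve",
    "estimate_new_subject_qvr_intercepts",
    "estimate_qvr_intercepts",
    "infer_vr_intercepts",
]

log = logging.getLogger(__name__)


def kernel_pls(X: np.ndarray, Y: np.ndarray,
               n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kernel-algorithm PLS2 on *centered* X (n x p) and Y (n x m).

    Works on the cross-product matrix X'Y: each component's X-weight w is the
    dominant left singular direction of the current X'Y (for m = 1 simply the
    normalized X'Y), deflated through X-loadings only. Returns
    ``(W_rot, P, Q)`` where ``W_rot`` (p x a) are the X-rotations mapping
    centered predictors to scores, ``P`` (p x a) the X-loadings and ``Q``
    (m x a) the Y-loadings; the coefficient matrix for ``a`` components is
    ``W_rot[:, :a] @ Q[:, :a].T``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    m = Y.shape[1]
    a_max = min(n_components, p, max(n - 1, 1))
    XY = X.T @ Y                      # p x m cross-product kernel
    R = np.zeros((p, a_max))          # rotations
    P = np.zeros((p, a_max))          # X-loadings
    Q = np.zeros((m, a_max))          # Y-loadings
    for a in range(a_max):
        if m == 1:
            w = XY[:, 0]
        else:
            # dominant eigenvector of (X'Y)(X'Y)' via the small m x m problem
            C = XY.T @ XY
            vals, vecs = np.linalg.eigh(C)
            q = vecs[:, -1]
            w = XY @ q
        norm = np.linalg.norm(w)
        if norm <= np.finfo(float).eps * 100:
            R, P, Q = R[:, :a], P[:, :a], Q[:, :a]
            break
        w = w / norm
        # rotation: orthogonalize w against previous loadings
        r = w.copy()
        for j in range(a):
            r -= (P[:, j] @ w) * R[:, j]
        t = X @ r
        tt = t @ t
        if tt <= np.finfo(float).eps * 100:
            R, P, Q = R[:, :a], P[:, :a], Q[:, :a]
            break
        P[:, a] = (X.T @ t) / tt
        Q[:, a] = (XY.T @ r) / tt
        R[:, a] = r
        XY = XY - np.outer(P[:, a], Q[:, a]) * tt
    return R, P, Q


@dataclass
class PlsrModel:
    """Fitted qvr -> vr intercept map."""

    predictor_rois: list[str]
    response_rois: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    rotations: np.ndarray          # p x A
    x_loadings: np.ndarray         # p x A
    y_loadings: np.ndarray         # m x A
    n_components: int
    #: LOO RMSEP indexed 1..max_components
    loo_rmsep: np.ndarray = field(default_factory=lambda: np.array([]))

    def coef(self, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        if a < 0 or a > self.rotations.shape[1]:
            raise ValueError(f"n_components must lie in [0, {self.rotations.shape[1]}]")
        return self.rotations[:, :a] @ self.y_loadings[:, :a].T

    def predict(self, X: np.ndarray | pd.DataFrame,
                n_components: int | None = None) -> np.ndarray:
        """Predict vr intercepts; with 0 components returns the response means."""
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        Yhat = self.y_mean + (X - self.x_mean) @ self.coef(n_components)
        return Yhat[0] if one else Yhat


def _fit_raw(X: np.ndarray, Y: np.ndarray, a: int):
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    R, P, Q = kernel_pls(X - x_mean, Y - y_mean, a)
    return x_mean, y_mean, R, P, Q


def loo_rmsep_curve(X: np.ndarray, Y: np.ndarray, max_components: int) -> np.ndarray:
    """Leave-one-subject-out RMSEP pooled over all responses, for component
    counts 1..max_components."""
    n = X.shape[0]
    max_components = min(max_components, X.shape[1], n - 2)
    press = np.zeros(max_components)
    for i in range(n):
        keep = np.arange(n) != i
        x_mean, y_mean, R, P, Q = _fit_raw(X[keep], Y[keep], max_components)
        xc = X[i] - x_mean
        fitted = R.shape[1]
        for a in range(1, max_components + 1):
            aa = min(a, fitted)
            resid = Y[i] - (y_mean + xc @ (R[:, :aa] @ Q[:, :aa].T))
            press[a - 1] += float(resid @ resid)
    return np.sqrt(press / (n * Y.shape[1]))


def fit_plsr(qvr_intercepts: pd.DataFrame, vr_intercepts: pd.DataFrame,
             max_components: int = 10) -> PlsrModel:
    """Fit the null-cohort PLSR map with LOO-selected component count.

    Both tables must be indexed by subject; rows with any missing cell are
    dropped (logged). Fewer than 3 complete subjects is fatal.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if not qvr_intercepts.index.equals(vr_intercepts.index):
        common = qvr_intercepts.index.intersection(vr_intercepts.index)
        qvr_intercepts = qvr_intercepts.loc[common]
        vr_intercepts = vr_intercepts.loc[common]
    complete = ~(qvr_intercepts.isna().any(axis=1) | vr_intercepts.isna().any(axis=1))
    if (~complete).any():
        log.warning("dropping %d subjects with incomplete intercepts from PLSR fit",
                    int((~complete).sum()))
    Xd = qvr_intercepts[complete].sort_index()
    Yd = vr_intercepts[complete].sort_index()
    if len(Xd) < 3:
        raise RuntimeError(f"PLSR needs >= 3 complete subjects, got {len(Xd)}")
    X = Xd.to_numpy(float)
    Y = Yd.to_numpy(float)
    curve = loo_rmsep_curve(X, Y, max_components)
    n_comp = int(np.argmin(curve)) + 1
    x_mean, y_mean, R, P, Q = _fit_raw(X, Y, n_comp)
    return PlsrModel(
        predictor_rois=list(Xd.columns), response_rois=list(Yd.columns),
        x_mean=x_mean, y_mean=y_mean, rotations=R, x_loadings=P, y_loadings=Q,
        n_components=min(n_comp, R.shape[1]), loo_rmsep=curve,
    )


def estimate_new_subject_qvr_intercepts(subject_obs: pd.DataFrame,
                                        fits: dict[str, LMEFit],
                                        qvr_rois: list[str]) -> pd.Series:
    """Estimate a new subject's qvr intercepts from their own observations.

    Inverts the expected-value relation per observation and averages:
    y0 = mean_j( y_ij - beta_a * age_ij - beta_e * educ_i ), using the null
    model's fixed effects for that ROI. ROIs with no observation are NaN.
    """
    out = {}
    for roi in qvr_rois:
        fit = fits[roi]
        sub = subject_obs.dropna(subset=[roi])
        if len(sub) == 0:
            out[roi] = np.nan
            continue
        adj = (sub[roi] - fit.beta_age * sub["age_years"]
               - fit.beta_educ * sub["educ_years"])
        out[roi] = float(adj.mean())
    return pd.Series(out)


def estimate_qvr_intercepts(std_cohort: pd.DataFrame, fits: dict[str, LMEFit],
                            qvr_rois: list[str],
                            impute_means: pd.Series | None = None) -> pd.DataFrame:
    """Per-subject qvr intercepts for a (standardized) cohort.

    Subjects with no usable observation at all are skipped (logged). Missing
    individual ROIs are imputed with the null cohort's mean intercept for
    that ROI when ``impute_means`` is given (imputation counts logged).
    """
    rows = {}
    skipped = 0
    for sid, sub in std_cohort.groupby("subject_id", sort=True):
        vec = estimate_new_subject_qvr_intercepts(sub, fits, qvr_rois)
        if vec.isna().all():
            skipped += 1
            continue
        rows[sid] = vec
    if skipped:
        log.warning("skipped %d subjects without any qvr observation", skipped)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    if impute_means is not None and table.isna().any().any():
        n_imp = int(table.isna().sum().sum())
        log.warning("imputing %d missing qvr intercept cells with null-cohort means",
                    n_imp)
        table = table.fillna(impute_means[qvr_rois])
    return table


def infer_vr_intercepts(model: PlsrModel,
                        qvr_intercepts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Predict vr intercepts for one subject (Series) or a table of subjects."""
    if isinstance(qvr_intercepts, pd.Series):
        missing = [r for r in model.predictor_rois if r not in qvr_intercepts.index
                   or pd.isna(qvr_intercepts[r])]
        if missing:
            raise ValueError(f"missing qvr predictors: {missing}")
        yhat = model.predict(qvr_intercepts[model.predictor_rois].to_numpy(float))
        return pd.Series(yhat, index=model.response_rois)
    missing = [r for r in model.predictor_rois if r not in qvr_intercepts.columns]
    if missing:
        raise ValueError(f"missing qvr predictors: {missing}")
    X = qvr_intercepts[model.predictor_rois]
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing qvr predictor values in columns: {bad}")
    Yhat = model.predict(X.to_numpy(float))
    return pd.DataFrame(Yhat, index=qvr_intercepts.index, columns=model.response_rois)
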