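"""PLSR intercept transfer: kernel-algorithm correctness against independent
implementations, LOO component selection, and new-subject intercept rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from normbrain.intercept_inference import (
    PlsrModel,
    estimate_new_subject_qvr_intercepts,
    estimate_qvr_intercepts,
    fit_plsr,
    infer_vr_intercepts,
    kernel_pls,
    loo_rmsep_curve,
)
from normbrain.null_model import LMEFit
from normbrain.synthetic_cohort import generate_cohort

from conftest import make_config


def _model_from_arrays(X, Y, n_components, x_cols=None, y_cols=None):
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    R, P, Q = kernel_pls(X - x_mean, Y - y_mean, n_components)
    return PlsrModel(
        predictor_rois=x_cols or [f"x{i}" for i in range(X.shape[1])],
        response_rois=y_cols or [f"y{i}" for i in range(Y.shape[1])],
        x_mean=x_mean, y_mean=y_mean, rotations=R, x_loadings=P,
        y_loadings=Q, n_components=R.shape[1])


def _fake_fit(roi, beta_a, beta_e, beta1=0.0):
    return LMEFit(roi_id=roi, beta_intercept=beta1, beta_age=beta_a,
                  beta_educ=beta_e, psi=0.1, sigma2=0.01, se_age=0.01,
                  p_age=0.5, intercepts=pd.Series(dtype=float),
                  n_subjects=10, n_observations=40)


class TestKernelPls:
    @pytest.mark.parametrize("n,p,m,a", [(30, 6, 4, 1), (30, 6, 4, 3),
                                         (25, 10, 1, 4), (40, 3, 7, 2)])
    def test_matches_sklearn_nipals(self, n, p, m, a):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(n, p))
        B = rng.normal(size=(p, m))
        Y = X @ B + 0.1 * rng.normal(size=(n, m))
        model = _model_from_arrays(X, Y, a)
        # tight inner tolerance: our kernel solution is an exact
        # eigendecomposition, sklearn's NIPALS iterates to tol
        ref = PLSRegression(n_components=a, scale=False, tol=1e-12,
                            max_iter=10000).fit(X, Y)
        Xnew = rng.normal(size=(5, p))
        # agreement limited by the iterative oracle, not by our closed-form
        # eigendecomposition (per-component rotations agree to ~1e-12)
        np.testing.assert_allclose(model.predict(Xnew), ref.predict(Xnew),
                                   atol=1e-4)

    def test_single_component_single_response_brute_force(self):
        # one component, one response: regression of y on the first PLS
        # score t = X_c w, w = X_c' y_c / ||X_c' y_c||
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 5))
        y = (X @ rng.normal(size=5) + 0.2 * rng.normal(size=20)).reshape(-1, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean(axis=0)
        w = Xc.T @ yc[:, 0]
        w /= np.linalg.norm(w)
        t = Xc @ w
        q = (t @ yc[:, 0]) / (t @ t)
        model = _model_from_arrays(X, y, 1)
        Xnew = rng.normal(size=(6, 5))
        brute = y.mean() + ((Xnew - X.mean(axis=0)) @ w) * q
        np.testing.assert_allclose(model.predict(Xnew)[:, 0], brute, atol=1e-10)

    def test_zero_components_returns_response_means(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(15, 4)), rng.normal(size=(15, 3))
        model = _model_from_arrays(X, Y, 2)
        np.testing.assert_allclose(model.predict(X[0], n_components=0),
                                   Y.mean(axis=0))
        # mean predictor vector maps to the response means at any order
        np.testing.assert_allclose(model.predict(X.mean(axis=0)),
                                   Y.mean(axis=0), atol=1e-12)


class TestFitPlsr:
    @staticmethod
    @pytest.fixture(scope="class")
    def latent_tables():
        cfg = make_config(groups={"sHC": 30}, intercept_noise_sd=0.0,
                          obs_noise_sd=0.0, dropout_prob=0.0, seed=17)
        _, truth = generate_cohort(cfg)
        p = truth.params["F"]
        ids = [s for s in truth.intercepts.index if s.startswith("F")]
        y0 = truth.intercepts.loc[ids]
        qvr_cols = [y0.columns[i] for i in p.qvr_index]
        vr_cols = [y0.columns[i] for i in p.vr_index]
        return cfg, y0[qvr_cols], y0[vr_cols]

    def test_noise_free_recovery_at_latent_dim(self, latent_tables):
        cfg, Xq, Yv = latent_tables
        model = fit_plsr(Xq, Yv, max_components=8)
        assert model.n_components >= cfg.latent_dim
        # LOO error collapses once the latent dimension is reached
        assert model.loo_rmsep[cfg.latent_dim - 1] < 1e-8
        pred = infer_vr_intercepts(model, Xq)
        np.testing.assert_allclose(pred.to_numpy(), Yv.to_numpy(), atol=1e-8)

    def test_loo_curve_monotone_at_choice(self, latent_tables):
        _, Xq, Yv = latent_tables
        model = fit_plsr(Xq, Yv, max_components=8)
        assert model.loo_rmsep[model.n_components - 1] <= model.loo_rmsep[0]

    def test_response_equal_to_predictor_column(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 4)),
                         index=[f"s{i}" for i in range(20)],
                         columns=list("abcd"))
        Y = X[["b"]].rename(columns={"b": "resp"})
        model = fit_plsr(X, Y, max_components=4)
        pred = infer_vr_intercepts(model, X)
        np.testing.assert_allclose(pred["resp"], X["b"], atol=1e-8)

    def test_row_permutation_invariance(self, latent_tables):
        _, Xq, Yv = latent_tables
        m1 = fit_plsr(Xq, Yv, max_components=5)
        perm = np.random.default_rng(0).permutation(len(Xq))
        m2 = fit_plsr(Xq.iloc[perm], Yv.iloc[perm], max_components=5)
        assert m1.n_components == m2.n_components
        np.testing.assert_allclose(m1.coef(), m2.coef(), atol=1e-10)

    def test_too_few_subjects_fatal(self):
        X = pd.DataFrame(np.eye(2), columns=["a", "b"])
        with pytest.raises(RuntimeError):
            fit_plsr(X, X, max_components=1)
        with pytest.raises(ValueError):
            fit_plsr(pd.DataFrame(np.eye(4)), pd.DataFrame(np.eye(4)),
                     max_components=0)


class TestNewSubjectIntercepts:
    def test_single_observation_arithmetic(self):
        obs = pd.DataFrame(dict(subject_id=["s1"], age_years=[70.0],
                                educ_years=[16.0], roi_q=[0.5]))
        fits = {"roi_q": _fake_fit("roi_q", beta_a=0.004, beta_e=0.0)}
        y0 = estimate_new_subject_qvr_intercepts(obs, fits, ["roi_q"])
        assert y0["roi_q"] == pytest.approx(0.5 - 0.004 * 70.0)  # 0.22

    def test_two_observations_on_a_line_agree(self):
        fits = {"roi_q": _fake_fit("roi_q", beta_a=-0.02, beta_e=0.01)}
        y_at = lambda age: 1.3 - 0.02 * age + 0.01 * 12.0
        obs = pd.DataFrame(dict(subject_id=["s1"] * 2, age_years=[70.0, 75.0],
                                educ_years=[12.0, 12.0],
                                roi_q=[y_at(70.0), y_at(75.0)]))
        y0 = estimate_new_subject_qvr_intercepts(obs, fits, ["roi_q"])
        # y0 excludes the education contribution: it is subtracted along
        # with the age trend when inverting the expected-value relation
        assert y0["roi_q"] == pytest.approx(1.3)

    def test_noise_free_subject_recovers_truth(self, noise_free_cohort):
        cfg, cohort, truth = noise_free_cohort
        p = truth.params["F"]
        roi_idx = p.qvr_index[0]
        roi = cfg.roi_names[roi_idx]
        fits = {roi: _fake_fit(roi, beta_a=p.slopes[roi_idx],
                               beta_e=p.educ_effects[roi_idx])}
        sid = "F_sHC_000"
        sub = cohort[cohort["subject_id"] == sid]
        y0 = estimate_new_subject_qvr_intercepts(sub, fits, [roi])
        assert y0[roi] == pytest.approx(truth.intercepts.loc[sid, roi], abs=1e-10)

    def test_missing_roi_gives_nan_then_imputed(self):
        fits = {"roi_q": _fake_fit("roi_q", 0.0, 0.0),
                "roi_r": _fake_fit("roi_r", 0.0, 0.0)}
        obs = pd.DataFrame(dict(subject_id=["s1"], age_years=[70.0],
                                educ_years=[12.0], roi_q=[1.0],
                                roi_r=[np.nan]))
        table = estimate_qvr_intercepts(obs, fits, ["roi_q", "roi_r"],
                                        impute_means=pd.Series(
                                            dict(roi_q=0.0, roi_r=-0.4)))
        assert table.loc["s1", "roi_r"] == pytest.approx(-0.4)

    def test_missing_predictor_raises_with_names(self):
        model = _model_from_arrays(np.random.default_rng(0).normal(size=(10, 3)),
                                   np.random.default_rng(1).normal(size=(10, 2)),
                                   1, x_cols=["a", "b", "c"])
        with pytest.raises(ValueError, match="b"):
            infer_vr_intercepts(model, pd.Series(dict(a=1.0, c=2.0)))
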