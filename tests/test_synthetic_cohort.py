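"""Generator contracts: determinism, noise-free geometry, dropout, CSF
mixtures, ground-truth consistency and file round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from normbrain.synthetic_cohort import (
    CohortParseError,
    ConfigError,
    GeneratorConfig,
    SchemaError,
    cohort_to_csv_bytes,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from normbrain.diagnosis_labeling import classify_csf_profile

from conftest import make_config


class TestConfigValidation:
    @pytest.mark.parametrize("overrides", [
        dict(visit_months=(6, 12)),                # must start at 0
        dict(visit_months=(0, 12, 12)),            # strictly increasing
        dict(dropout_prob=1.0),
        dict(slope_vr_range=(0.005, 0.08)),        # crosses 1%/yr boundary
        dict(slope_qvr_max=0.02),                  # above the qvr ceiling
        dict(latent_dim=100),                      # > n_qvr_rois
        dict(obs_noise_sd=-1.0),
    ])
    def test_invalid_configs_rejected(self, overrides):
        cfg = GeneratorConfig(**overrides)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_error_names_the_violated_invariant(self):
        with pytest.raises(ConfigError, match="dropout_prob"):
            GeneratorConfig(dropout_prob=2.0).validate()


class TestGeneration:
    def test_row_count_without_dropout(self):
        # 10 subjects (5 per gender) x 5 visits, no dropout -> exactly 50 rows
        cfg = make_config(groups={"sHC": 3, "sMCI": 2}, dropout_prob=0.0,
                          visit_months=(0, 6, 12, 18, 24), seed=0)
        cohort, _ = generate_cohort(cfg)
        assert len(cohort) == 50
        assert cohort["subject_id"].nunique() == 10

    def test_noise_free_values_lie_on_subject_lines(self, noise_free_cohort):
        cfg, cohort, truth = noise_free_cohort
        rois = cfg.roi_names
        for sid, sub in cohort.groupby("subject_id"):
            sub = sub.sort_values("visit_month")
            gender = sub["gender"].iloc[0]
            p = truth.params[gender]
            expected = (truth.intercepts.loc[sid].to_numpy()[None, :]
                        + np.outer(sub["age_years"], p.slopes)
                        + np.outer(sub["educ_years"], p.educ_effects))
            np.testing.assert_allclose(sub[rois].to_numpy(), expected,
                                       atol=1e-12)
            # equivalently: linear interpolation between any two visits is exact
            y = sub[rois].to_numpy()
            a = sub["age_years"].to_numpy()
            mid = y[0] + (y[-1] - y[0]) * (a[1] - a[0]) / (a[-1] - a[0])
            np.testing.assert_allclose(y[1], mid, atol=1e-10)

    def test_determinism_same_seed_byte_identical(self):
        cfg = make_config(seed=1, groups={"sHC": 5, "cAD": 5})
        c1, _ = generate_cohort(cfg)
        c2, _ = generate_cohort(make_config(seed=1, groups={"sHC": 5, "cAD": 5}))
        assert cohort_to_csv_bytes(c1) == cohort_to_csv_bytes(c2)

    def test_different_seed_differs(self):
        a, _ = generate_cohort(make_config(groups={"sHC": 5}, seed=1))
        b, _ = generate_cohort(make_config(groups={"sHC": 5}, seed=2))
        assert cohort_to_csv_bytes(a) != cohort_to_csv_bytes(b)

    def test_monotone_dropout_and_conversion_visit_realized(self):
        cfg = make_config(groups={"cAD": 40, "cMCI": 40}, dropout_prob=0.3, seed=3)
        cohort, truth = generate_cohort(cfg)
        schedule = list(cfg.visit_months)
        for sid, sub in cohort.groupby("subject_id"):
            months = sorted(sub["visit_month"])
            # monotone: realized visits are a prefix of the schedule
            assert months == schedule[:len(months)]
            conv = truth.conversion_month[sid]
            assert conv in months and conv > 0

    def test_dx_trajectories_match_group(self, default_cohort):
        _, cohort, truth = default_cohort
        for sid, sub in cohort.groupby("subject_id"):
            sub = sub.sort_values("visit_month")
            group = truth.subjects.loc[sid, "group"]
            dx = list(sub["dx_age"])
            if group == "sHC":
                assert set(dx) == {"NL"}
            elif group == "sMCI":
                assert set(dx) == {"MCI"}
            elif group == "sAD":
                assert set(dx) == {"Dementia"}
            elif group == "cMCI":
                assert dx[0] == "NL" and dx[-1] == "MCI" and "Dementia" not in dx
            else:
                assert dx[0] == "MCI" and dx[-1] == "Dementia"

    def test_healthy_csf_mostly_normal(self, healthy_cohort):
        _, cohort, _ = healthy_cohort
        base = cohort[cohort["visit_month"] == 0]
        profiles = [classify_csf_profile([ab], [tv])
                    for ab, tv in zip(base["csf_abeta"], base["csf_tau"])]
        assert np.mean([p == "normal" for p in profiles]) >= 0.9

    def test_empirical_slopes_match_truth(self, healthy_cohort):
        # per-subject OLS slopes average to the true slope within 3 MC SE
        cfg, cohort, truth = healthy_cohort
        sub_f = cohort[cohort["gender"] == "F"]
        p = truth.params["F"]
        for j, roi in enumerate(cfg.roi_names[:6]):
            slopes = []
            for _, s in sub_f.groupby("subject_id"):
                a = s["age_years"].to_numpy()
                slopes.append(np.polyfit(a, s[roi].to_numpy(), 1)[0])
            slopes = np.asarray(slopes)
            se = slopes.std(ddof=1) / np.sqrt(len(slopes))
            assert abs(slopes.mean() - p.slopes[j]) < 3 * se + 1e-12

    def test_noise_free_intercept_map_is_exact_regression(self):
        # with no intercept noise, regressing true vr on true qvr intercepts
        # recovers GroundTruth's latent-factor map exactly
        cfg = make_config(groups={"sHC": 30}, intercept_noise_sd=0.0,
                          obs_noise_sd=0.0, dropout_prob=0.0, seed=9)
        _, truth = generate_cohort(cfg)
        for gender in ("F", "M"):
            p = truth.params[gender]
            ids = [s for s in truth.intercepts.index if s.startswith(gender)]
            y0 = truth.intercepts.loc[ids]
            X = y0.iloc[:, p.qvr_index].to_numpy()
            Y = y0.iloc[:, p.vr_index].to_numpy()
            B = np.linalg.lstsq(X, Y, rcond=None)[0]
            np.testing.assert_allclose(B, p.qvr_to_vr_map, atol=1e-8)
            np.testing.assert_allclose(X @ p.qvr_to_vr_map, Y, atol=1e-8)

    def test_destandardize_applies_affine_constants(self):
        base = make_config(groups={"sHC": 4}, dropout_prob=0.0, seed=13)
        plain, truth_p = generate_cohort(base)
        dest = make_config(groups={"sHC": 4}, dropout_prob=0.0, seed=13,
                           destandardize=True)
        scaled, truth_s = generate_cohort(dest)
        roi = base.roi_names[0]
        for gender in ("F", "M"):
            p = truth_s.params[gender]
            rows = scaled["gender"] == gender
            np.testing.assert_allclose(
                scaled.loc[rows, roi],
                p.destd_offset[0] + p.destd_scale[0] * plain.loc[rows, roi],
                rtol=1e-10)


class TestRoundTrip:
    def test_write_read_lossless(self, tmp_path, default_cohort):
        cfg, cohort, _ = default_cohort
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path, cfg)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back, cohort.reset_index(drop=True), check_exact=True)
        assert (tmp_path / "cohort.yaml").exists()

    def test_missing_age_column_is_schema_error(self, tmp_path, default_cohort):
        _, cohort, _ = default_cohort
        path = tmp_path / "bad.csv"
        cohort.drop(columns=["age_years"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="age_years"):
            read_cohort(path)

    def test_non_numeric_biomarker_cell_cites_row(self, tmp_path, default_cohort):
        _, cohort, _ = default_cohort
        bad = cohort.head(10).copy()
        bad["roi_000"] = bad["roi_000"].astype(object)
        bad.loc[bad.index[4], "roi_000"] = "oops"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="row 5"):
            read_cohort(path)
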