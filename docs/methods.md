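# Methods

## The normative model

Each regional biomarker (ROI) is modelled on the null cohort — stable,
CSF-normal controls, separately per gender — with a random-intercept linear
mixed-effects model on the standardized scale:

    y_ijr = β₁ʳ + β_aʳ · age_ij + β_eʳ · educ_i + υ_ir + ε_ijr

with υ_ir ~ N(0, ψ_r) a subject-level intercept deviation and ε i.i.d.
N(0, σ²_r) within subject (homoscedastic identity error covariance — the
minimal structure consistent with a random-intercept-only model). Estimation
is REML via `statsmodels.MixedLM`. Age enters raw in years, deliberately
uncentered: the model intercept is then literally the subject's extrapolated
value at age 0, the y₀ used by the transfer and residual stages, and the
expected-value arithmetic stays a plain dot product. The conditioning cost
of an age-60–95 design column is negligible at this scale.

The p-value attached to β_a is a Wald z-test (estimate/SE against the
standard normal). The reference implementation of mixed models in this field
deliberately reports no p-values because the reference distribution is
contentious for small samples; the Wald test is the simplest defensible
choice at 150+ observations and is used only for the variant/quasi-variant
screen, not for inference proper.

**Variant/quasi-variant rule.** A ROI is *variant* (vr) when |β_a| > 0.01
SD/year **and** p ≤ 0.05, *quasi-variant* (qvr) when |β_a| ≤ 0.01. Because
ROIs are standardized to unit variance, 0.01 in model units is exactly "1%
of the ROI's SD per year". The two definitions do not exhaust the plane: a
ROI with a large but non-significant slope is neither, and is excluded from
both sets and from downstream features (logged). This happens for a few
borderline ROIs per run at null-cohort sizes around 20 per gender.

**Minimum data.** ROIs observed at fewer than two distinct ages, or
constant on the null cohort, are dropped before/at standardization.

## Intercept transfer (PLSR)

The identification assumption of the whole method: quasi-variant ROIs barely
change with age *and are assumed undistorted by disease*, so a patient's qvr
intercepts can be estimated from their own visits, and a map fitted on
healthy subjects can then predict the vr intercepts the patient *would have
if healthy*. The map is a partial least squares regression from the null
cohort's qvr intercept table to its vr intercept table, computed with the
cross-product ("kernel") PLS algorithm: per component, the X-weight is the
dominant left singular direction of the current X'Y (an exact m×m
eigendecomposition, not an iterative inner loop), deflated through the
X-loadings only. This is algebraically equivalent to NIPALS PLS2; the test
suite cross-checks predictions against scikit-learn's NIPALS implementation
and against a closed-form single-component construction.

The number of components is selected by leave-one-subject-out
cross-validation minimizing the root-mean-squared prediction error pooled
over all vr responses — one shared component count for the whole map, since
a single model serves all responses. The LOO error curve is stored in the
model bundle.

**New-subject qvr intercepts.** For a subject outside the null cohort,
y₀ for each qvr ROI is the mean over their visits of
y_ij − β_a·age_ij − β_e·educ_i, i.e. the expected-value relation solved for
y₀ with the null model's fixed effects. This rule is an interpretation (the
estimation procedure for new subjects is otherwise underdetermined): it
inverts the prediction equation exactly, is unbiased under the null model,
and uses all available visits. Missing qvr ROIs are imputed with the null
cohort's mean intercept for that ROI (with a logged count). Note the mean
intercept is *not* 0 even on the standardized scale: y₀ extrapolates to age
0, so β₁ ≈ −β_a·mean(age); the imputation is neutral only relative to the
PLSR centering, which is the property that matters.

## Residuals and features

Expected values: ŷ_ijr = y₀_ir + β_a·age_ij + β_e·educ_i, with vr
intercepts from the PLSR map and qvr intercepts from the subject's own
adjusted observations. Residuals e = y − ŷ form the matrix E; the retained
submatrix E_v keeps every vr column and any qvr column not identically zero
(|e| > 1e-12 somewhere). The asymmetry is deliberate: vr residuals are the
method's signal and always enter; qvr residuals vanish exactly for subjects
with a single visit (the mean-inversion rule fits one point perfectly) and
only carry within-subject scatter otherwise. Excluded-ROI columns are
dropped. Feature sets: F1 = E_v columns + age; F2 = F1 + CDR global + MMSE
(rows lacking either score are dropped from F2 only).

## Classification and evaluation

Radial-kernel SVM, misclassification cost C = 1, kernel width by the
standard 1/(n_features · Var) heuristic (`gamma='scale'`), features scaled
to *training-split* statistics to avoid leakage. Evaluation is 10 repeated
random subject-stratified 60/40 splits: the 60/40 subject-level split sizes
are the operational contract, and grouping by subject prevents a
longitudinal subject's visits from appearing on both sides. Sensitivity and
specificity treat the disease class of each pair (AD, MCI, AD respectively)
as positive. Under the `last` labelling mode the MCI-vs-AD pair is
restricted to sMCI vs cAD subjects — the prodromal-AD discrimination.

**Advancement.** For a converter (a subject whose visit diagnosis differs
from their final class somewhere), per test repeat:

    advancement = (age at first clinical visit diagnosed as the final class)
                − (age at earliest visit predicted as the final class while
                   the visit diagnosis is still pre-conversion)

counted only when such an earlier correct prediction exists; per-subject
values are the mean over their test repeats, averaged within gender ×
five-year strata of the clinical conversion age. Subjects never correctly
predicted before conversion contribute nothing. The formula is a
formalization of the quantity's verbal definition ("years by which the
method leads the clinical diagnosis"); no closed-form definition exists in
the literature the method comes from.

## The synthetic cohort generator

The generator emulates the *structure* of an ADNI-like study, not its
anatomy. Per gender and trajectory group (sHC, sMCI, cMCI, sAD, cAD):

| parameter | default | meaning |
|---|---|---|
| `n_subjects_per_group` | 40 per gender | comparable to the study's per-gender arms |
| `visit_months` | 0,6,12,18,24,36,48,60 | the study's schedule |
| `dropout_prob` | 0.08/visit | monotone attrition, ~½ of subjects complete |
| `n_vr_rois` / `n_qvr_rois` | 15 / 12 | desk-scale stand-in for 166 measures |
| `slope_vr_range` | 0.02–0.08 SD/yr | atrophy/expansion rates; hippocampal-like at the top |
| `slope_qvr_max` | 0.003 SD/yr | clearly inside the 1%/yr boundary |
| `educ_effect_range` | 0–0.01 SD/yr-of-educ | small protective effect |
| `latent_dim` | 3 | shared anatomy factors linking qvr and vr intercepts |
| `intercept_noise_sd` | 0.1 | ROI-specific intercept part not explained by factors |
| `obs_noise_sd` | 0.12 | measurement + visit-level noise; reflects the high test-retest reliability of automated morphometry relative to population SD |
| `disease_offset` | 1.0 SD | vr-ROI shift in AD (MCI: × `mci_severity` = 0.5) |
| `disease_slope_accel` | 0.05 SD/yr | extra atrophy after onset |
| `biomarker_lead_visits` | 0 | visits by which biomarker onset precedes the clinical conversion |
| `csf_available_prob` | 0.6 | fraction of subjects with CSF measured (the study had CSF for ~half its cohort; subjects without CSF have unknown profile and stay in the early-prediction cohort) |

Subject intercepts are y₀ = L·f + noise with f ~ N(0, I) shared across all
ROIs and L row-normalized so every ROI has intercept variance 0.5 — this
guarantees an exact low-rank linear qvr→vr map (stored in `GroundTruth`)
and comparable subject spread across regions. Baseline age ~ U[60, 90)
populates all five-year strata; age at visit = baseline + months/12.
Conversion visits are uniform over a converter's realized non-baseline
visits (converters are guaranteed ≥ 2 visits); stable patients carry the
disease effect from baseline. CSF is drawn at baseline only from per-group
two-component mixtures with a shared normal/abnormal indicator, giving the
bimodal amyloid distribution and ≥ 90% CSF-normal stable controls. MMSE and
CDR are drawn per visit from diagnosis-dependent ranges, making F2
informative by construction. Biomarkers are generated directly on the SD
scale; `destandardize=True` exports them through per-ROI affine constants so
the pipeline's standardization step is exercised non-trivially.

**What passing tests do and do not show.** The generator's world is linear,
Gaussian, and has homogeneous disease effects confined to variant ROIs; the
null cohort's pooled SD is close to (not exactly) 1 because age trends and
intercept spread coexist. Real data add site effects, nonlinear
trajectories, heterogeneous severity, diagnosis noise and informative
dropout — none of which are modelled. Green tests therefore certify the
*pipeline's correctness and calibration under its own assumptions* (slope
recovery, type-I error, transfer exactness, leakage-free evaluation,
lead recovery), not clinical performance; the near-ceiling HC-vs-AD
accuracies are a property of the default separation (Bayes error ≈ 0), not
a clinical claim.

## Numerical choices

- Standardization uses the pooled sample SD (ddof = 1); constant ROIs are
  dropped, never NaN-propagated. Applying null-cohort constants to new
  cohorts is mandatory — new cohorts are never self-standardized.
- Non-convergent mixed-model fits are excluded from both ROI sets (logged);
  a ψ→0 boundary fit is kept.
- The kernel-PLS loop stops early if a weight or score norm underflows
  (collinear/degenerate predictors), returning fewer components.
- Ties and determinism: every stochastic stage (generator, splits) takes an
  explicit seed; two runs with equal configuration are byte-identical, which
  the suite asserts at file level.
- Cohort CSVs are written at %.17g so write→read round-trips are exact
  (parsing goes through numpy's exact float parser, not pandas' fast path).

## Problem sizes

Default runs use 400 subjects (40 per group per gender), 27 ROIs, and a
~2,500-row visit table; the statistical calibration tests use 200 simulated
ROIs for bias/coverage and 1,000 zero-slope ROIs for the type-I error of the
variant screen, at 40 subjects × 8 visits each. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bounds while keeping a full
suite run in a few minutes on one CPU.

## Known limitations

- Random intercepts only: subjects share each ROI's slope. Random slopes
  are a natural extension but change the y₀ extraction and the transfer's
  meaning.
- The Wald z p-value is mildly liberal for small null cohorts; the type-I
  test pins it to [3.5%, 6.5%] at the default design, not beyond.
- The age-0 extrapolation embeds fixed-effect estimation error
  (≈ SE(β̂_a)·mean age per ROI). It cancels between the transfer and
  residual stages at observed ages, but absolute y₀ values should not be
  interpreted on their own.
- The qvr-undistorted-by-disease assumption is built into the generator
  (affected set ⊆ vr); the pipeline cannot detect its violation, only
  inherit the resulting bias.
- CSF profiling uses baseline-only values in the generator; the
  all-observations rule is implemented but exercised with one observation
  per subject by default.
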