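# normbrain

Age-based normative ("null") modeling of longitudinal brain biomarkers, and
residual-based classification and early prediction of conversion to MCI and
Alzheimer's disease (AD).

## The problem

Brains shrink with healthy aging, and the regions that shrink overlap with
the regions AD attacks. To tell disease apart from aging, this package
models what *healthy* aging looks like — per region, per gender — and scores
every new subject by how far their MRI-derived regional biomarkers deviate
from that healthy expectation. The deviations (residuals), not the raw
measurements, feed the classifiers. It is aimed at researchers working with
ADNI-style longitudinal cohorts: one row per subject-visit with age,
education, per-visit clinical diagnosis (NL / MCI / Dementia), MMSE, CDR
global score, baseline CSF amyloid-beta and total tau, and a block of
FreeSurfer-style regional volumes/thicknesses ("ROIs").

## The method

**Stage A — labelling.** Each subject gets a trajectory class `dx_last`
(sHC, sMCI, cMCI, sAD, cAD) from their visit-by-visit diagnoses, and a CSF
profile: *normal* iff Aβ₁₋₄₂ ≥ 192 pg/mL **and** τ ≤ 93 pg/mL at every
measurement. Stable controls with a normal CSF profile form the *null-model
cohort*; everyone else is the *early-prediction cohort*.

**Stage B — the null model (per gender).** Each ROI r, standardized to the
null cohort's mean/SD, is fitted with a random-intercept linear
mixed-effects model

```
y_ijr = β₁ʳ + β_aʳ·age_ij + β_eʳ·educ_i + υ_ir + ε_ijr,
υ_ir ~ N(0, ψ_r),  ε_ijr ~ N(0, σ²_r)
```

(REML). ROIs with |β_a| > 0.01 SD/year and Wald p ≤ 0.05 are *variant* (vr);
ROIs with |β_a| ≤ 0.01 are *quasi-variant* (qvr). Each null subject's
intercept y₀ = β₁ + υ̂ is extracted, and a kernel-algorithm PLS regression
(components chosen by leave-one-out error) maps qvr intercepts → vr
intercepts.

**Stage C — residuals and prediction.** For a new subject, qvr intercepts
come from their own visits (y₀ = mean of y − β_a·age − β_e·educ), vr
intercepts through the PLSR map — so disease, which hits the vr side, cannot
contaminate them. Expected values ŷ = y₀ + β_a·age + β_e·educ give residuals
e = y − ŷ (matrix **E**, retained columns **E_v**). Radial-kernel SVMs
(C = 1) on feature sets F1 (residuals + age) and F2 (+ MMSE, CDR) run three
binary experiments — HC-vs-AD, HC-vs-MCI, MCI-vs-AD — labelled either by the
visit diagnosis (classification) or by `dx_last` (early prediction, where
MCI-vs-AD contrasts stable MCI with MCI-to-AD converters). Evaluation uses
10 random subject-grouped 60/40 splits, so no subject's visits straddle
train and test. For converters, the *advancement* is how many years the
first correct pre-conversion prediction of the final class precedes the
clinical diagnosis change.

Because the original cohort is access-restricted, the package ships a
synthetic-cohort generator (`normbrain.synthetic_cohort`) that reproduces
the study's data structure — visit schedule, dropout, latent-factor subject
intercepts shared between vr and qvr ROIs, disease offsets on vr ROIs,
group-wise CSF mixtures — with full ground truth, so every stage is testable.

## Worked example

The analysis is a chain of numbered drivers writing to `results/`:

```
python analysis/01_generate_cohort.py
python analysis/02_label_subjects.py
python analysis/03_fit_null_models.py
python analysis/04_compute_residuals.py
python analysis/05_classification.py
python analysis/06_early_prediction.py
```

Representative output (seeds fixed in the scripts):

```
null-model cohort: 44 subjects (266 visits); early-prediction cohort: 356 subjects
F: 22 null subjects; 15 variant, 11 quasi-variant, 1 excluded ROIs; PLSR components = 4
F: mean variant-ROI residual by trajectory class (SD units):
  cAD -0.654   cMCI -0.307   sAD -1.249   sHC 0.002   sMCI -0.623
accuracy averaged over genders:
  F1  HC-vs-AD 100.0   HC-vs-MCI 80.8   MCI-vs-AD 100.0
  F2  HC-vs-AD 100.0   HC-vs-MCI 96.3   MCI-vs-AD 100.0
mean advancement over 48 converters: 1.79 years (biomarker lead built in: 2 annual visits)
```

Reading this: stable controls sit on the null model (mean residual ≈ 0);
converters and patients deviate increasingly negatively; adding the
cognitive scores (F2) lifts the one experiment that is off the ceiling; and
when the generator plants the biomarker onset two annual visits before the
clinical conversion, the classifier recovers a ≈ 2-year prediction lead.

The same workflow is scriptable through the CLI (`normbrain generate`,
`label`, `fit-null`, `infer-intercepts`, `residuals`, `evaluate`,
`run-all`) or the library (`normbrain.run_pipeline`).

## Layout

- `src/normbrain/` — the library: `synthetic_cohort`, `diagnosis_labeling`,
  `null_model`, `intercept_inference`, `residual_engine`, `classifier`,
  `bundle`, `pipeline`, `cli`.
- `analysis/` — the numbered drivers above.
- `tests/` — unit, property and end-to-end statistical tests.
- `docs/methods.md` — modeling assumptions, generator design, parameter
  defaults and limitations.
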