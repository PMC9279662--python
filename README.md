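# rectomics

Multiparametric-MRI radiomics for long-term prognosis in rectal cancer:
a from-scratch pipeline that predicts 5-year overall survival (OS) in
stage II–III disease from eight MRI-derived channels (T1w, T2w, ADC,
dynamic contrast-enhanced phases L2–L4 and two subtraction images) plus
routine clinical covariates.

The package is aimed at quantitative-imaging researchers who want a fully
inspectable, testable implementation of a classic radiomics survival
workflow — every stage from voxel-level feature engineering to the final
nomogram is open code, and a built-in synthetic-cohort generator makes the
whole pipeline runnable and verifiable without any patient data.

## What it computes

1. **Preprocessing** — per channel z-score intensity normalization,
   trilinear resampling to a 1 mm isotropic grid, 1 mm morphological
   erosion of the tumor mask (discrete-ball structuring element) and
   64-level min–max gray quantization inside the eroded ROI.
2. **Feature extraction** — a fixed 4,686-slot layout per patient:
   6 shape descriptors, and per channel 14 histogram statistics,
   7 Galloway run-length (GLRLM) features and 44 co-occurrence (GLCM)
   features (22 Haralick-style features × distances 1 and 2 voxels, each
   averaged over the 13 unique 3D directions) on the native volume, plus
   the same 65 first-order/texture features on each of the 8 sub-bands of
   a one-level 3D Haar wavelet transform:
   6 + 8 × (14 + 51 + 520) = 4,686.
3. **Signature construction** — Spearman redundancy filtering
   (|ρ| > 0.90), L1-penalized logistic regression tuned by 100 × 4-fold
   cross-validated binomial deviance under a <11-feature cap
   (the 10:1 events-per-variable rule), and the radiomics score

   Rad_score = σ(β₀ + Σₖ βₖ·xₖ),  σ(x) = 1 / (1 + e^(−x)).

   The frozen 8-term reference signature (intercept −0.664) from the
   study this package re-implements is bundled as
   `published_signature()`.
4. **Evaluation** — four logistic risk models (TNM stage only; clinical;
   Rad_score only; combined), ROC AUC with stratified-bootstrap CIs,
   Harrell's C-index, decile Hosmer–Lemeshow calibration, a points-based
   nomogram, and Kaplan–Meier curves with a log-rank test after splitting
   at the Youden-optimal Rad_score cutoff.
5. **Reproducibility** — ICC(2,1) agreement of every feature under
   simulated re-segmentation (mask jitter), with the standard
   interpretation bands and an ICC > 0.6 pass gate.

A synthetic-cohort module generates multiparametric studies whose tumor
texture, histogram shape and mean intensity differ between survivor
groups by configurable effect sizes, and clinical tables drawn from the
group-conditional marginal counts of the 165-patient reference cohort
(114 primary / 51 test, 75% 5-year OS).

## Worked example

```python
from rectomics import (CohortConfig, PipelineConfig, SelectionConfig,
                       run_pipeline)

config = PipelineConfig(
    cohort=CohortConfig(n_patients=50, volume_shape=(16, 16, 16),
                        tumor_radius_range_mm=(5.0, 6.5),
                        channels=("T1w", "L2"), seed=7),
    selection=SelectionConfig(repeats=5, n_lambdas=20, seed=7),
    g=16, n_bootstrap=200, seed=7,
)
report = run_pipeline(config)
for name, cohorts in report.auc.items():
    auc, lo, hi = cohorts["primary"]
    print(f"{name:10s} AUC {auc:0.2f} (95% CI {lo:0.2f}-{hi:0.2f})")
```

prints (seed 7, 35 primary / 15 test patients):

```
tnm        AUC 0.68 (95% CI 0.44-0.87)
clinical   AUC 0.96 (95% CI 0.89-1.00)
radiomics  AUC 1.00 (95% CI 1.00-1.00)
combined   AUC 1.00 (95% CI 1.00-1.00)
```

i.e. on a small planted-signal cohort the radiomics signature separates
the survivor groups perfectly in-sample, TNM stage alone is far weaker,
and the clinical model sits in between — the qualitative pattern the
pipeline is designed to quantify. (At this toy size n = 35 the in-sample
AUCs saturate; the replicate-scale experiments in `rectomics.experiments`
use n = 200, where the held-out radiomics AUC averages ≈ 0.9 and the
ordering combined ≥ radiomics > clinical > TNM is assessed properly.)

There is also a CLI: `rectomics simulate|extract|select|score|all`
(`rectomics all --n-patients 50 --out results/` runs everything and
writes features, signature, scores and the evaluation report).

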