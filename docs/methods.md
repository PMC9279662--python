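# Methods

This note documents the models, conventions and design choices behind
`rectomics`, and what its synthetic experiments do and do not show.

## The problem and the pipeline

The package addresses long-term (5-year overall survival, OS) prognosis in
stage II–III rectal cancer from pre-treatment multiparametric MRI. A
patient is represented by eight co-registered channels — anatomical T1w
and T2w, the diffusion-derived ADC map, three dynamic contrast-enhanced
phases (L2 at 15 s, L3 at 60 s, L4 at 120 s post-injection) and two
subtraction images (L3−L1, L4−L1, formed on raw intensities before any
normalization) — plus a binary tumor mask and a clinical table. The 5-year
OS endpoint is binary: survival ≥ 60 months from resection.

Stages: preprocess → extract 4,686 features → Spearman + LASSO selection
on the primary cohort → sigmoid Rad_score → four logistic risk models →
discrimination / calibration / nomogram / Kaplan–Meier evaluation. All
fitting decisions (redundancy filter, λ, signature coefficients, Youden
cutoff) are made on the primary cohort only; the test split is scored
once.

## Preprocessing conventions

* **z-score region**: mean/SD estimated over the nonzero support of the
  whole volume, applied globally. ROI-internal statistics are captured
  separately by the histogram features.
* **Resampling**: trilinear for intensities, nearest-neighbour for masks,
  output shape `round(n·spacing/target)`; an already-isotropic input is
  returned voxel-identical.
* **Erosion**: 1 mm discrete ball (offsets with center distance ≤ radius
  in mm at the actual spacing). Erosion that empties the mask is an error
  ("tumor too small"), not a silent fallback.
* **Quantization**: fixed bin count (default G = 64) over the in-ROI
  min–max, `level = min(G, ⌊G·(x−min)/(max−min)⌋ + 1)`; a constant region
  maps to level 1. Quantization is therefore invariant to positive affine
  intensity rescaling. Each wavelet sub-band is quantized independently,
  since sub-band value ranges differ by construction.

## Feature definitions

* **Morphology (6, computed once per patient)**: volume (voxel count ×
  voxel volume); surface area from a marching-cubes mesh of the mask
  lightly smoothed with a σ = 0.5 voxel Gaussian (the raw binary mesh
  overestimates smooth-tumor area by ~5–10%; thin masks fall back to the
  binary mesh); circularity/sphericity π^⅓(6V)^⅔/A; compactness
  V/(√π·A^{3/2}); convexity V/V_hull with the hull rasterized over voxel
  centers (exactly 1 for convex digitized bodies); irregularity
  A/A_sphere = 1/circularity.
* **Histogram (14)**: min, mean, max, P10…P90 (linear interpolation
  between order statistics), Fisher skewness g₁ and excess kurtosis g₂
  from biased sample moments; constant samples define both as 0.
* **GLRLM (7)**: Galloway SRE, LRE, GLN, RLN, RP, LGRE, HGRE; run
  matrices per direction, features averaged over the 13 unique 3D
  directions; RP uses the in-mask voxel count Np.
* **GLCM (22 × 2 distances)**: autocorrelation, cluster prominence /
  shade / tendency, contrast, correlation, difference average / entropy /
  variance, dissimilarity, energy, joint entropy, homogeneity (inverse
  difference moment), informational measures of correlation 1 and 2,
  inverse difference, maximum probability, sum average / entropy /
  variance, variance, inverse variance. Matrices are symmetric
  (pair-accumulated both ways), normalized per direction; features are
  computed per direction and averaged over the 13 directions, separately
  for distances 1 and 2. Logs are base 2. Degenerate directions (no valid
  pair, or a single occupied cell) use the constant-ROI convention:
  entropy-, contrast- and correlation-type features 0, maximum
  probability and energy 1.
* **Wavelet (8 × 65 per channel)**: one-level separable 3D Haar transform
  with periodized boundaries (orthogonal, so input energy equals the sum
  of sub-band energies, which the tests check to 1e-8). Sub-band labels
  map filter order to axes as L/H per (X, Y, Z); coefficients are
  block-replicated back to the input grid so the eroded mask applies
  unchanged.

Two numerically identical texture paths exist: a per-direction reference
implementation and a vectorized all-directions fast path used by the
extractor; the test suite asserts their equality to 1e-10, and both are
checked against brute-force pair/run enumeration oracles.

## Selection and signature

The Spearman filter scans features in the deterministic layout order
(channel, sub-band, family, name, distance) and drops a feature whose
|ρ| with any already-retained feature exceeds 0.90; constant columns are
dropped first with a logged reason. The LASSO stage standardizes columns
internally (coefficients are mapped back to the original scale), builds a
30-point descending geometric λ grid from the data-driven λ_max, and
averages held-out binomial deviance over repeated stratified k-fold CV
(default 100 × 4). λ is the deviance minimizer, moved toward stronger
penalty along the path if needed until fewer than 11 features remain
(the 10:1 events-per-variable rule for a ~114-patient cohort). The
signature is `sigmoid(intercept + Σ βk·xk)`; higher scores mean better
survival odds.

`published_signature()` freezes the 8-term reference model (intercept
−0.664; coefficients +0.106, −0.029, +0.022, +0.067, +0.05, −0.082,
+0.05, −0.092). Where the reference description's prose feature list and
its printed formula disagree, the formula is authoritative; the
discrepancy is recorded in the model's metadata note. The LAVA2/LAVA3
channel names resolve to the raw DCE phases L2/L3, and the GLCM terms
carry distance 1 (unstated in the source formula).

## Risk models and evaluation

Four logistic models: `tnm` (stage only), `clinical` (stage, gender, CEA,
tumor deposits, lymph-node ratio, yN), `radiomics` (Rad_score only),
`combined` (clinical + Rad_score). Categorical covariates are one-hot
encoded against fixed reference levels (stage IIA, male, N0, surgery
LAR, …). Fits are maximum-likelihood via statsmodels; (quasi-)separation
is detected (non-finite or |β| > 50) and either raised or, when allowed,
replaced by a weak ridge (C = 10 on standardized columns, mapped back)
and flagged.

* **AUC**: tie-averaged rank statistic; CI by stratified bootstrap
  (default 2,000 replicates, seeded). **C-index**: identical to AUC for a
  binary endpoint (ties ½), kept as a named operation because it is the
  nomogram's reported discrimination measure.
* **Hosmer–Lemeshow**: decile-of-risk groups (qcut, tie-collapsed groups
  merged and logged), χ² against g−2 degrees of freedom — the reference
  distribution for fitted logistic predictions. The package's calibration
  control therefore simulates *fitted* models; applying the g−2 test to
  externally given true probabilities would be anti-conservative.
* **Nomogram**: per-predictor points 100·|β·(value−ref)|/M with
  M = max |β·range| over the design columns and the reference at the
  low-risk end of each observed range; total points map to probability
  through the logistic at the reference linear predictor. The round-trip
  identity (points path ≡ direct model probability) is asserted to 1e-9.
* **Kaplan–Meier**: risk groups split at the Youden-optimal Rad_score
  cutoff frozen on the primary cohort. Deaths (all before 60 months by
  construction) are events at their survival time; survivors are censored
  at their recorded last follow-up (60–121 months). No post-60-month
  deaths are modeled. Log-rank p via lifelines; a no-event stratification
  reports "not applicable" rather than a number.
* **Cohort comparison**: one-way ANOVA for continuous covariates and a
  hand-written exact Fisher test for 2×k categorical tables (multivariate
  hypergeometric enumeration; scipy covers only 2×2, against which the
  implementation is cross-checked).

## Reader-agreement analysis

ICC(2,1) — two-way random effects, absolute agreement, single rater —
from the explicit mean-square decomposition; zero between-subject
variance returns 0 by convention. A second reader is emulated by mask
jitter: a random sub-voxel-scale translation plus a random dilation or
erosion up to the jitter radius. Band interpretation: 0.81–1 almost
perfect, 0.61–0.80 substantial, 0.41–0.60 moderate, 0.21–0.40 fair,
below 0.21 poor; ICC > 0.6 passes. Features failing the gate are
reported, not excluded, by default.

## The synthetic cohort: what it emulates

Each patient gets an axis-aligned ellipsoidal tumor (semi-axes drawn from
the configured radius range) in each channel, over an i.i.d. Gaussian
background with channel-specific base intensity. Three planted effects
distinguish the OS groups, each through a per-patient latent
z ~ N(effect·group, 1), so the configured effect size is the
between-group separation in within-group SDs (a Cohen's d on the
generative parameter) and the groups overlap as real cohorts do:

* **texture_correlation_length** (default d = 2.5): tumor texture is
  unit-variance Gaussian noise smoothed with σ = 0.5 + 0.35·z voxels —
  movable by GLCM/GLRLM features;
* **histogram_skewness_shift** (default d = 1.5): a shifted log-normal
  intensity component added to the DCE phases — movable by histogram
  skewness/percentiles;
* **mean_intensity_shift** (default d = 1.2): an ADC tumor mean offset.

Defaults were calibrated once so that the recovered held-out radiomics
AUC lands in the high-0.8s/low-0.9s — the discrimination regime of the
reference study — and then frozen.

Clinical covariates are sampled conditional on the OS label from the
pooled group-specific count tables of the 165-patient reference cohort,
which reproduces its marginal frequencies and plants the weak clinical
prognostic signal those tables imply. Exceptions for coherence: clinical
N-stage is derived from stage (II ⇔ N0), pathological node counts from
yN (N0 → 0, N1 → 1–3, N2 → ≥ 4 positive nodes, LNR = positive/total),
and survival months from the group (survivors ~N(82, 14²) clipped to
[60, 121]; non-survivors ~N(31, 15²) clipped to [5, 59]). CEA's
group-conditional log-mean separation is attenuated relative to its
printed marginal means because all covariates are sampled independently
here: real covariates are cross-correlated, and full marginal separation
on every one of them would overstate the joint clinical discrimination
relative to the reference clinical model.

What the generator does **not** emulate: MRI physics (bias fields, coil
profiles, motion, partial volume), irregular or infiltrative tumor
shapes, spatial correlation between channels, joint clinical covariate
structure beyond the coherence rules above, and post-60-month mortality.
A passing replicate suite therefore shows that the pipeline recovers
planted texture/histogram/mean effects under realistic noise and honest
train/test separation — not that it would achieve the same AUC on real
rectal-cancer MRI.

## Experiment problem sizes

The seed-replicated experiments in `rectomics.experiments` run at a
reduced problem size chosen for single-CPU tractability while preserving
every pipeline stage: n = 200 patients per replicate (split 138/62 in the
114:51 ratio of the reference cohort), 16³ volumes at 1 mm with
5–6.5 mm tumor radii, a single DCE channel (L2, which carries both the
texture and skewness effects), 16 gray levels, and 5 × 4-fold CV with a
25-point λ grid in the LASSO. The model-ordering check compares nested
models (combined vs radiomics; clinical vs TNM) in-sample — adding
covariates to a maximum-likelihood logistic fit cannot meaningfully hurt
in-sample discrimination, so this isolates the intended contrast — and
the non-nested radiomics-vs-clinical comparison on the held-out split,
where overfit cannot reverse it. Full-scale (8-channel, 32³, G = 64)
extraction is exercised by the structural-count checks and the default
`PipelineConfig`.

## Known limitations

* The 22-name GLCM set is one canonical choice; other radiomics software
  enumerates slightly different 44-feature sets.
* Haar is the default wavelet; other families change sub-band features
  (configurable via `extract_all(..., wavelet=...)`).
* The greedy Spearman filter is order-dependent by design (deterministic
  layout order); a different scan order retains a different, equally
  valid non-redundant subset.
* The penalized-separation fallback changes coefficient scale (weak
  ridge); affected fits are flagged `penalized=True`.
* The exact 2×k Fisher enumeration is exponential in k and intended for
  the small contingency tables of cohort description, not for large k.
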