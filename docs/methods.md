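# Methods

`gkradiomics` implements an MRI-radiomics outcome-prediction pipeline for
brain metastases treated with stereotactic (Gamma Knife) radiosurgery:
multi-contrast preprocessing, a fixed 1763-entry radiomic profile per
lesion, outcome labeling, two-step feature selection with class balancing,
an RBF-SVM classifier with Bayesian hyperparameter search, and bootstrap
model comparison.  Because no patient data ship with the package, every
stage is exercised on synthetic phantom cohorts whose planted statistical
structure is known exactly; this note records the models, the defaults, and
the design decisions behind both.

## Synthetic phantom cohorts (`synthgen`)

Each patient owns three co-registered contrasts (T1w, T1c, T2w) on a common
isotropic grid (default 48³ voxels at 1 mm) and 1–3 ellipsoidal lesions
with per-axis radii jittered ±30% around a 3–6 mm draw — non-spherical
shapes exercise the geometry features without mesh machinery.  Backgrounds
are smooth Gaussian anatomy fields shared across contrasts; lesions are
plateaus at contrast-specific intensities.

Planted structure, all deterministic under one seed:

- **Latent outcome class.**  A fixed quota `round(poor_fraction * n)` of
  patients (default 35%) is "poor"; lesions inherit their patient's class.
  A quota rather than iid draws keeps prevalence exact, which matters for
  the median-split property below.
- **Texture effect.**  Inside each mask, smoothed Gaussian noise
  (correlation length ≈ 2 voxels) is added with a class-dependent
  amplitude, default 0.15 (good) vs 0.9 (poor) in units of the
  lesion/background contrast step.  This produces GLCM-detectable
  heterogeneity differences — the mechanism the radiomics model is meant to
  pick up.  Equal amplitudes make the classes texture-indistinguishable.
- **Clinical effect.**  Binary covariates (KPS ≥ 90, extracranial
  metastases, primary-tumor control) come from thresholded latent Gaussians
  separated by configurable standardized effect sizes (defaults 0.8 / 0.8 /
  0.5), so a clinical-only model has real but imperfect power; the lesion
  count gets a class-dependent Poisson increment.
- **Follow-up volumes.**  Good lesions draw a volume ratio U(0.5, 1.05),
  poor lesions U(1.15, 2.0), so the >10% progression rule recovers the
  class; a configurable flip rate draws from the opposite class's ratio
  distribution.
- **Overall survival.**  Log-normal per class (default medians 20 vs 7
  months, σ = 0.45).  At flip rate 0 the drawn values are rank-matched to
  the classes (poor patients receive the lowest ranks), so with
  `poor_fraction = 0.5` a cohort-median split recovers the latent classes
  exactly; with a flip rate > 0, or any other prevalence, recovery is
  approximate — the median split always labels ~n/2 patients per side,
  which no overlapping class-conditional distribution can match exactly.

What the phantoms do **not** emulate: brain anatomy, acquisition physics,
bias fields, partial-volume effects, scanner variation, or any correlation
between lesion size and outcome beyond the planted ones.  Passing tests
therefore demonstrate that the pipeline recovers planted signal and stays
at chance under the null — not that the clinical effect sizes of real
cohorts are attainable.

## Preprocessing (`imgprep`)

Order: isotropic resampling (default 1×1×1 mm, trilinear; nearest-neighbour
for masks) → rigid co-registration of T1w/T2w onto T1c → whole-image
Z-score.  Registration uses a six-parameter Euler transform and Mattes
mutual information (32 bins, 25% random sampling) with a three-level
multi-resolution gradient-descent scheme; visual quality control is
replaced by a numeric flag (converged MI above −0.05 marks a failed pair).
Z-scoring uses whole-image statistics including background, and is
idempotent and monotone; constant volumes map to zeros with a warning.
Normalization is applied after any resampling into the T1c grid, a choice
documented here because either order is defensible.

## Radiomic features (`radfeat`)

Per contrast, the original image and 8 single-level undecimated coif1
subbands (LLL…HHH; symmetric boundary, low-pass normalized to unit DC gain
so LLL preserves the local mean) each yield 65 features:

- **16 histogram**: energy (sum of squared intensities), entropy and
  uniformity (on the 32-bin discretized distribution, making them invariant
  to affine intensity rescaling), min, max, mean, median, range, variance,
  SD, skewness, kurtosis (Pearson, 3 for a Gaussian), 10th/90th
  percentiles, IQR, mean absolute deviation.  Note energy is intensity-based
  rather than discretized — a discretized "energy" would duplicate
  uniformity.
- **26 GLCM**: symmetric co-occurrence at distance 1, each of the 13 unique
  3D directions, features averaged over directions (rotational invariance);
  the set is the standard Haralick/extended list (autocorrelation, cluster
  prominence/shade/tendency, contrast, correlation, difference
  average/entropy/variance, dissimilarity, energy, entropy, homogeneity 1
  and 2, IMC1, IMC2, IDMN, IDN, inverse variance, joint average, maximum
  probability, sum average/entropy/variance, variance, MCC).
- **13 GLRLM**: SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE,
  LRHGE, GLV, RLV, direction-averaged the same way.
- **10 LBP**: rotation-invariant uniform (riu2) codes with 8 neighbours at
  radius 1, computed per axial slice on mirror-padded data and pooled
  across slices into a normalized 10-bin histogram.

Geometry adds 8 mask-only features: volume (voxel counting), surface area
(exposed-face counting — deterministic and oracle-checkable, but a known
~1.5× overestimate for smooth digital shapes, which reverses naive
sphericity intuitions: an axis-aligned digital cube scores higher than a
digital ball), surface-to-volume ratio, sphericity, compactness 1 and 2,
spherical disproportion, and maximum 3D diameter (largest pairwise distance
between surface-voxel centers).  Total: 3 × 9 × 65 + 8 = **1763**.

Numerical conventions: gray levels use 32 equal-width bins over the in-mask
min–max (top bin right-closed; constant ROI → level 1).  Degenerate inputs
substitute finite values: correlation, IMC1 and MCC are 0 when a marginal
variance or entropy vanishes; skewness/kurtosis are 0 for (numerically)
constant ROIs.  Feature extraction crops each lesion to its bounding box
plus a 6-voxel margin (the coif1 support), which leaves in-mask values
unchanged for interior lesions and dominates the ~0.5 s/lesion runtime.

## Labeling and table assembly (`cohort`)

Local tumor control is lesion-wise: relative volume change
Δ = (followup − baseline)/baseline, Δ > 0.10 → poor (exactly +10% is good).
Survival is patient-wise: OS below the cohort median → poor (OS equal to
the median is good).  Both boundary conventions are package choices; the
verbal rules leave them open.  The cohort median is computed over the full
analyzed cohort before splitting — a deliberate mirror of the descriptive
phrasing of the labeling rule, noted here as a potential (mild) leakage
channel.  Survival models use only the largest-baseline-volume lesion per
patient (ties → lexicographically smallest lesion id, logged).  Clinical
covariates are encoded as KPS ≥ 90, binary flags, integer lesion count and
log-volume (mm³).  Labels are encoded poor = 1 so that sensitivity is the
recall of the poor class.

## Modeling (`selectml`)

Pipeline order: grouped stratified 70/30 hold-out → Welch t-test ranking →
NearMiss-2 → sequential forward selection → Bayesian-optimized RBF SVM.

- **Split.**  Drawn at patient level (all lesions of a patient on one
  side), stratified by patient majority label — stricter than an ungrouped
  split and chosen to exclude within-patient leakage.
- **Welch t-test** (unequal variances — the safer reading of "two-sample
  t-test") per radiomic feature; keep the ≤ 25 smallest p-values below
  0.05; zero-variance features get p = 1.
- **NearMiss-2** equalizes classes by keeping the majority rows with the
  smallest average Euclidean distance (standardized features) to their k = 3
  farthest minority rows.  Implemented in-package.
- **SFS** wrapper criterion is stratified 5-fold CV AUC of an RBF SVM
  (AUC matches the headline metric); greedy addition stops when the best
  candidate improves the criterion by ≤ 1e-4.  Clinical covariates bypass
  selection and, in the combined view, are always included in the wrapper's
  base set.  Under a pure-noise candidate pool this stopping rule admits on
  average ≤ 2 noise features through CV selection bias — a property the
  tests pin down rather than hide.  Fold counts cap at the smallest class
  count so tiny balanced sets remain fittable.
- **SVM.**  RBF kernel; (log₁₀C, log₁₀γ) searched over C ∈ [1e−3, 1e3],
  γ ∈ [1e−4, 1e1] by expected improvement under a Matérn-5/2 Gaussian
  process surrogate (8 random initial points, 30 evaluations by default),
  objective = stratified 5-fold CV AUC; refit at the optimum.  The search
  loop is implemented in-package on top of sklearn's GP regressor.
- **Evaluation.**  AUC from decision scores (rank statistic), accuracy /
  sensitivity / specificity at score threshold 0.  Model comparison uses
  100 paired bootstrap resamples of the test set (shared indices across
  models; single-class resamples redrawn, bounded and logged), paired
  t-tests per metric and model pair, Bonferroni-corrected at α/3 for the
  three view pairs.

## Reproducibility

A single master seed is fanned out to every stage through
`numpy.random.SeedSequence.spawn`; run directories carry the config, the
per-stage seeds, and content hashes of the clinical and feature tables, so
a rerun is verifiable hash-for-hash.

## Problem sizes used by the test suite and acceptance script

Chosen so the whole suite runs on one CPU in well under half an hour:
planted-effect recovery uses 10 seeds × 20 patients (1–2 lesions each,
texture amplitudes 0.2 vs 0.7, clinical effects off/on); the null-safety
check uses one 200-patient, one-lesion-per-patient cohort (patient-wise
survival task — covariates and labels live at patient level, so patient
count, not lesion count, sets the resolution of a CV AUC estimate; at
n = 200 a 3-fold CV AUC has σ ≈ 0.04) with 20 modeling seeds; registration
recovery uses 100 random perturbations (≤ 5°, ≤ 5 mm) of a 32³ smooth
phantom, and the acceptance script subsamples 25.  Model-search budgets in
tests use smaller CV fold counts (3) and search iterations (10) than the
library defaults; all are ordinary configuration, not separate code paths.

## Known limitations

- Phantoms are geometric, not anatomical; absolute metric values on them do
  not transfer to clinical data.
- Surface area (and features derived from it) uses the exposed-face
  convention and overestimates smooth shapes.
- The exact identities of the 16 + 49 per-image-set features follow the
  registry fixed here; other reasonable registries of the same family
  counts exist.
- The survival labeling uses the whole-cohort median (see above); a
  training-only median would be the stricter protocol.
- Bootstrap paired t-tests treat resampled metrics as paired observations;
  with B = 100 this is the conventional, slightly anticonservative choice.
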