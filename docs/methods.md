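# Methods

This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic tests do and do not
establish about real data.

## Connectome construction

**Functional.** Pearson correlation across time between every pair of
ROI columns, clipped to |r| ≤ 1 − 1e-7 and Fisher-Z transformed
(`atanh`). The clip keeps the matrix finite so the downstream cosine
affinity is well defined; the diagonal is zeroed rather than excluded.
Edge-wise confound regression is OLS of each edge on
[intercept, age, sex] across subjects, returning residual + intercept:
covariate effects are removed while the grand mean of each edge is
preserved. Regression is applied to functional edges by default;
structural matrices are left unregressed, with a switch
(`regress_structural_confounds`) to include them.

**Structural (symmetric KL).** Vertex surface-area values (mm²) of each
ROI are summarized as a probability density; the connectome entry for a
pair of ROIs is the symmetrized Kullback–Leibler divergence of their
densities in nats (natural log — the base is a convention; nats are
standard). Density estimation is a Gaussian KDE with Silverman's
bandwidth (scipy's factor, `(3n/4)^(-1/5)·sd`), evaluated on **one
common 256-point grid per subject** spanning
[min − 3h, max + 3h] of the subject's pooled vertex areas, where h is
the largest bandwidth over ROIs. A shared grid makes the R×R divergence
computable from shared density vectors in O(R²) and guarantees grid
compatibility; masses are floored at ε = 1e-12 and renormalized so no
KL term is infinite. If an ROI's values are all identical (zero
bandwidth) the estimator falls back to a bandwidth of 1e-3×mean with a
warning. Grid size and floor are configurable.

In the continuous limit the KL connectome is invariant to a common
rescaling of all areas; with the default grid the drift under ×2
scaling is below 5e-2 per entry (tested).

## Gradient embedding

Rows are sparsified to the top 10 % of entries per row (negatives
zeroed first, diagonal excluded, ties broken toward the lower column
index for determinism) — the convention of the standard gradient
toolboxes — then converted to cosine similarity with negatives clipped
to 0 so the Markov construction is valid. The diffusion map uses
anisotropic normalization α = 0.5 (halfway between pure graph Laplacian
and Laplace–Beltrami; retains global relations while damping
sampling-density effects) and diffusion time t = 0, meaning the
multiscale scaling λ/(1−λ). Ten components are retained; the explained
ratio of a component is its eigenvalue's share of the retained
eigenvalue mass. Eigendecomposition goes through the symmetric
conjugate of the Markov operator (`scipy.linalg.eigh`), which is exact
and stable; a dense non-symmetric eigensolver serves as an independent
cross-check in the tests (agreement ≤ 1e-6 per entry).

KL (divergence) matrices enter the same affinity pipeline directly:
ROIs whose divergence *profiles* are similar are morphometrically
organized alike, which is the relation the gradient should capture. An
optional `invert_kl` switch (max − KL) is provided for users who prefer
a similarity-valued input.

**Connectivity of the affinity graph.** The embedding refuses
disconnected affinity graphs (it reports the component sizes). For
clean, strongly modular matrices — notably noise-free group means — the
10 % row sparsification can occasionally disconnect a network block; the
pipeline then relaxes the keep fraction by ×1.5 steps until the graph
connects, and logs the relaxation. Analyses of very small matrices
(≲40 ROIs) should start from a higher keep fraction.

**Sign convention.** Eigenvector signs are arbitrary. The group
template is oriented so each component's DMN mean exceeds its VIS mean
(the principal gradient runs primary → association); individual
embeddings are aligned to the template by Procrustes rotation, which
handles reflections.

**Procrustes alignment.** Alternating minimization of
Σᵢ‖SᵢQᵢ − ref‖²_F: each subject's orthogonal rotation comes from the
SVD of SᵢᵀR, then the reference is refreshed as the mean of the aligned
sets. The initial reference is the control-group template (the
embedding of the control-mean connectome); iteration stops after 10
rounds or when the discrepancy improves by < 1e-8. The discrepancy is
non-increasing by construction. The alignment template is a design
choice (a grand-mean template is equally defensible); the control
template makes patient deviations interpretable against the healthy
pattern.

**Gradient span** is max − min of one component's scores per
participant, optionally over an ROI subset.

## Group statistics

- Welch's t for independent comparisons (variances are not assumed
  equal between patients and controls), paired t for pre/post.
  Zero-variance units are flagged rather than returning ±∞: identical
  groups give t = 0, p = 1; a constant non-zero paired difference is
  marked degenerate (NaN statistics) and excluded from the FDR family.
- Benjamini–Hochberg FDR within each family (per component ×
  per comparison), via statsmodels, cross-checked against a literal
  step-up implementation.
- Classification: linear SVM (C = 1), features standardized **inside
  training folds only**, stratified 5-fold CV with a fixed shuffle
  seed; accuracy is the pooled out-of-fold correct fraction, ROC/AUC
  from pooled out-of-fold decision values. With a 34/76 class imbalance
  the chance level for accuracy is the majority rate (~0.69), so
  chance-level checks use AUC (chance 0.5 regardless of imbalance).
- Treatment correlations: ΔGradient = |pre| − |post| applied at the
  network level (after averaging ROI scores within the network), and
  ΔUPDRS-III = pre − post; both are residualized on [intercept, age,
  sex] and the Pearson correlation of residuals is reported with
  df = n − 2 − n_covariates.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the parcellated level only (no volumes, surfaces, hemodynamics or
motion).

| parameter | default | meaning |
|---|---|---|
| n_controls / n_patients | 34 / 76 | one control session; pre+post per patient |
| n_roi / n_networks | 100 / 7 | scalable to 400; canonical 7-network labels |
| n_timepoints | 240 | time points per session |
| rho_within | 0.5 | correlation plateau for ROIs at zero axis distance |
| rho_decay | 1.0 | exponential decay of correlation per unit axis distance |
| axis_positions | 0 … 2.4, equally spaced | network coordinates on the latent axis |
| span_shrink | 0.4 | patient-pre contraction of axis coordinates toward the mean |
| area_shift | 1.3 | patient stretch of the log-area axis drift (structural effect) |
| restoration | 0.5 | mean per-subject fraction of each effect undone post-treatment |
| clinical_noise_sd | 0.44 | SD of noise on the planted ΔUPDRS-III (see calibration) |
| vertices_per_roi | 50 | vertex surface-area samples per ROI |

ROI axis coordinates are their network's coordinate plus N(0, 0.15)
jitter — ROIs differ in how prototypical they are of their network, and
network blocks blend into their neighbours as in real parcellations.
The covariance `C_ij = rho_within·exp(−rho_decay·|axis_i − axis_j|)`
(diagonal 1) is an Ornstein–Uhlenbeck kernel on the axis and therefore
positive definite for any 0 ≤ rho_within < 1; the generator still
verifies the Cholesky factorization and names the offending parameters
if it fails. Time series are temporally white Gaussian draws from this
covariance.

Vertex areas are log-normal (σ_log = 0.3, median ≈ 0.55 mm²) with the
log-median drifting ±0.15 along the axis. The patient effect multiplies
this drift by `area_shift`, i.e. a per-network multiplicative scale
shift that is largest at the axis extremes — a flat per-network factor
would be invisible to the scale-invariant cosine affinity, whereas the
graded shift widens the structural gradient span, which is the planted
structural abnormality. Post-treatment sessions reuse the subject's
random substream, so pre and post differ only through the planted
restoration plus fresh noise — the coupling paired tests require.

Each patient draws an individual restoration fraction uniformly within
±0.25 of the configured mean (clipped to [0, 1]); the planted clinical
improvement is `ΔUPDRS = 5·restoration + N(0, clinical_noise_sd)` on a
UPDRS-III-like scale (pre ≈ 31 ± 12 on 0–108, mean improvement 2.5).

**Calibration of clinical_noise_sd.** The observable correlation
between measured DMN gradient change and ΔUPDRS is attenuated by
gradient measurement noise (finite T, KDE sampling, alignment). The
attenuation was measured once at the default conditions
(corr(ΔG_DMN, restoration) ≈ −0.35 with noise-free clinical scores) and
clinical_noise_sd was then fixed at 0.44 so the observable partial
correlation is ≈ −0.30 at n = 76 — a planted effect of realistic,
detectable-but-noisy size. The target (−0.30 at the DMN) is recorded in
the cohort's ground-truth dictionary.

**What the generator does not emulate.** Temporal autocorrelation and
global artifacts of fMRI (noise is white), spatial geometry of the
cortex (ROIs live on a 1-D axis, so no spatial autocorrelation
structure beyond it), heavy-tailed morphometry, and — importantly — the
spectral concentration of real connectomes: the smooth 1-D latent
geometry spreads functional eigenvalue mass nearly evenly, so the
principal functional component explains ~0.16 of the retained mass
rather than the >0.3 typical of real FC data (the structural template,
nearly rank-one, concentrates ~0.75). Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
effects, not that real-data effect sizes are reproduced.

## Problem sizes in the test suite and acceptance script

The suite runs cohorts at n_roi = 100 (scalable to 400 via config):
single default cohorts for axis recovery, classification and the
qualitative span pattern; 100 replicate cohorts each for the planted
span effect and its null calibration; 20 replicates for treatment-
correlation recovery; 200 null replicates for FDR validity; 20 random
50-node affinities for embedding-oracle agreement. The acceptance
script repeats the same computations with 25 replicate cohorts for the
detection rates. A full default pipeline run takes well under a minute
for the functional stream and a few seconds more for the structural
stream on one CPU.

## Known limitations

- The KL connectome depends on the KDE grid; divergences are reported
  on the discretized densities, not the underlying continuous ones.
  Entries are exactly grid-compatible within a subject but grids differ
  between subjects by construction.
- The paper-style symmetric KL uses the arithmetic mean of the two
  directions; other symmetrizations (Jensen–Shannon) are out of scope.
- Whether confound regression should be applied before or after
  sparsification, and whether the alignment template should be the
  control mean or the grand mean, are genuinely open choices; the
  defaults (regress first, control template) are exposed in config.
- With very small groups (< 3 per group) the group statistics refuse to
  run rather than returning unstable values.
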