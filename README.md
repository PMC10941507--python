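# neurograd

Functional and structural connectome **gradient** analysis for
parcellated brain data, with a fully synthetic cohort generator so the
entire pipeline is testable end to end without patient data.

The package is aimed at neuroimaging researchers studying disorders of
cortical hierarchical organization (e.g., Parkinson's disease) who have
per-subject parcellated data — ROI×time resting-state series and
vertex-wise cortical surface-area values — and want subject-level
gradients, group statistics, classification, and treatment-outcome
correlations from plain-text inputs.

## The method

**Connectomes.** For each subject-session the pipeline builds

- a *functional* connectome: Fisher-Z transformed Pearson correlation
  between ROI time series, `z_ik = atanh(r_ik)`, with optional edge-wise
  OLS removal of age/sex effects across subjects; and
- a *structural* connectome from cortical morphometry: for each ROI the
  probability density `f_i` of its vertex surface-area values (Gaussian
  KDE, Silverman bandwidth, one common grid per subject), and for each
  pair of ROIs the symmetric Kullback–Leibler divergence

  `KL_adj(i,k) = ( KL(f_i‖f_k) + KL(f_k‖f_i) ) / 2`,
  `KL(f‖g) = Σ f·log(f/g)` (nats).

  Small divergence = similar cortical morphology.

**Gradients.** Each connectome row is sparsified (top 10 % of entries
kept per row), turned into a cosine-similarity affinity matrix, and
embedded by a diffusion map with anisotropic normalization `α = 0.5`:
`W' = D^-α W D^-α`, the Markov operator `P` of `W'` is eigendecomposed,
and component `c` is `ψ_c · λ_c/(1−λ_c)` (multiscale scaling). The
principal component (largest eigenvalue) is the principal gradient —
FCG1 for the functional, STG1 for the structural connectome — a
continuous sensorimotor→association axis. Subjects are made comparable
by iterative Procrustes rotation onto the control-group template, and
each subject's *gradient span* is the range (max − min) of their
principal-gradient scores.

**Group analysis.** Network-mean gradient scores (7-network scheme:
VIS, SMN, DAN, VAN, LIB, FPN, DMN), ROI/network-wise Welch and paired
t tests with Benjamini–Hochberg FDR, linear-SVM classification of
patients vs controls from network gradient features (stratified k-fold,
pooled out-of-fold accuracy and ROC/AUC), and partial Pearson
correlation (age/sex removed) between per-network gradient change
`ΔGradient = |pre| − |post|` and clinical change
`ΔUPDRS-III = pre − post`.

**Synthetic cohorts.** `generate_cohort` plants a latent 1-D hierarchy
axis: ROI time-series covariance decays exponentially with axis
distance, patients' axis coordinates are contracted (narrower
functional span), their morphometric axis drift is stretched (wider
structural span), and treatment partially restores both effects with a
per-subject restoration fraction that also drives a planted
UPDRS-III-like improvement. Ground truth is retained for
parameter-recovery tests.

## Worked example

```python
import numpy as np
from neurograd import CohortConfig, generate_cohort, analyze_cohort

cohort = generate_cohort(CohortConfig(seed=1))      # 34 controls, 76 patients
results = analyze_cohort(cohort)

spans = results["span_FCG1"].groupby("session")["span"].mean()
print("FCG1 span  control=%.2f  pre=%.2f  post=%.2f"
      % (spans["control"], spans["pre"], spans["post"]))
```

prints

```
FCG1 span  control=14.33  pre=8.24  post=11.42
control vs pre: p = 3.40e-24
axis recovery r = 0.991
SVM FCG1     accuracy=0.982 AUC=0.999
SVM STG1     accuracy=0.682 AUC=0.642
SVM combined accuracy=0.982 AUC=0.993
DMN ΔFCG1 vs ΔUPDRS-III: r = -0.442, p = 0.0001
```

Reading the numbers: patients' functional gradient span is contracted
before treatment (8.24 vs 14.33 in controls) and partially restored
after (11.42); the group-mean principal functional gradient recovers
the planted hierarchy axis almost perfectly (r = 0.991); combined
functional+structural network features discriminate patients from
controls far better than structural features alone; and the DMN
functional gradient change tracks the planted clinical improvement
(negative sign: restoration moves the DMN score away from zero, toward
the control mean).

## Command line

```bash
neurograd simulate --seed 0 --out data/           # write a synthetic cohort
neurograd run-all config.yaml                     # full pipeline + manifest
neurograd connectome --timeseries ts.tsv --out fc.tsv
neurograd gradient fc.tsv --out grad.tsv
```

`run-all` reads a YAML config (output directory, either a `simulate`
block or a `data_dir` of TSV inputs, and pipeline parameters) and
writes every artifact with a checksummed manifest. All formats are
plain TSV/JSON; see `docs/methods.md` for details and defaults.

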