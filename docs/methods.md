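# Methods

This note records the models, conventions and design choices behind
`rsdiag`, in enough detail to reproduce or audit any stage.

## The diagnostic comparison

The package frames diagnosis as supervised classification of
participants into control / ADHD-combined / ADHD-inattentive (three-way)
or control / ADHD (binary, subtypes collapsed), from one of two input
families: a short personal-characteristic vector, or features extracted
from a resting-state 4D scan. A *diagnostic pipeline* is a fixed
combination of input choice, preprocessing, feature extraction and
classifier family, evaluated under counterbalanced 10-fold
cross-validation against a majority-class chance baseline. The central
scientific point the machinery makes quantitative: a group-level
difference of high statistical significance need not separate
individuals (a mean separation δ between two unit-variance Gaussian
groups yields a nearest-group-mean accuracy of Φ(δ/2), regardless of how
large the two-sample t is — at n = 1000 per group, t ≈ 7.1 corresponds
to δ ≈ 0.32 and only ≈ 56% accuracy).

## Synthetic data: what it emulates and what it does not

**Participant tables.** Cohorts are drawn from per-group marginal
distributions — group sizes, per-group site proportions, age mean ± sd,
fraction female, handedness category probabilities, medication
probabilities, and per-score IQ mean ± sd — parameterized to the
published summaries of a 668-participant training cohort (429/141/98)
and a 171-participant holdout cohort (94/51/26). Structural missingness
is encoded as per-site/per-field missing probability 1 (one site
provides no IQ; two sites provide only a full-scale estimate; the Full-2
score exists only at one site and only for controls), and one site
("NeuroIMAGE") emits continuous Edinburgh handedness scores, simulated
uniform on [−100, 100] since only the score's range convention is fixed.
Missing values are NaN throughout — distinct from every legal score, so
imputation is observable in tests. Fields are sampled independently
given group and site: the published summaries are marginal, so no joint
structure (age×IQ correlation, site-specific age ranges) is imposed, and
passing tests say nothing about such joint structure in real data.

**Scans.** A scan is `site_gain · (baseline + Σ_k tc_k ⊗ w_k·map_k +
noise)`: sparse spatially-disjoint source maps (two rectangular blocks
per source, lightly smoothed — sparse supports make the sources
super-Gaussian, which spatial ICA requires), smooth unit-variance random
timecourses, subject weights uniform on [0.8, 1.2], i.i.d. Gaussian
voxel noise, a constant tissue baseline (default 0; set ≈ 100 when
percent-signal-change normalization will be applied, since that scaling
divides by the temporal mean), and a multiplicative site gain. Source 0
is the default-mode-like network; a designated block of its support can
carry an additive group difference `dmn_effect` in the patients'
weighting — injected on weights in a known voxel block, not on noise, so
downstream statistics have a recoverable target. No scanner physics,
motion, physiological noise or slice timing is simulated; the generator
supports the pipeline's algebra and statistics, not realism of spectra
or artifacts.

## Preprocessing conventions

- **Temporal standardization** keeps the *first* 185 s and resamples by
  linear interpolation at sample times 0, 0.5, …, 184.5 s anchored at
  the first volume, giving 370 volumes at 0.5 s. Scans shorter than the
  target are refused (no extrapolation).
- **Spatial window averaging (SWA)** with factor r produces
  `floor(dim/r)` windows per axis; the final window of each axis absorbs
  the remainder voxels, so every voxel contributes exactly once and the
  printed output grids (19×22×16 at r=3; 7×8×6 at r=8 from 57×67×50)
  hold. Nominal voxel size scales by r.
- **Masking** thresholds the across-scan mean volume at
  `threshold_frac` (default 0.5) times the global mean of its nonzero
  voxels; reduced-resolution masks use majority vote within SWA windows
  (ties include). The threshold is recorded in the mask's provenance.
- **Flattening** is x-fastest lexicographic everywhere (Fortran ravel);
  the inverse zero-fills excluded voxels.
- **PSCS-tc** maps each voxel timecourse to percent change about its own
  temporal mean (output voxel means are exactly zero — which is why it
  is never combined with the temporal-average feature); **PSCS-s**
  scales the whole scan by its mean over masked voxels and time,
  cancelling site gain while preserving between-voxel mean contrasts. A
  zero mean inside the mask is an error naming the voxel.

## Feature extraction

- **T Avg**: per-voxel temporal mean (η = 1 values per voxel).
- **Timecourse PCA**: observations are voxel timecourses pooled across
  training participants; the basis comes from a full SVD of centered
  observations (covariance scaling), with the deterministic sign
  convention that each component's largest-|loading| entry is positive.
  Projections keep the first 1 or 5 coefficients per voxel. When used
  inside cross-validation the basis is fitted per training split.
- **FFT / ALFF**: unnormalized forward DFT of the 370-point timecourse;
  the low-frequency band is the 18 components k = 1..18 at frequencies
  k/185 Hz, exactly those in [0.001, 0.1] Hz inclusive. FFT features are
  the 18 moduli followed by the 18 phase angles (η = 36); ALFF is the
  mean band modulus (η = 1). The DFT convention is pinned by a Parseval
  check in the tests.
- Feature vectors are masked, flattened and concatenated in component
  order, reproducing the published lengths (3558/186 for η=1 maps at
  r=3/r=8 mask sizes, 930 for PCA₁₋₅, 6696 for FFT, 3720 for FC₁₋₂₀).

## Group spatial ICA and GICA3

Each participant's masked, PSCS-tc-normalized (time × voxels) matrix is
reduced to 25 temporal dimensions by spatial PCA (voxels as
observations, rows centered across voxels). The reductions are
concatenated (subjects × 25 rows) and a second PCA retains 20 whitened
group dimensions. Symmetric (parallel) FastICA with the tanh/logcosh
contrast separates the whitened rows into 20 spatial components;
non-convergence raises an error carrying the iteration budget.
Component sign is fixed so each group map's largest-|value| voxel is
positive. GICA3 back-reconstruction computes subject maps through the
stored linear transforms, `S_i = M · W · G_iᵀ (X_i − c_i)`, whose
across-subject mean equals the group maps *identically* — the defining
property, verified to < 1e-6 relative error in tests. The DMN is
identified as the component maximizing |spatial correlation| with a
template (in tests, the generator's ground-truth map), with a
configurable floor (default 0.2) below which no DMN is reported.

Numerical note: on toy cohorts whose effective rank is far below the
20-component model order, the excess whitened dimensions are isotropic
Gaussian and the symmetric FastICA update cannot settle to the default
1e-6 tolerance (Gaussian subspaces have no preferred rotation). Full
model-order runs on such cohorts therefore use a relaxed tolerance
(5e-2, config-exposed); source recovery is unaffected (|r| > 0.95 on
four injected sources). Unit tests at reduced model order use 1e-4.

## Group statistics and cluster selection

Voxelwise pooled-variance two-sample t (df = n_A + n_B − 2) and
one-sample t (df = n − 1) maps; zero-variance voxels get t = 0 with a
warning. Thresholding zeroes |t| ≤ θ_t, then removes connected
components smaller than θ_cs mm³. Components use 26-connectivity by
default (6/18 available), and positive/negative suprathreshold voxels
cluster separately, since the contrasts are two-tailed and mixing signs
would corrupt cluster means.

The **cluster-size threshold** is calibrated by Monte-Carlo simulation:
null fields are Gaussian white noise smoothed to a configured FWHM
(default 8 mm) and variance-normalized; either the smoothed field itself
is thresholded (z-field null) or, given group sizes, per-subject fields
are drawn and the two-sample t-field thresholded (matching a
group-comparison null — the variant used in the calibration tests). The
returned threshold is the smallest cluster size whose exceedance
probability by the largest null cluster is ≤ α.

The **cluster extractor** takes local |t| maxima over suprathreshold
voxels as candidate peaks, merges peaks closer than d_min mm (higher |t|
wins; ties break to the lower linear voxel index), assigns every
suprathreshold voxel to the nearest surviving peak (Euclidean mm, ties
to the lower-index peak), discards clusters below v_min mm³, orders
survivors by statistical mass (Σ|t| over member voxels) and keeps the
top n_clusters (∞ allowed). Flat plateaus yield one peak per plateau
voxel; on smooth t-fields peaks are unique, and the merge radius
controls fragmentation. Features are per-cluster means of the
participant's feature volume, concatenated in (map, mass-rank) order.

The **robust variant** additionally computes, for each cross-validation
iteration i, nine sub-iteration map sets excluding folds i and j, each
thresholded identically, and zeroes every voxel of the iteration's maps
not significant in all nine — equivalently a voxelwise AND across the
ten sets, which is the oracle the tests compare against. Statistical
selection always runs on training folds only.

## Evaluation

Counterbalanced folds come from a greedy stratified assignment:
participants are processed rarest stratum-combination first (after a
seeded shuffle) and placed in the eligible fold (sizes may differ by at
most one) holding the fewest participants sharing their stratum levels;
the documented imbalance cost — summed absolute deviation from
proportional allocation over strata, levels and folds — is what the
random-baseline test bounds. Classifier backends use the toolkit
defaults a practitioner would reach for: logistic regression with a
small ridge penalty, SVMs at complexity constant 1.0 with linear,
degree-2, degree-3 and RBF (scale-bandwidth) kernels; all settings are
config-exposed, deterministic given the seed. Imputation, scaling, PCA
bases and cluster selection are fitted per training split (a
`--global-stats` CLI switch replicates whole-dataset fitting where that
older convention is wanted). Accuracies are reported as percent,
mean ± sd over the 10 test folds; pipelines are compared by one-tailed
paired t-tests on fold accuracies (df = 9; zero-variance differences
degenerate to p → 0/0.5/1 with a warning). The competition score awards
1 point per exact diagnosis and 0.5 for an ADHD diagnosis with the wrong
subtype.

## Problem sizes and tolerances used in the test suite

Synthetic fMRI checks run at 12–24 subjects on 12×12×10 to 15×15×12
grids with 100 time points (200 s at TR 2 s), sizes at which every
stage's contract — the GICA3 identity (< 1e-6 relative), source recovery
(|r| > 0.9), effect-cluster recovery (median Jaccard ≥ 0.5 over five
replicates at an injected weighting offset of 1.0 against 0.4-sd smooth
noise), and family-wise error control (≤ α + 3 binomial sd over 200
null cohorts at a threshold calibrated from 500 simulations) — is
exercised in seconds. Participant-table statistics use the full 668/171
cohort sizes. Edge conventions chosen for determinism: Edinburgh score 0
recodes to right-handed (with a warning); constant columns min-max-scale
to 0; chance-baseline ties break in class order control, ADHD-C, ADHD-I.

## Known limitations

Real acquisition heterogeneity (per-site TR/duration differences beyond
the configurable values, motion, physiological noise) is not modelled,
so pipeline accuracies on synthetic cohorts quantify the machinery, not
expected real-data performance; the published real-data accuracies are
not reproducible without the original multi-site dataset. The brain
mask construction and the cluster extractor implement documented,
configurable conventions where the original appendices admit
alternatives (connectivity, peak merging, remainder handling); all such
choices are parameterized and recorded in provenance fields.
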