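# Methods

This note documents the models, algorithms and design choices behind
`habhet`, the package's synthetic-data generator, and the problem sizes used
in the test suite and the acceptance script.

## Overview

`habhet` quantifies intratumoral and peritumoral heterogeneity (ITH/PTH) on
co-registered multi-sequence 3D MRI (T2-weighted, precontrast T1, arterial
phase, hepatobiliary phase) and feeds the resulting per-case signature into
a diagnostic classifier suite (e.g. microvascular-invasion prediction in
hepatocellular carcinoma) and survival-risk stratification. The stages are:

1. **Preprocessing** — resample all sequences and masks to a
   1.0 × 1.0 × 3.0 mm grid (linear interpolation for images, nearest for
   masks); z-score each sequence over the whole volume.
2. **Regions** — peritumoral bands at 3, 5 and 7 mm built from the exact
   anisotropic Euclidean distance transform of the tumor complement,
   thresholded at each distance. Bands are cumulative shells (Peri3 ⊆
   Peri5 ⊆ Peri7) and exclude the tumor.
3. **Habitats** — masked SLIC supervoxels on the four normalized channels
   (equal weight, spatial term scaled by physical spacing), followed by a
   deterministic merge/split post-pass that enforces exactly
   K_eff = min(K, n_voxels) nonempty habitats (default K = 50).
4. **Radiomics** — the canonical 107-feature set (18 first-order, 14 shape,
   24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) per habitat and sequence:
   428 features per habitat, with shape shared across sequences.
5. **Heterogeneity** — per region and feature, the coefficient of variation
   across habitats (sample SD / |mean|); 428 × 4 regions = 1712 named
   values per case.
6. **Modeling** — three-step selection (ICC ≥ 0.800 under repeated
   segmentations; univariate t/Mann-Whitney screen at α = .05; top 20 by
   decision-tree Gini importance), then seven classifiers (logistic
   regression, random forest, decision tree, SVM, AdaBoost, k-NN, MLP).
7. **Survival** — Kaplan-Meier with Brookmeyer-Crowley median CIs, two-group
   log-rank, restricted means at 36/60 months with integrated-Greenwood
   variance, univariable Cox (Efron ties).

## Radiomic feature engine

No radiomics toolkit is a dependency; the 107 features are implemented
in-package from the standard reference definitions.

Intensities are discretized with a **fixed bin width of 0.1** on z-scored
volumes, with bin edges aligned to multiples of the width so a voxel's gray
level does not depend on the ROI it is evaluated in. Texture matrices use
the 13 unique 3D direction offsets at distance 1; GLCM features are computed
per direction on the symmetrized matrix and averaged; the GLRLM run matrix
is accumulated over directions before feature computation; GLSZM zones and
GLDM dependences use 26-connectivity with α = 0 (a neighbour is dependent
when it shares the discretized level; dependence size = dependent
neighbours + 1). Shape features come from a marching-cubes mesh (surface
area, mesh volume via the divergence theorem, sphericity, maximum 3D/2D
diameters) and from the eigenvalues of the physical-coordinate covariance
(axis lengths 4√λ, elongation, flatness).

Features that are undefined on degenerate ROIs — all texture classes on
habitats under 3 voxels, mesh features on collapsed geometry — are recorded
as missing (NaN), never as zero. Missing cells are excluded pairwise in the
CV step and median-imputed from training-split statistics at modeling time.

Two independent implementations of the extraction exist: a per-ROI
reference path and a batched path that vectorizes across all habitats of a
region (texture statistics accumulated from region-level neighbour scans
grouped by habitat id; GLSZM zones from value-aware connected components on
a sparse voxel graph). The batched path exploits two exact identities for
symmetric co-occurrence matrices — HXY1 = HXY2 = 2·HX, and the reduction of
all value-weighted sums to the |i−j| and i+j marginal distributions. The
test suite asserts column-by-column agreement of the two paths to
floating-point round-off; the pipeline uses the batched path.

## Heterogeneity statistics

CV uses the sample SD (ddof = 1) divided by |mean|, returning missing when
fewer than two finite values survive or |mean| < 1e-8. Because volumes are
z-scored, across-habitat means of signed intensity features can sit close
to zero, which makes individual CVs heavy-tailed; aggregate summaries over
many CV features therefore use the **geometric mean** (mean of log CV),
which is robust to those blow-ups and scale-free. Per-feature CVs are left
untransformed.

Feature stability across habitat counts K ∈ {30, 40, 50, 60, 70} is
summarised by ICC(2,1) — two-way random effects, absolute agreement, single
measurement — treating K settings as raters and cases as targets. The
closed-form ANOVA implementation is vectorized over features and is
cross-checked against `pingouin.intraclass_corr` in the tests.

## Classifier suite

Imputation (train median), standardization (train mean/SD), the univariate
normality gate (Shapiro-Wilk at α = .05 per group), selection, and the
operating threshold are all fitted on the training split only. The
operating point is the Youden-optimal threshold on the training ROC, frozen
for all evaluation splits. Calibration is summarised by a 10-bin
equal-width expected calibration error.

In the importance step, a single decision tree assigns nonzero importance
only to the features it actually splits on; on small training sets that can
be far fewer than 20. Importance ties — in particular the zero-importance
mass — are therefore broken by the univariate P value from the previous
step and only then by name, so the deterministic fill of the top-20 is
evidence-ranked.

The "DNN" is a small multilayer perceptron (hidden layers 64/32, ReLU)
regularized with an L2 penalty (α = 1e-2) and early stopping on a 20%
internal validation split; with ~20 inputs and a few hundred cases,
dropout-style regularization is not available in the chosen backend and the
L2 + early-stopping combination fills the same role. Below 60 training
cases the validation split is too small to steer stopping, and the MLP
instead trains for a fixed 300-iteration budget.

For small simulated cohorts the package also provides a pooled out-of-fold
AUC (stratified 5-fold, selection redone inside each fold): a single 7:3
holdout of a few dozen cases contains only two or three positives, and the
pooled estimate uses every case as a test case while remaining leakage-free.

## Synthetic phantom cohorts

The generator emulates the structure of a co-registered multi-sequence
liver-MRI cohort, not its anatomy or MR physics:

- **Geometry** — ellipsoidal tumor (radius 7–12 mm by default) in a
  64 × 64 × 24 volume at 1 × 1 × 3 mm.
- **Texture** — two shared Gaussian random fields (correlation length 4 mm,
  spectral filtering of white noise) mixed with distinct affine weights per
  sequence, plus channel noise; tumor contrast offsets make the lesion
  conspicuous on every sequence.
- **Class effect** — the high class (e.g. MVI-positive) differs from the
  low class mainly in the *spatial arrangement* of its texture: the local
  texture amplitude is modulated by a lognormal random field
  (mean-amplitude preserving) whose log-sd is 0.2 for low-class lesions but
  0.7 intratumorally and 1.1 peritumorally for high-class lesions, on top
  of a modest total-variance ratio (1.5×, again amplified 1.5× in the
  shell). High-class lesions are therefore patchy — quiet and wild
  subregions — most strongly in the peritumoral shell. This placement
  mirrors the biological claim the pipeline is built to probe (peritumoral
  heterogeneity carries the dominant signal) and is what gives the
  habitat/CV pipeline its advantage over whole-tumor features: a whole-ROI
  summary is largely blind to how variance is arranged in space and cannot
  see outside the tumor mask at all, while across-habitat dispersion
  measures it directly.
- **Nuisance** — structured parenchyma-like background texture (amplitude
  0.4), a per-case lognormal background-noise level (log-sd 0.35) and a
  global intensity gain, emulating scanner variability; the CV signature is
  invariant to these, whole-tumor intensity features are not.
- **Observers** — two mask variants obtained by perturbing the ellipsoid's
  implicit surface with a smooth random field (~1 mm amplitude).
- **Survival** — Weibull event times (shape 1.3; scale 110 months for
  recurrence, 220 for death) with the hazard multiplied by exp(log 2.2) for
  the high class, and uniform administrative censoring on 60–120 months.
- **Prevalence** — 0.25 positives.

What the phantom does **not** model: liver anatomy, vessels or organ
boundaries (bands may extend into "extrahepatic" voxels), partial-volume
and bias fields, registration error between sequences, and realistic
radiologic texture classes. Passing tests therefore demonstrate the
correctness and the directional behaviour of the pipeline, not clinical
performance.

## Problem sizes in tests and acceptance runs

Simulation studies are sized to run comfortably on a single CPU. The suite
uses a compact phantom geometry (44 × 44 × 14 voxels, tumor radius
5.5–8 mm; 40 × 40 × 12 with radius 5–7 mm for the repeated-cohort
comparison) with the full K = 50 habitat encoding. The TH-vs-Rad comparison
uses cohorts of 40 cases across ≥10 generator seeds with pooled out-of-fold
AUC; the habitat-count stability analysis uses 30 cases across
K ∈ {30, 40, 50, 60, 70} on a first-order feature subset; Cox recovery uses
100 replicates of n = 275 with true HR 2.2. Full-size single-case runs
(64 × 64 × 24, K = 50) complete in well under a minute.

## Numerical choices and edge cases

- Affine congruence between sequences is tolerated to 1e-3 (mm/cosine).
- Resampling output shape is `round(shape · spacing/target)` per axis,
  preserving physical extent within one voxel; masks stay binary via
  nearest-neighbour interpolation.
- SLIC count enforcement: smallest habitat merges into the adjacent habitat
  with the nearest mean channel vector (ties to the smallest id); the
  largest habitat splits along its principal spatial axis at the median
  projection. Both operations are deterministic; final ids are renumbered
  by first voxel occurrence.
- The split arithmetic assigns `n − floor(ratio·n)` cases to the test set
  with largest-remainder allocation across classes, guarding against float
  representation of the ratio.
- RMST variance uses the integrated-Greenwood formula computed directly
  from the Kaplan-Meier event table (the generic numerical-integration
  variance was unstable on step functions).
- Cox fits reject exactly collinear covariate pairs before fitting.

## Known limitations

- ICC-based reproducibility filtering (step 1) requires repeated
  segmentations; when none are supplied the step passes all features
  through, which is logged in the selection report.
- Exact numerical parity with any specific radiomics toolkit release is not
  claimed; definitions follow the published reference formulas, and
  in-suite oracles (hand computations, closed forms, brute-force
  enumerations) pin the behaviour.
- The phantom's class effect is by construction strongest peritumorally;
  conclusions about which feature families dominate on real data do not
  follow from these simulations.
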