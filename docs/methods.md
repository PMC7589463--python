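# Methods

## Problem and pipeline

`rimradiomics` asks whether the *periphery* of a tumour carries more
prognostic information than its interior. Given a CT image, a binary gross
tumour volume (GTV) mask and right-censored time-to-event outcomes, the
pipeline

1. resamples image and mask to 1 mm isotropic voxels (cubic spline for the
   image; trilinear + 0.5 threshold for the mask);
2. splits the GTV into a peripheral **rim** and an interior **core** by
   cropping the outer contour inward by a fixed margin (3 or 5 mm), with a
   40% minimum-core floor, and optionally grows the rim outward by
   1–5 mm (**extended rim**);
3. restricts each sub-volume to soft tissue (−150 to 180 HU);
4. expands the image into a ten-image bank (base, 8 stationary coiflet-1
   wavelet combinations, 1 multi-scale Laplacian-of-Gaussian image);
5. extracts 1538 IBSI-style features per sub-volume
   ((18 statistical + 38 histogram + 95 texture) × 10 images
   + 28 morphology on the base image);
6. fits bootstrap-ensemble survival risk models for each of 5 feature
   selectors × 6 learners and evaluates them with Harrell's C-index,
   median-risk Kaplan–Meier stratification with log-rank tests, tumour
   volume subgroups (20 cm³ threshold) and a paired sign-flip permutation
   test comparing sub-volumes across the 30 model combinations.

## Sub-volume geometry

Margins are realised as thresholds on the exact Euclidean distance
transform with the voxel-centre metric: the core candidate is
`{distance to nearest background voxel centre >= margin}`, inclusive. This
is deterministic and sub-voxel consistent on isotropic grids, but the
distance to the nearest background voxel *centre* exceeds the distance to
the continuous boundary by up to one voxel diagonal; digital-sphere cores
therefore run 6–19% larger than the analytic shell at radii of 10–20 mm.
Tests bracket the analytic value between the shells at `margin` and
`margin − 1 voxel` and additionally require exact agreement with a
brute-force distance scan.

When the candidate core holds less than 40% of the tumour, the margin is
shrunk to the largest distance threshold whose superlevel set reaches the
floor (ties included), so the floor is met exactly and order-free.
Sub-volumes are built from the geometric mask and re-segmented afterwards;
morphology uses the geometric mask, intensity-weighted members use the
re-segmented intensities.

## Filter bank

The single-level stationary wavelet transform is separable FIR filtering
with the coiflet-1 decomposition filters (taps from PyWavelets) and no
decimation, applied via 1-D correlation with mirror boundaries — this
keeps every output on the input grid with symmetric boundary handling.
The LoG image averages scale-normalised responses (σ²·∇²G_σ) over kernel
widths 1, 2, 3, 5 and 6 mm; the combiner (voxelwise mean) is a package
choice, isolated behind `log_filter(..., sigmas_mm=...)`, since only "one
image from five widths" is specified by the design the package follows.

## Feature set

Discretisation is fixed-bin-number (32 bins over the in-ROI range) for all
discretised features on all transforms; FBN stays well defined on filter
responses where HU-width binning is meaningless. The exact 38-member
histogram family (23 intensity-histogram + 13 intensity-volume-histogram +
2 intensity peaks) and 28-member morphology family are frozen in
`radiomics_features/manifest.tsv`; the counts are the contract, the
composition is a documented package decision. Degenerate inputs never drop
a feature silently: undefined values (zero variance, single grey level,
single voxel) map to documented constants and are logged.

Texture matrices are computed in 3D: GLCM (distance 1, symmetrised) and
GLRLM per 13 unique directions with feature-level averaging; GLSZM/GLDZM
on 26-connected zones (GLDZM distances are city-block steps to the ROI
edge, border voxels = 1); NGTDM/NGLDM on the 26-neighbourhood (NGLDM
coarseness parameter a = 0, dependence count = dependent neighbours + 1).
All six families are verified against brute-force enumeration oracles on
small ROIs.

Morphological meshes come from marching cubes on the raw binary mask.
Two discretisation biases are accepted and documented rather than hidden:
the staircase mesh of a digital sphere overestimates surface area by ~9%
(sphericity ≈ 0.92 for an ideal sphere), and chamfered corners
underestimate a cube's area by ~6%. Mesh volume is accurate to ~0.5%.
Maximum 3D diameter is computed on the convex hull of voxel corners,
which is exact for axis-aligned boxes and overestimates smooth shapes by
at most one voxel diagonal. Moran's I and Geary's C subsample ROIs above
2000 voxels with a fixed generator (reproducible features, unbiased under
random subsampling).

## Risk modelling

Preprocessing z-scores every feature with exploratory-cohort statistics,
drops zero-variance features, and merges clusters of |Spearman ρ| ≥ 0.90
(complete linkage on 1 − |ρ|) into mean meta-features. Validation rows are
transformed with the exploratory statistics and cluster map only.

Feature selection runs on bootstrap resamples of the exploratory cohort
(default 1000; tests use 5–50) and aggregates per-bootstrap scores by mean
rank, ties broken by name:

* `spearman` — |ρ| between feature and event time among event patients;
* `mim` — mutual information between the 4-bin equal-frequency binned
  feature and the event indicator;
* `mifs` / `mrmr` — greedy forward MI with total-redundancy (β = 1) or
  mean-redundancy penalty (greedy ordering capped at 30 picks; the tail
  is ranked by relevance);
* `rfvi` — permutation importance of a 25-tree random survival forest.

Hyper-parameters (signature size k ∈ 1..10 plus learner grids frozen in
`risk_modelling/ensemble.py`) are tuned by random search scored by mean
out-of-bag C over inner bootstrap fits. Model training fits the learner on
(default) 1000 bootstrap resamples; degenerate or non-convergent fits are
dropped with a log record and only >50% failures abort. The ensemble risk
is the unweighted mean of per-model risks; every learner is oriented
higher = worse:

* Cox, BT-Cox, BGLM-Cox, RSF wrap scikit-survival estimators;
* MSR-RF is an in-package survival forest splitting on the maximally
  selected standardised log-rank statistic (Hothorn–Lausen linear
  statistic over cutpoints in the 10–90% feature quantile range), leaf
  risk = node Nelson–Aalen cumulative hazard;
* BT-Weibull boosts the full Weibull accelerated-failure-time
  log-likelihood with shallow regression trees on the μ gradient and a
  1-D maximum-likelihood σ refresh per iteration; risk = −μ(x).

The representative combination for a sub-volume is the selector whose
median C over learners is closest to the median of those medians, crossed
with the analogous learner (ties lexicographic).

## Evaluation

Harrell's C is implemented directly (comparable pair = shorter time has an
event; tied risks score ½) and cross-checked in tests against brute-force
pair enumeration and `sksurv.metrics.concordance_index_censored`.
Confidence intervals are percentile bootstrap over patients (1000
resamples). Stratification uses the exploratory median risk, ties to the
low-risk group, applied unchanged to validation; curves are Kaplan–Meier
and group comparison is the two-group log-rank test (lifelines). The
sub-volume comparison across the 30 combinations is a paired sign-flip
permutation test on per-combo C differences (10 000 draws, add-one
smoothed, two-sided) — assumption-light and testing the same null as a
multi-level model.

## Synthetic cohorts: what they emulate, and what not

`generate_cohort` draws per-patient latent severity `z ~ N(0,1)`,
log-uniform tumour volumes over [5, 150] cm³ (spanning the 20 cm³
subgroup threshold; equivalent radii ~10.6–33 mm) with mild random
anisotropy, and renders ellipsoidal phantoms: background −40 HU, core
40 HU, rim 60 HU, global noise 3 HU, all tumour voxels clipped to
(−140, 170) HU so soft-tissue re-segmentation is non-destructive.

The prognostic signal lives in the **rim texture**: voxel noise with
standard deviation `20·max(0, 1 + 0.5·z)` HU inside the boundary shell of
fixed 5 mm thickness (voxel-centre EDT). A fixed physical thickness —
rather than a fixed fraction of the radius — keeps the signal at the
spatial scale of the rim margins for every tumour size; with a
proportional rim, large tumours would carry texture deep into the 5 mm
core and the rim/core contrast would vanish by construction. A side
effect matches clinical intuition: small tumours, where the 40% core
floor forces the core into the textured shell, show similar rim and core
performance, while large tumours show a clear rim advantage.

Outcomes follow a Weibull proportional-hazards model on standardised z
(shape 1.2, scale 50 months, log-hazard coefficient β = 2 by default)
with uniform administrative censoring on [0, 60] months, giving ~35–40%
events. β = 0 yields calibration cohorts.

Not emulated: scanner reconstruction kernels, contrast phases,
multi-centre acquisition variation, delineation variability, correlated
clinical covariates. Passing tests therefore demonstrate that the
*pipeline* recovers a rim-localised signal under its stated assumptions,
not that any specific clinical effect size is reproduced.

## Problem sizes used by the test suite

Structural and oracle tests run on single phantoms or ≤4×4×4 grids in
seconds. The directional-reproduction checks use 20 seeded replicates of
n = 300 cohorts (2:1 split) with the replicate pipeline reduced to
base-image intensity statistics and the spearman+cox combination
(selection on 25, training on 50 bootstrap resamples, k = 3): the rim
signal is a texture-SD effect that intensity statistics capture directly,
so the reduction changes cost, not the question. Null calibration
(β = 0) is asserted on the mean validation C over three replicates, since
a single n = 100 validation cohort estimates C with sd ≈ 0.04.

## Known limitations

* No IBSI reference-phantom certification; texture definitions are
  verified against in-repo brute-force oracles instead.
* Mesh-derived morphology carries the voxelisation biases quantified
  above.
* The MSR-RF and BT-Weibull learners are compact reference
  implementations, adequate for ensemble use at cohort sizes of a few
  hundred; they are not speed-optimised.
* The IVH uses the continuous in-ROI intensity range (min–max), which on
  filter-response images makes the 10%/90% anchors data-dependent.
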