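# Methods

`reconradiomics` studies how CT reconstruction settings — slice thickness
(Thin 1 mm vs Thick 5 mm) crossed with convolution kernel (Sharp vs Smooth)
— change the performance of a radiomic classifier of EGFR mutation status,
using a fully synthetic phantom cohort in place of patient data. This note
documents the models, the parameter choices that matter, and what the
synthetic experiments do and do not show.

## The phantom cohort

Each "patient" is one ellipsoidal lung lesion rendered on a fine isotropic
grid (0.5 mm, 48³ voxels ≈ a 24 mm cube) and then reconstructed under the
four settings. Geometry and mean intensity are class-independent nuisances:

* diameter 16 ± 2 mm (uniform), semi-axis ratios jittered ±12% and
  renormalized to preserve the geometric-mean diameter;
* lesion plateau +40 HU in a −800 HU background, with a sigmoidal margin of
  softness 1 mm (half-width of the intensity falloff).

The class effect is intra-lesion texture only. A unit-variance Gaussian
random field (white noise smoothed at a correlation length) is passed
through a tanh saturation (`texture_saturation = 2.0`) and scaled by an
amplitude:

* wild-type: amplitude 40 HU, correlation length 3.5 mm;
* mutant: amplitude 70 HU, correlation length 1.5 mm;
* per-lesion lognormal spreads (σ_ln = 0.5 for both amplitude and length)
  make the class distributions overlap, so no single lesion is decisive.

Two modeling points deserve emphasis. First, the saturation is deliberate:
a purely Gaussian texture changes only the *scale* of the intensity
distribution, and min–max-binned histogram statistics (entropy, uniformity)
are scale-invariant, so heterogeneity would be invisible to exactly the
features the analysis centres on. Saturating the field forms regionally
coherent intensity plateaus — a crude stand-in for enhancing vs necrotic
subregions — which makes the intra-lesion histogram multi-modal and couples
heterogeneity to LoG-entropy, the behaviour the study design requires.
Second, the class separation is scale-dependent by construction: the mutant
texture lives at ~1.5 mm, which 1 mm slices resolve and 5 mm slab averaging
destroys; the wild-type texture at ~3.5 mm survives both. This is the
mechanism behind every thin-vs-thick comparison below.

## Reconstruction emulation

* Thin: average the 0.5 mm stack in non-overlapping pairs → 1 mm slices.
* Thick: average non-overlapping 5-slice slabs of the thin stack → 5 mm
  slices (partial-volume effect; slab means conserve the thin-stack mean).
* Smooth kernel: in-plane Gaussian blur, σ = 1.6 mm, plus white noise
  σ = 3 HU.
* Sharp kernel: in-plane unsharp mask (amount 0.8, σ = 1.0 mm) plus white
  noise σ = 14 HU.
* Masks follow each grid by per-voxel majority vote.

This reproduces the qualitative noise–resolution trade-off of clinical
kernels; no MTF, sinogram or dose physics is modelled.

Test–retest pairs (for the reproducibility filter) re-render the same scene
with a fresh noise realization, a uniform sub-voxel rigid shift (≤ 0.5
voxel per axis) and, with probability 0.25, a one-voxel erosion or dilation
of the mask — emulating repositioning and minor re-segmentation between
same-day repeat scans.

## Feature bank

Names follow `Family_Statistic[_Params]_Aggregation`. Aggregations: `2D`
(per axial slice, averaged over slices weighted by mask area), `25D`
(in-plane texture matrices pooled across slices, summarized once), `3D`
(volumetric). Families:

* **LoG** at σ ∈ {0, 0.5, 1.5, 2.5} mm (σ = 0 is the identity, i.e.
  first-order statistics). Separable convolution with a zero-sum-corrected
  sampled kernel, so constants map exactly to zero; σ is metric (mm) and
  converted per axis through the voxel spacing, which keeps the filter
  scale comparable across reconstruction settings. Statistics: min–max
  histogram entropy/uniformity (32 bins) plus moments and median.
* **LoG_Z**: the LoG response z-scored within the mask and histogrammed on
  *fixed* bins spanning [−4, 4]. A plain z-normalization followed by
  min–max binning would reproduce the plain statistics exactly (affine
  invariance), so the fixed-bin variant is used: it measures the shape of
  the standardized response. Both variants are reported.
* **Gabor**: per-slice complex filtering at 0/45/90/135°, wavelength 4 mm,
  envelope σ = wavelength/2, exact zero-DC kernel (offset invariance);
  magnitude statistics, `2D` per slice and `3D` pooled over the volume.
* **Laws**: 3D separable kernels over {L5,E5,S5,R5,W5}³, enumerated
  lexicographically 1..125 (code 8 = L5·E5·S5); local energy = mean |response|
  in a 5-voxel window. Default set: code 8.
* **GLCM** (distance 1, symmetric, 4 in-plane / 13 3D directions) and
  **NGTDM** (Amadasun–King, 8/26-connected) on intensities quantized to 32
  equal-width levels inside the mask; only voxel pairs / complete
  neighborhoods inside the mask count.
* **Shape**: volume, largest surface-voxel diameter, compactness
  36πV²/S³ and roundness π^{1/3}(6V)^{2/3}/S from a marching-cubes mesh of
  the lightly smoothed mask (raw binary meshes overestimate area), and a
  9-bin histogram of the curvature shape index over the surface.
* **Sigmoid margin**: radial profiles from the centroid along ~100
  Fibonacci-sphere directions, centred on the surface crossing, fitted with
  I(t) = b + A/(1 + e^{−s(t−t₀)}); statistics of |A| and |s| over converged
  fits; > 50% failures is a quality error.

The default bank yields 178 features; the study configuration used by the
pipeline (`STUDY_CONFIG`, 172 features) drops the sigmoid family, whose
per-lesion cost (≈100 nonlinear fits) dominates extraction while adding no
texture information to the comparisons of interest. The feature count is a
closed-form function of the configuration and is verified against an
independent enumeration of the grammar.

## Statistical pipeline

* **Reproducibility**: Lin's CCC with population (1/n) moments — the
  convention of Lin's original estimator; the sample convention would shift
  borderline features. Strict threshold: retained iff CCC > 0.9.
  Degenerate conventions: both samples constant and equal → 1; one constant
  → 0.
* **Redundancy**: complete-linkage clustering on 1 − |r| cut at
  1 − 0.8, guaranteeing every within-cluster pair exceeds the threshold;
  Pearson |r| by default with CCC available (the appropriate association
  is genuinely ambiguous; both ship).
* **Rankers**: ReliefF (k = 5, standardized features), χ² and mRMR
  (mutual-information difference) on quartile-binned features, pooled
  |t|, Wilcoxon rank-sum |z|, univariate threshold accuracy
  (resubstitution, both orientations). Ties break lexicographically.
  mRMR's greedy criterion is not monotone, so its reported scores are the
  selection ranks.
* **Coarse selection**: per ranker, keep the top-scoring member of each
  redundancy cluster, re-rank, truncate to 10.
* **Fine selection**: single-pass forward search in ranked order over an
  SVM (linear kernel, C = 100, per-fold z-scoring) under one stratified
  3-fold assignment shared by all candidate models; a feature is kept iff
  it strictly (tol 1e-10) increases the cross-validated AUC from the
  chance baseline 0.5; if nothing is kept, the top-ranked candidate is the
  fallback. The kernel form is a genuinely open choice; linear is the
  default and RBF is available by configuration.
* **Evaluation**: Mann–Whitney AUC (ties 0.5) on pooled out-of-fold
  decision scores; 95% percentile CI from 1000 patient-level bootstrap
  resamples (single-class resamples redrawn, budget 10·B); model
  comparison by paired bootstrap of ΔAUC with
  p = 2·min(frac(Δ*≤0), frac(Δ*≥0)) clipped to (1/B, 1].
* Selection runs on the full cohort with CV as the search objective — the
  protocol the study design describes. This makes the reported CV AUC an
  optimistic estimate under the null (the forward search maximizes it;
  measured null mean ≈ 0.7 at n = 60). `nested_cv_auc` is the unbiased
  alternative: the entire coarse + fine selection re-runs inside each
  outer training fold, and its permuted-label null is centered at chance.
  The null-calibration experiment uses the nested mode; the optimism of
  the plain mode is itself asserted by a test rather than hidden.
  Transfer evaluation (frozen weights and standardization applied to
  other settings) is unaffected by either choice.

## Study conditions and problem sizes

The default study (`StudyConfig`) uses n = 60 patients at prevalence 0.5,
20 test–retest pairs per setting, 10 mixture cohorts, B = 1000 bootstrap
replicates, and cohort seeds 1–10 for the seed-replication experiments.
Balanced classes stabilize 3-fold CV at this cohort size. One full study
run takes about 45 s on one core; the dominant cost is feature extraction
(~400 lesion renderings × ~0.1 s).

## What the phantom shows — and does not

The generator encodes, by construction, the qualitative orderings the
analysis is meant to detect: mutant lesions are more heterogeneous; the
heterogeneity contrast is larger on thin than thick slices; smooth kernels
are less noisy than sharp ones; mixtures of settings inject
setting-dependent feature shifts. Passing the seed-replication experiments
therefore shows that the pipeline *recovers* these built-in effects through
the full extraction–filter–select–classify chain — not that the effects
hold in real CT data, and not that synthetic effect sizes match any
clinical cohort. Realistic anatomy (vessels, pleura, airways), scanner
MTFs, dose-dependent noise and inter-scanner calibration are all absent;
absolute AUCs here are higher than clinical values because the phantom's
nuisance structure is simpler than biology.

Two of the built-in orderings are weaker than intended at this scale, and
the seed-replication experiments report them as such. Mixture cohorts land
between the thin and thick homogeneous performances rather than below the
worst setting: each mixture model is re-selected on the mixed cohort, and
the scale-free statistics in the cross-setting reproducible feature pool
are robust to the level shifts that mixing injects (mixture ≤ the *mean*
of the four settings in every seed; ≤ the *minimum* in only a few). And
the mutant-above-wild-type LoG-entropy median ordering holds in all four
settings simultaneously in most but not all cohort seeds — with the
per-lesion nuisance spreads that keep AUCs off the ceiling, a 30 + 30
cohort occasionally shows one tiny negative per-setting gap.

## Numerical conventions

* Population (ddof 0) moments throughout feature statistics; kurtosis is
  the non-excess (Pearson) form; skewness/kurtosis of a constant sample
  are defined as 0.
* Equal-width quantization inside the mask; constant regions map to level
  1; min/max map to levels 1 and n.
* NGTDM coarseness is capped at 1/ε = 1e12 (constant regions).
* GLCM correlation of a single-level matrix is defined as 1.
* Mirror boundary for every convolution; all randomness flows from
  explicit integer seeds through `numpy` `SeedSequence` streams, making
  every pipeline output a pure function of (configuration, seed).
* Support-vector fractions are percentages rounded half-up to one decimal.
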