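# reconradiomics

Radiomic analysis of how CT reconstruction settings — slice thickness
(Thin 1 mm vs Thick 5 mm) × convolution kernel (Sharp vs Smooth) — affect a
machine-learning model that predicts EGFR mutation status of lung
adenocarcinomas from texture features of the tumor. The package implements
the full analysis chain as a tested, reusable pipeline and exercises it
end-to-end on a synthetic CT phantom cohort, for researchers studying the
robustness of radiomic signatures to acquisition parameters.

The pipeline:

1. **Feature extraction** — a configurable radiomic bank per lesion
   (volume + binary mask): first-order and Laplacian-of-Gaussian histogram
   statistics at σ ∈ {0, 0.5, 1.5, 2.5} mm, Gabor magnitude at four
   orientations, Laws texture energy, GLCM and NGTDM matrices on 32
   quantized gray levels, shape and margin-sharpness descriptors, in 2D /
   2.5D / 3D aggregations.
2. **Reproducibility filter** — Lin's concordance correlation coefficient
   CCC = 2·cov(x,y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²) on simulated test–retest
   pairs; a feature survives iff CCC > 0.9.
3. **Coarse-to-fine selection** — complete-linkage clustering on 1 − |r|
   cut at 0.8 removes redundant features; six rankers (ReliefF, χ²,
   mRMR, |t|, Wilcoxon |z|, univariate accuracy) each nominate a top-10
   list; a single-pass forward search over a soft-margin SVM
   (box-constraint C = 100, features z-scored per training fold) keeps a
   candidate iff it strictly raises the stratified 3-fold
   cross-validated AUC.
4. **Evaluation** — Mann–Whitney AUC on pooled out-of-fold scores, 95%
   percentile CI from 1000 patient-level bootstrap resamples, paired
   bootstrap p-values for model comparison, transfer of the frozen best
   model across settings, ten random "mixture" cohorts, and the per-setting
   class contrast of the heterogeneity feature `LoG_Entropy_Sigma2.5_2D`.

Because no patient data ship with the analysis, a first-class phantom
module generates the cohort: ellipsoidal lesions whose intra-lesion texture
heterogeneity carries the class label (mutant = stronger, finer-grained,
more multi-modal texture), rendered under all four reconstruction settings
and as same-day test–retest pairs. See `docs/methods.md` for the model and
its assumptions.

## Worked example

```python
import reconradiomics as rr

report = rr.run_study(rr.StudyConfig(seed=1))   # ~45 s on one core
print(report.summary_frame().to_string(index=False))
```

```
  setting   cv_auc   ci_low  ci_high  n_features   ranker  sv_fraction_pct  n_retained
 Thin-Shp 0.981111 0.947230 1.000000           2 wilcoxon             21.7          92
 Thin-Smo 0.928889 0.860751 0.979978           6     chi2             28.3         107
Thick-Shp 0.978889 0.944189 1.000000           3 wilcoxon             23.3         103
Thick-Smo 0.843333 0.730796 0.934916           4   relief             51.7          80
  Mixture 0.873444      NaN      NaN           0                       NaN           0
```

Reading the table: each homogeneous setting gets its own optimal model —
`n_retained` features survived that setting's test–retest CCC filter,
`ranker` produced the winning candidate list, `n_features` were kept by the
forward search, and `cv_auc` is the cross-validated AUC with its bootstrap
CI. On this cohort seed the thin-slice settings outperform their thick
counterparts (0.98 vs 0.98→0.84 within kernel), the thick-smooth setting is
worst and uses the most support vectors (least generalizable fit), and the
mixed-settings cohort (0.873) sits below the homogeneous average —
heterogeneous acquisition parameters cost performance. The report also
carries pairwise model p-values, the transfer matrix of the best frozen
model, and per-class medians of `LoG_Entropy_Sigma2.5_2D` (mutant above
wild-type in every setting here, e.g. 4.800 vs 4.752 on Thin-Smo).

The same stages are scriptable from a shell (`reconradiomics extract`,
`repro`, `select`, `model`, `study run`, `study phantom`); each subcommand
is a thin wrapper over the functions above.

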