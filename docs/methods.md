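# Methods

`aplscreen` implements a two-stage screening method for acute promyelocytic
leukemia (APL) built on data a routine hematology analyzer already
produces: the DIFF- and WNB-channel scattergrams of a blood sample and its
CBC / cell-population-data (CPD) parameters.

## The screening model

**Stage 1 — morphological feature extraction.** Each sample contributes
four 256×256×3 scattergram images: the SS–FL ("XY") and FS–FL ("YZ")
projections of the DIFF and WNB channels. One binary CNN per view is
trained to discriminate APL from non-APL samples (cross-entropy loss, SGD
with momentum and weight decay). Gradient-based class-activation heatmaps
of the APL class are thresholded into regions of interest (ROIs), and each
view is summarized by five deterministic image metrics:

| metric | definition |
|---|---|
| `APL-Ratio` | fraction of foreground ("particle") pixels covered by the ROI masks |
| `ClusterDist` | mean pairwise centroid distance of the 3 largest 8-connected foreground components |
| `Neu-Area` | foreground pixel count inside the neutrophil gate |
| `LymMonDist` | centroid distance between gated lymphocyte and monocyte pixels |
| `NeuMonDist` | centroid distance between gated neutrophil and monocyte pixels |

Four views × five metrics give the 20 scattergram parameters
(`D-APL-Ratio-XY` … `N-NeuMonDist-YZ`).

**Stage 2 — interpretable tabular screening.** The 20 scattergram
parameters are concatenated with 50 routine CBC/CPD parameters into a
70-feature table (RFC-S); a 50-feature routine-only table (RFC-C) serves
as the baseline. After train-only z-scoring, features are selected by
recursive feature elimination scored with stratified 5-fold
cross-validated ROC-AUC, forest hyperparameters are tuned by grid search,
and a random forest with `balanced_subsample` class weights is fitted
(300 trees for RFC-S, 150 for RFC-C; `max_features="sqrt"`). The decision
threshold is tuned on out-of-fold training scores to maximize specificity
subject to a sensitivity floor of 0.95 (Youden's J is available as an
alternative rule). Explanations are exact path-dependent tree-Shapley
attributions on the probability scale.

## Heatmap weighting: a deliberate design choice

Classic Grad-CAM weights each feature-map channel by the *spatial mean* of
the class-score gradient, `alpha_k = mean(dS/dA_k)`, and renders
`ReLU(sum_k alpha_k A_k)`. That weighting relies on deep, wide stacks
whose channels are effectively region- and concept-specific. On the
desk-scale networks this package trains (three small conv blocks and a
fully connected head), the channels are generic blob detectors and the
spatial structure of the classifier lives in the FC head; averaged
channel weights then either cancel under the ReLU or highlight every
dense cluster indiscriminately. The spatially resolved first-order
decomposition `ReLU(sum_k dA_k ⊙ A_k)` — the exact per-location
contribution of the hooked layer to the class score for conv→flatten→FC
architectures — localizes the discriminative cluster correctly, which we
verified directly by comparing gradient maps against the planted cluster
position on synthetic cohorts.

`grad_cam()` therefore exposes both: `weights="mean"` (the classic
formula, the default, validated against a finite-difference oracle) and
`weights="elementwise"`, plus a `target` switch between the raw APL logit
and the two-logit margin. The pipeline feeds ROI extraction with the
elementwise/margin variant; both choices are recorded in the run config.
ROIs are per-sample heatmap components (threshold 0.5 of the
max-normalized map, 8-connectivity, minimum area 20 px); a fixed ROI
template aggregated over training APL heatmaps is a possible variant that
we did not adopt.

## The synthetic cohort generator

No real analyzer data ships with the package, so `synthgram` generates
cohorts with the statistical structure the method assumes:

* **Event clouds.** Each sample gets one DIFF and one WNB cloud of
  ~8–12×10³ events in a unit cube with axes (FS, SS, FL). Common leukocyte
  populations (Neu, Lym, Mon, Eos, Debris) are trivariate Gaussians at
  textbook positions. Disease classes add an abnormal population *on top*:
  the common populations keep identical absolute concentrations across
  classes (their mixture fractions shrink while the per-class event count
  scales up), so the image-level class signal is the planted cluster, not
  a diffuse compositional shift — compositional information is carried by
  the routine parameters instead, as it is in real CBC data.
* **The APL signature.** Abnormal promyelocytes form a *tight* (σ = 0.03),
  high-fluorescence, high-forward-scatter cluster. AML blasts share its
  (SS, FL) footprint in the WNB channel but have ordinary forward scatter
  and a diffuse covariance (σ ≈ 0.08–0.09), so only the FS–FL (YZ)
  perspective resolves APL from AML — the package's analogue of the
  volume-resolved immature cluster that motivates the WNB features. ALL
  lymphoblasts extend the lymphocyte region.
* **Per-sample variability.** The abnormal-cell burden is drawn per sample
  (uniform on 0.10–0.40 for APL, 0.10–0.45 for AML/ALL), and every cluster
  position receives an isotropic Gaussian shift (σ = 0.025) emulating
  patient- and instrument-level drift. Without these, single geometric
  features separate classes perfectly and feature selection collapses to
  one column.
* **Routine parameters.** All 50 parameters are clipped Gaussians; the
  roster (fixed at exactly 50 names) contains the parameters the screening
  literature names (PLT, PCT, WBC, MCV, MCHC, D-Neu-SFL-W, leukocyte
  counts/ratios) padded with standard CBC/CPD names. Disease classes share
  cytopenias — APL and AML values deliberately shadow each other — so the
  routine-only baseline cannot isolate APL, while healthy controls are
  easy for it.

What the generator does **not** emulate: real analyzer optics and reagent
chemistry, true CPD computation, instrument saturation artifacts, or the
morphological heterogeneity of FAB subtypes (coarse- vs microgranular
APL). Passing end-to-end tests therefore demonstrates that the pipeline
recovers a planted morphological signal under realistic noise — not
clinical performance.

## Rendering and preprocessing

Events are projected per view, side scatter is compressed with
`ln(1 + s)` (rescaled by `1/ln 2` so the unit interval maps onto itself),
histogrammed into 256² half-open bins (a coordinate of exactly 1 falls in
the last bin), intensity-mapped with `ln(1 + count)`, min–max scaled to
[0, 255] per image, replicated to three channels, and flipped so high
fluorescence is at the image top. A constant image normalizes to all
zeros ("no particles"); min–max normalization is per-image. Foreground is
channel-mean intensity ≥ 10/255; population gates are fixed pixel
rectangles derived once from the shipped population geometry (±0.14 event
units around each population center, mapped through the render transform).

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| CNN learning rate / momentum / weight decay | 1e-6 / 0.9 / 1e-4 | recorded full-scale values; the desk profile raises the rate to 1e-3, which suits a from-scratch vgg-tiny on ~100 images |
| epochs / batch size | 100 / 10 | "iterations" read as epochs; 100 minibatch steps would be under 3 epochs on any realistic cohort. Desk profile: 10 epochs |
| ROI threshold θ / min area | 0.5 / 20 px | on the max-normalized heatmap |
| foreground threshold τ_fg | 10 (of 255) | particle pixel definition |
| RFE tolerance | 0.003 | smallest width within 0.3 % of the best CV AUC |
| RFE forest size | 100 trees | selection only; the final forest keeps 300/150 |
| grid | trees ∈ {100, 150, 300} × max_features ∈ {sqrt, all} | winning point refit on all training data |
| sensitivity floor | 0.95 | threshold tuning on out-of-fold scores |
| split | 8:2 stratified by 4-way class | fixed seed |

## Numerical choices and degenerate inputs

* Degenerate min–max (constant image) → zeros; degenerate z-score column
  (zero training variance) → sd replaced by 1, column identically 0.
* Empty event cloud renders a blank image with a warning; empty gated
  populations yield 0-valued distance metrics with a logged warning, so
  feature tables stay rectangular.
* RFE drops exactly one feature per step; importance ties break by column
  order. Grid-search ties keep the earliest grid point. Threshold ties
  keep the higher cut; tuned thresholds are clamped to the open unit
  interval at float resolution.
* Connected components use 8-connectivity; equal-area components order by
  first raster occurrence.
* AUC is the trapezoidal/rank statistic with half credit for ties
  (verified against an O(n²) pair-counting oracle).
* Tree-Shapley values are computed per tree with the path-dependent
  polynomial algorithm using `weighted_n_node_samples` covers and averaged
  over the forest, so local accuracy holds against `predict_proba` within
  1e-6.
* All randomness flows from explicit integer seeds (cohort, weight init,
  minibatch order, CV folds, forests); per-view CNN seeds derive from the
  global seed.

## Desk-scale problem sizes

The shipped `desk` profile — used by the test suite and the acceptance
script — simulates 120 samples (40 APL / 30 AML / 20 ALL / 30 HC) at
8 000 nominal events per cloud, trains `vgg-tiny` (≈72 k parameters,
< 1 % of VGG16) for 10 epochs per view, and runs the full tabular stage
on the 96-sample training split. The `full` profile records the
full-scale configuration (VGG16, 100 epochs, study-sized cohort) and is
not exercised by the tests. Metrics at desk scale are properties of the
synthetic cohort, not estimates of the published clinical performance.

## Known limitations

* The numpy CNN stack is CPU-only and single-threaded; VGG16 is buildable
  and runs forward, but training it at full scale is out of desk scope.
* The 20-parameter roster realizes the three metric families (count, area,
  spacing) with one defensible operationalization; "particle count" is
  pixel-count on the density image, since raw event counts are not
  recoverable from exported scattergrams.
* Per-sample heatmap ROIs make the ratio features depend on CNN training
  quality; a saturated network yields conservative (small) ROIs.
* The generator's class geometry is stylized; none of the reported numbers
  transfer to real analyzers without retraining on real cohorts.
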