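# Methods

## Pipeline model

`bonetex` treats opportunistic BMD estimation as a per-slice regression
problem. Each sample is one (case, vertebral level) pair: a 2D axial CT
slice in Hounsfield units, paired with reference DXA BMD values
(total-lumbar and total-hip, g/cm²). The pipeline makes three modelling
assumptions:

* the trabecular compartment of the vertebral body can be isolated by a
  fixed HU window, and a single axis-aligned rectangle inside it is a
  representative texture sample;
* 45 first- and second-order texture statistics of that rectangle carry
  the density signal;
* the feature→BMD map is well approximated on the full sample either
  linearly or by a very small ReLU network, with no held-out split — the
  reported correlations are therefore *in-sample* correlations, a design
  choice inherited from the study protocol this pipeline follows, not a
  generalization claim.

## ROI isolation

Thresholding keeps pixels with `hu_low ≤ HU ≤ hu_high` (defaults 0 and
400: above soft tissue and marrow fat, below cortical bone; both
configurable). A 3×3 morphological closing (on by default in the
pipeline, off in unit-level calls) bridges thin trabecular gaps before the
largest 4-connected component is selected. The requirement that the
rectangle "cover most of the trabecular area" is operationalized as the
**maximum-area axis-aligned rectangle inscribed in the component**,
computed by the histogram-of-heights stack algorithm in O(rows × cols).
Ties are broken deterministically: larger row extent, then smaller
starting row, then smaller starting column. Rectangles below
`min_roi_area` (default 64 px) are rejected as degenerate rather than
silently accepted. This choice is deterministic and parameter-free; it is
a stand-in for whatever manual or semi-automatic placement a clinical
workflow would use, and an exhaustive O(n⁴) enumeration validates it in
the tests.

## Texture features

The 45-vector is ordered and named: `hist_mean, hist_std, hist_skew,
hist_kurt, hist_entropy`, then `glcm_{N}_{direction}_{statistic}` for N in
ascending order, horizontal before vertical, statistics in (entropy,
contrast, correlation, homogeneity, variance).

Numerical conventions, all unit-tested:

* **Histogram features** use population moments (divisor n); kurtosis is
  the non-excess Pearson form m₄/m₂². Entropy is Shannon entropy (log₂)
  of a 256-equal-width-bin histogram over the ROI's own [min, max].
  A constant ROI yields (c, 0, 0, 0, 0).
* **Quantization** is per-ROI min–max equal width,
  `level = floor(N·(x−min)/(max−min))` clamped to N−1. This discards the
  absolute HU scale from the GLCM features (it survives in `hist_mean`);
  because absolute attenuation plausibly matters for BMD, a fixed-window
  mode (`quantize_mode="fixed"`, clipping to a configurable HU window) is
  provided as a first-class alternative and the resolved config records
  which was used.
* **GLCMs** are accumulated symmetrically (each pair increments (i,j) and
  (j,i)) and normalized to total mass 1, the classic Haralick convention;
  a non-symmetric mode exists behind `symmetric=False`. Offsets are one
  pixel: (0,+1) horizontal, (+1,0) vertical.
* **Statistics**: entropy −Σ p log₂ p with 0·log 0 = 0; contrast
  Σ (i−j)² p; correlation from the marginal means/SDs, defined as 0 when a
  marginal SD vanishes; homogeneity in the inverse-difference-moment form
  1/(1+(i−j)²) by default (the 1/(1+|i−j|) variant is selectable, and the
  default matters — the two differ numerically); variance is the Haralick
  sum-of-squares on the row marginal, which equals the column form for
  symmetric matrices.

These formulas are the standard literature forms; where the originating
study protocol left a convention open (symmetry, variance definition,
bin counts, moment divisors) the choice is fixed here, documented, and
covered by closed-form tests (e.g. a two-column stripe image must give
correlation −1, contrast (N−1)² and entropy exactly 1 bit at every N).

## Regression

Features and the reference are z-scored with the **sample** (n−1) mean/SD;
zero-variance columns are flagged and map to 0. The linear model is
ordinary least squares on the normalized data (weights + bias minimizing
MSE), solved with a rank-tolerant solver so that rank-deficient designs —
easily reached with 45 features and a small cohort — get the minimum-norm
solution. No regularization and no train/test split are applied by
default, matching the protocol this pipeline implements.

The ANN is a fixed 45-8-8-2-1 multilayer perceptron, ReLU on hidden
layers, a single linear output node (one BMD value forces the output
width). Training specifics are this package's own choices, all explicit
in `AnnTrainingConfig` and logged with the model: full-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate 1e-3, 2000 epochs,
Glorot-uniform weight initialization, hidden biases initialized to 0.1,
MSE loss, fixed seed. Everything is pure NumPy, so a fixed seed gives
bit-identical models across runs and the whole model (weights,
normalization, config, loss history) serializes to JSON.

The 0.1 bias initialization is a deliberate numerical choice: with only
two units in the last hidden layer, zero-initialized biases occasionally
let all ReLUs in that layer die early in training, freezing the network at
a constant prediction (observed at roughly one in ten seeds on noisy
cohorts). Slightly positive biases remove the failure mode without
affecting the network's capacity; final training MSE on noiseless linear
data (n = 300) stays below 0.05 on the normalized scale across all tested
seeds, typically below 0.01.

## Evaluation

Pearson product-moment correlation between predicted and reference BMD,
computed per (model, target): pooled over all samples and stratified by
vertebral level, with at least 3 usable rows per reported cell. Constant
inputs raise an error rather than silently reporting 0. The
`lumbar_total_excl_L1` target drops L1 rows from the *pooled* estimate
while still reporting the L1 stratum, so both the per-level and the
excluding-L1 readings of a cohort are available from one report. Each
target's correlations are computed from the model fit against that
target's reference. Rows with a missing reference are dropped and counted,
so usable + dropped = input for every target. Spearman correlation is
available for robustness studies but not reported by default; no p-values
or agreement statistics are computed.

## Synthetic phantom generator

The generator is a test instrument, not an anatomical model. One slice =
soft-tissue background (−50 HU), an elliptical body with a cortical rim
(bone + 400 = 700 HU), and a two-phase trabecular interior: a unit
Gaussian field smoothed with σ = `correlation_length` (default 2.5 px) is
thresholded at its interior (1−d) quantile; pixels above threshold get
`bone_hu` (300), below `marrow_hu` (100); independent N(0, 5 HU) noise is
added everywhere. The bone-pixel fraction therefore equals the latent
density d up to quantile granularity, and interior mean HU runs linearly
from 100 to 300 as d goes 0→1 — the clinically typical trabecular range.
The palette is chosen so the whole interior sits inside the default
[0, 400] ROI window while the background and rim sit outside it, making
ROI isolation well-posed by construction.

Cohorts draw one density per case, uniform on [0.05, 0.95], and give each
vertebral level that density plus N(0, 0.03) jitter (clipped to [0, 1]),
mirroring the modest inter-vertebral variation of real spines; fully
independent per-level densities would make the case-level reference
unpredictable from a single slice by construction. The lumbar reference is
`0.6 + 0.6·mean(d)` g/cm² over the case's levels; the hip reference uses
coefficients (0.9·0.6, 0.85·0.6) to emulate an imperfectly matched second
site; optional Gaussian noise `bmd_noise_sd` (default 0) models
CT–DXA discordance. All randomness derives from one seed through
independent child streams, so cohorts are byte-reproducible and changing
the BMD noise leaves the rendered slices untouched.

What the generator does **not** emulate: 3D anatomy and partial-volume
effects, beam hardening and scanner kernels, marrow-fat variation,
degenerative sclerosis, aortic calcification, fractures. Passing the
end-to-end tests therefore shows the pipeline is a faithful, deterministic
implementation of the method with enough sensitivity to recover a planted
density→BMD link; it does not show that the method attains any particular
accuracy on patients.

## Problem sizes and defaults

The package's reference experiments use 128×128 px slices (ellipse
semi-axes 48×38 px, rim 3 px), 3 lumbar levels per case, and cohorts of
40 (examples) to 200 (acceptance runs) cases — sizes at which the full
simulate→extract→fit→evaluate loop completes in seconds to tens of
seconds on one CPU while leaving the ROI large enough (typically ~60×50
px) for stable co-occurrence estimates at N = 128.

## Known limitations

* One ROI per slice; vertebra detection/labeling and slice selection
  within a scan are the caller's responsibility.
* In-sample correlation only; no cross-validation or uncertainty
  quantification.
* Repeat cases from the same patient are kept (patient_id is carried so
  users can deduplicate) but no clustering correction is applied.
* The HU threshold window is global and fixed per run; pathological
  attenuation (sclerosis, contrast) will bias the ROI.
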