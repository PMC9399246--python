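# Methods

`anoscore` implements a pipeline for quantifying the cosmetic abnormality
of reconstructed breasts from routine follow-up CT, and for analyzing how
that abnormality evolves after post-mastectomy radiotherapy.  Because the
clinical CT archive behind the original analysis is not public, the
package ships seeded synthetic generators that emulate both ends of the
pipeline — surface renders and longitudinal score trajectories — and every
statistical claim the test suite makes is about those synthetic study
conditions.

## 1. From volume to image

A CT series (or synthetic density volume) is reduced to a 2D frontal
surface render:

1. **Volume.**  `VolumeGrid` holds a 3D scalar field with mm spacing;
   axis 0 is anterior–posterior (index 0 anterior), axis 1 left–right,
   axis 2 cranio–caudal.  DICOM series are sorted by slice position and
   rescaled to HU.
2. **Isosurface.**  Marching cubes at a configurable level (−300 HU for
   CT skin/air; 0.5 for phantom density fields).
3. **Frontal render.**  An orthographic *depth map*: each pixel records
   the distance from the anterior image plane to the first surface
   crossing along the AP axis, with sub-voxel linear interpolation of the
   crossing.  Hit depths are min–max normalized into [0, 0.95]; rays that
   miss are background and are exactly 1.0 (white), so the surface is
   always darker than the background.  The original workflow captured a
   white-on-white shaded isosurface in a commercial viewer with unstated
   lighting and projection; the depth map is a deliberate, deterministic
   proxy that preserves the 3D shape information a 2D network can see.
   It is a proxy, not a replication.
4. **Resize.**  Bilinear, clipped to [0, 1]; the published pipeline's
   500×500 intermediate and 256×256 model input are both supported.

## 2. Phantoms

`make_phantom_volume` builds a half-torso slab with two hemispherical
mounds on its anterior face.  The field is a binary occupancy map passed
through a Gaussian filter (σ = 1 voxel).  Noise (`noise_sd`, default
0.01) is added to the occupancy *before* smoothing, modeling smooth
density inhomogeneity.  This ordering matters: voxel noise added after
smoothing lets single voxels near the iso level flip grazing rays at the
torso silhouette, which destabilizes the depth range that the min–max
normalization divides by, and that instability — not anatomy — then
dominates the rendered image.

Four anomaly kinds deform the left mound, each scaled by a severity in
[0, 1] and each reducing to the normal phantom exactly at severity 0:

| kind            | geometry at severity s |
|-----------------|------------------------|
| `asymmetry`     | mound shifted medially by 0.5·s·r and shrunk by 25%·s |
| `missing_mound` | radius scaled by (1−s); fully absent at s = 1 |
| `contracture`   | radius shrunk by 50%·s and center pushed posteriorly (flattening) |
| `expander_bulge`| radius widened by 80%·s with a flattened anterior cap, capped at the normal protrusion |

These are geometric stand-ins for clinical deformity (the real outcomes
are capsular contracture, flap deformity, expander asymmetry); they were
designed so that the rendered image deviation grows monotonically with
severity, which `analysis/01_simulate_phantoms.py` verifies directly in
image space.  Dataset generation jitters mound radius and separation by
±5% per image so "normal" is a distribution, not a single image.

## 3. Anomaly model

The model is a fast anomaly GAN trained on normal images only:

* **Stage 1 — WGAN-GP.**  Generator G and critic D trained under the
  Wasserstein objective with gradient penalty (weight 10), 5 critic
  updates per generator update, Adam (β₁ = 0.5, β₂ = 0.999, lr 10⁻³).
  The printed description of the adversarial objective in the source
  method mixes the log-loss minimax form with a Wasserstein training
  procedure; this implementation follows the Wasserstein-with-penalty
  form throughout.
* **Stage 2 — izi_f encoder.**  With G and D frozen, an encoder E
  minimizes `Loss_izi = Loss_images + k·Loss_features` where
  `Loss_images = (1/n)‖X − G(E(X))‖²` and
  `Loss_features = (1/m)‖f(X) − f(G(E(X)))‖²`, f(·) being the critic's
  hidden-layer activation of dimension m.  The weighting factor k is not
  published; the default is k = 1 as in the original anomaly-GAN method.

**Networks are fully connected**, implemented in numpy with manual
backpropagation (no deep-learning framework is required at runtime).
G: latent → hidden → pixels (ReLU/sigmoid); D: pixels → hidden → scalar
(leaky-ReLU 0.2), the hidden activation doubling as the feature map f;
E mirrors D into the latent space.  For a one-hidden-layer critic with
piecewise-linear activations, the input gradient is
`∇ₓD = W₁(s ⊙ w₂)` with locally constant slopes s, so the gradient
penalty's parameter gradient has a closed form and no double
backpropagation is needed.  Float32 arithmetic; all randomness flows from
the seed in the hyperparameter block, so training is bit-reproducible on
a fixed BLAS.

The published full-scale configuration (256×256 input, latent 128, batch
32, 7000 epochs) is expressible through `GanHyperparams` but is a
long-running job; the tested configuration is the toy scale below.

## 4. Anomaly score

For an image X with reconstruction X′ = G(E(X)):

    AS(X) = (1 − λ)·R(X) + λ·D(X),   λ = 0.95 by default,

with R(X) the image-space mean-squared residual and D(X) the critic
feature-space mean-squared residual.  Raw scores are standardized as
z-scores against a normal reference set — by default the raw scores of
the normal training images themselves (the alternative, a held-out normal
set, is a one-line switch).  Standardization is global, not per visit,
since scores are compared across time points.  Missing visits in a
patient's series are reported absent, never imputed.

## 5. Longitudinal analysis

Scores over the three CT visits (pre-RT day 0, one and two years after
RT) are analyzed three ways:

* **Pairwise paired t-tests** between visits, overall and stratified by
  major complication and reconstruction type.  Degenerate strata (under
  two complete pairs, zero-variance differences) are reported as such.
  P-values are unadjusted, matching the source analysis; a Bonferroni
  column is emitted alongside.
* **Trajectory patterns** per patient: the signs of (z₁ᵧ − z_pre) and
  (z₂ᵧ − z₁ᵧ) give increasing / decreasing / inc-dec / dec-inc, with
  |Δ| ≤ 0.1 z-units treated as no change and a fifth `flat` class when
  both segments are flat (a tolerance the four-pattern description leaves
  implicit; a segment-level tie inherits the other segment's direction,
  making the classifier exhaustive and mutually exclusive).
* **Random-intercept LME.**  AS ~ days + reconstruction type +
  type×days + fractionation + fractionation×days + mastectomy type +
  SCL + IMN + boost + plan + complication + age + BMI>23, random
  intercept per patient, fit by maximum likelihood (not REML, so nested
  contrasts are coherent) via statsmodels MixedLM, with Wald 95% CIs and
  p-values and no small-sample df correction.  Age enters centered at 50
  years.  "Days after RT" and "days after baseline" are treated as the
  single time variable days-since-baseline-CT.  The optimizer falls back
  from L-BFGS to BFGS/Powell when the intercept variance collapses to the
  boundary; convergence is reported honestly in the fit object.
* **Contrasts.**  The expander-vs-autologous (or hypo-vs-conventional)
  difference at day d is β_type + d·β_type×days with a delta-method Wald
  interval from the fixed-effect covariance, evaluated on the grid
  0/180/360/540/720 days.

## 6. Cohort simulator

`generate_cohort` draws, per patient: binary covariates from marginal
frequencies matching the published cohort (expander 0.230,
hypofractionation 0.131, NSM/SSM 0.361, boost 0.197, IMRT 0.213,
complication 0.164, BMI>23 0.475; SCL and IMN, whose frequencies are not
published, default to 0.5), age uniform on 30–70 years, visit days
uniform over the published interquartile ranges (1-year visit 343–512
days, 2-year 741–951 days), a patient intercept b_i ~ N(0, 1.5²), and
residuals ε ~ N(0, 1²).  The generating fixed effects default to the
clinically estimated nonzero coefficients (days 0.004/day, expander
+2.223, age 0.073/year) with all other effects zero.  One global integer
seed drives a single generator stream; per-patient values are drawn in a
fixed order, so cohorts are bit-reproducible.

## 7. Problem sizes and what the tests show

The tested configuration is deliberately small: 64×64 renders, 200
normal training phantoms, 2000 generator steps, 1000 encoder steps,
latent 32, hidden width 128 (training ≈ 4–6 minutes on one CPU);
recovery experiments use 20 replicates of 200 patients × 3 visits.
At this scale the suite verifies:

* exact arithmetic identities (score weighting, loss decomposition,
  z-score moments, contrast linearity) to machine precision;
* rendering against closed forms (sphere depth within one voxel,
  marching-cubes area converging to 4πr²);
* that severity-1 anomalous phantoms receive stochastically larger
  z-scores than held-out normals (Mann–Whitney, n = 30 per group), and
  that three-visit severity progressions score non-decreasingly in ≥ 80%
  of series;
* that the mixed model recovers the generating coefficients within
  Monte-Carlo error with 95% CI coverage between 90% and 99%.

What passing these tests does **not** show: that the score tracks human
cosmetic judgment on real anatomy.  The phantoms have no ribs, arms,
posture variation, scanner artifacts or registration error; the anomaly
geometries are stylized; the depth-map render is a proxy for the original
shaded-surface capture.  Clinical validity of the score remains a claim
about the original data, not something this package can establish.

## 8. Numerical and design notes

* Depth normalization is per image (min–max), as specified for the
  render contract; consequently absolute protrusion scale is not
  preserved, only shape.  The expander-bulge anomaly caps its anterior
  protrusion at the normal mound's for exactly this reason — severity
  expresses as widening/flattening rather than as a rescaling of the
  whole depth range.
* `fit_reference` requires ≥ 2 finite scores with nonzero variance and
  uses the n−1 sample SD.
* The paired t-test rejects (rather than returning ±∞) when the
  difference variance is zero; incomplete pairs are dropped first.
* Rank-deficient LME designs are rejected with the offending columns
  named; constant covariate columns are the common cause in small
  simulated cohorts.
* Training aborts with the step index on any non-finite loss.
* Checkpoints are an `.npz` of weights plus a JSON manifest
  (hyperparameters, seed, step counts); reloading reproduces scores
  exactly.
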