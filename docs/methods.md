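# Methods

This note documents the models and procedures implemented in
`broilergait`, the assumptions behind them, the simulator that stands in
for video data, and the numerical and design choices a user should know
before trusting (or extending) the results.

## The measurement problem

A rear-view camera at bird height films one broiler at a time walking a
3 m × 0.4 m corridor (12 fps, 1280 × 720 px).  A pose-estimation network
exports, per frame, image coordinates and a detection likelihood for 8
keypoints: head, neck and the left/right knees, hocks and feet.  The
pipeline works entirely in image coordinates — origin top-left, y
increasing downward, so "on the ground" means *larger* y — and uses only
the six leg keypoints for features.

Two instants of the gait cycle are informative and reliably detectable
in 2D: **double support** (both feet planted) and **maximum leg lift**
(one foot at the apex of its swing).  All features are angles, ratios,
or lengths relative to the per-frame normalization factor
N = max(foot y) − min(knee y), which makes them invariant to
translation and uniform scale, hence comparable across ages and camera
distances.  Feature definitions are in the README; left/right sided
features are kept separate until the statistics stage.

## Cleaning rules

* Trials are clipped to manually recorded start/end frames (inclusive,
  0-based), then floor(0.10·n) frames are dropped from each end: corridor
  entry and exit are unreliable for tracking.
* A frame is pose-eligible iff **all six** leg keypoints reach the
  likelihood threshold τ = 0.6.  The joint rule is deliberate: every
  feature needs several leg points in the same frame.
* Optional smoothing (default on) fits a cubic smoothing spline per
  coordinate series over eligible frames.  The smoothing strength is
  s = n·σ̂², with σ̂ the median absolute second difference scaled to a
  Gaussian sigma (0.6745·√6).  Second differences cancel locally linear
  motion, so genuine movement does not masquerade as noise, and a
  noiseless series yields an interpolating spline (identity).  Two
  guards: series with σ̂ < 0.5 px (below quantization relevance) are
  left untouched, and no point may move more than a configurable cap
  (default 10 px).

## Phase detection and pose selection

Ground contacts are local maxima of a foot's y series (with plateau
support — a planted foot holds a level for several frames); lifts are
local minima.  Extrema are computed on the eligible-frame subsequence
with prominence max(3·σ̂, 0.08·N̂), where σ̂ is the median absolute
frame-to-frame difference and N̂ a median per-frame normalization
estimate.  The relative floor matters: a standing bird's detector noise
must not masquerade as strides (a real lift is 30–50% of N), and it is
what turns a non-walking bird into a clean "no pose of any kind"
exclusion instead of garbage poses.

A foot is *in contact* at a frame when its y is within 0.10·N̂ of its
own contact level (median y over its maxima); using each foot's own
level tolerates camera tilt.  Candidates are then

* double support: eligible frames with both feet in contact, ranked by
  |Δy| ascending;
* step left/right: lift minima of that foot while the other is in
  contact, ranked by y_other − y_lifted descending.

Up to k = 3 frames per kind are selected under a pairwise separation of
min_separation = 7 frames (half the default stride period), forcing
frames from distinct gait cycles.  Selection is exact: among all
feasible subsets of maximal size it optimises the summed criterion,
ties broken toward earlier frames (candidate counts are a handful per
cycle, so exhaustive search is cheap and deterministic).  Features are
averaged over the selected frames; a bird-age with no pose of any kind
is excluded and logged.

## Rater model and agreement

Each bird's gait is the mean of four raters' integer 0–5 scores; the
binary classes are good (mean ≤ 2) vs suboptimal (> 2), with 2.5 and 3
available as robustness cutoffs.  Interobserver agreement uses Fleiss'
κ over the six categories (undefined, and flagged as such, when a
single category is used); intraobserver reliability uses Cohen's
weighted κ between two passes, with w_ij = 1 − (|i−j|/5)^p, p = 1
(default) or 2.  Agreement bands follow the conventional labels with
printed upper bounds inclusive (κ = 0.20 → slight, 0.205 → fair, …).

## Statistics

* **Outliers**: within each age × feature (sides pooled), values outside
  [Q1 − 2·IQR, Q3 + 2·IQR] are discarded; quartiles use linear
  interpolation (numpy default, configurable).  Note the fence sits
  ≈ 3.4σ out on Gaussian data, so clean cohorts are usually untouched
  but not always — roughly one sample in eight loses a point at
  n ≈ 164.
* **Class contrasts**: sided features are fit by OLS
  `value ~ class + body weight + side + class×side`; if the interaction
  has P > 0.05 the model is refit without it and the class coefficient,
  its 95% CI and P are reported from the refit.  Unsided ratios (HKDR,
  HFDR) drop the side terms.  "Value at good gait" is the model-implied
  good-class mean at covariate means with sides averaged.  The
  percentage difference 100·diff/value_at_good gets a delta-method CI
  over the full coefficient covariance.
* **Correlations**: Pearson r over birds at the oldest age, sides
  averaged per bird first; two-sided P from the t transform.
* **Body weight**: repeated measures across ages are compared between
  classes with a GEE marginal model (Gaussian, weight ~ age × class,
  exchangeable working correlation on bird, robust SEs); the per-age
  contrast is the class term plus the age interaction.
* P ≤ 0.05 is significant, 0.05 < P ≤ 0.10 a tendency; no
  multiple-testing correction is applied, and reports should say so.

## The synthetic cohort

The simulator replaces the unavailable recordings.  Design goals, in
order: (1) exact inverse consistency — in the noiseless limit the
pipeline must recover the generating truth to ≤ 1e-6 relative error for
all seven features; (2) population structure calibrated so that a
simulated study cohort (48 good + 36 suboptimal birds) reproduces the
study's descriptive statistics, class effects, correlation structure
and rater-agreement regime; (3) realistic failure modes (dropout,
noise, non-walkers).

**Skeleton.**  A bird is a planar chain per leg: foot → hock (shank,
length L_s) → knee (tibiotarsus, L_t).  The primitive truths are the
per-side hock and shank angles, the relative tibiotarsus length τ, the
hock–feet distance ratio, and a pixel scale N.  Chain closure fixes
everything else: L_t = τ·N; L_s is chosen so the taller leg's vertical
knee-to-foot extent equals N exactly; the foot spread follows from the
HFDR.  Consequently the relative shank length and HKDR are *derived*
quantities — a planar skeleton cannot set all published features
independently (with τ ≈ 0.55 the closure forces shank_rel ≈ 0.48, not
the printed 0.45; HKDR lands at ≈ 0.63–0.65, matching the printed 0.65
with no dedicated parameter).  This is the main structural difference
from real 3D birds, whose out-of-plane segment pitch breaks the
closure.

**Gait.**  Stride period 1.25 s (15 frames at 12 fps), stance fraction
0.6, right foot phase-shifted by 7/15 of a cycle.  These defaults put
both double-support windows and both swing apexes exactly on the frame
grid — the condition for exact inverse consistency — while a trial of
8 s contains ≥ 5 strides, guaranteeing ≥ 3 candidates per pose kind.
A swinging foot follows a half-sine of amplitude (step height %)·N/100;
its hock rises half as much and the knees hold their stance height, so
N measured at the apex equals its stance value and the extracted step
height equals the truth.  Both feet are never airborne.  Lateral sway
translates the whole skeleton (features are translation-invariant).
Non-walkers stand still (feet planted throughout) and are excluded by
the pipeline exactly like the study's non-walking birds.

**Population layers.**  Feature dispersion is built in four layers:
bird-level truth SDs, persistent left/right asymmetry, per-stride
jitter (angles, step height, torso pitch), and the measurement layer
(Gaussian pixel noise, sd 2.5 px; likelihood dropout 5% per leg
keypoint-frame, more for head/neck).  A per-bird latent *crouch* factor
loads negatively on both leg angles (and on HFDR), which is what makes
the two angle features correlate strongly across birds.  Suboptimal
birds receive additive class effects (hock −2.2°, shank −1.3°,
τ +0.01, HFDR −0.03, step −4.5 pp, plus age-specific body-weight
contrasts 9.7/26.4/64.3 g); age-level cohort means are stored at the
reference 48:36 class mixture and un-mixed internally, so a cohort
simulated at those proportions reproduces the cohort-level means.

**Calibration.**  Where the study reports a quantity, the defaults are
solved or measured to reproduce it *at the pipeline output*, not at the
latent truth level:

* Extraction is not unbiased: noise inflates N through order
  statistics (max of feet, min of knees), arccos curvature biases
  angles, and best-of-candidates selection inflates step height.  The
  default truth means therefore carry a small *extraction-bias
  compensation* (hock −0.32°, shank −0.12°, τ −0.0105, step +1.06 pp at
  N = 130 px, scaled by 130/N for other ages), estimated by simulation
  over 65 cohorts and frozen, so that extracted cohort means land on
  the published descriptive values.
* Dispersion is apportioned across the four layers so that the
  *sampling SD of the class-effect estimator* matches the published
  standard errors (hock ≈ 1.07°, step ≈ 1.40 pp, HFDR ≈ 0.013) — the
  condition under which estimated class effects fall inside the
  published 95% CIs in ≈ 95% of cohorts.  A consequence, and a known
  limitation, is that pooled record-level SDs for some features run
  below the published ones (hock ≈ 5.3 vs 6.9; step ≈ 7.5 vs 9.6;
  tibiotarsus ≈ 0.015 vs 0.05): the published record SDs and the
  published SEs cannot both be honoured by a generator whose records
  share bird-level variance, because the study's OLS treated side
  records as independent.
* The crouch loadings (3.65°/3.35° per unit latent, with small
  residual SDs) set the angle–angle correlation near 0.75; the
  tibiotarsus truth SD (0.005) and torso-pitch jitter (4.5 px) place
  the tibiotarsus–shank correlation near −0.6.  Notably, measurement
  noise alone anticorrelates the two relative lengths at r ≈ −0.5:
  hock-keypoint noise splits the leg into complementary segments while
  both share the same N — the same mechanism a real pipeline would
  exhibit.
* The rater model maps a lameness latent through rater-specific biases
  (±0.2, ±0.07) and noise (sd 0.5) to integer scores, redrawing until
  the mean lands on the bird's class side; calibrated to Fleiss'
  κ ≈ 0.30 (fair) and repeat-pass weighted κ ≥ 0.76.

**What passing tests do and do not show.**  The synthetic cohort
validates the *pipeline* — phase detection, selection optimality,
feature geometry, the statistical machinery — under a kinematic model
whose assumptions (planar skeleton, fixed stride period, half-sine
swing, Gaussian noise, ignorable occlusion) are simplifications.
Passing recovery tests says the software measures what it claims on
data of known truth; it does not certify performance on real videos,
where out-of-plane motion, tracking identity errors and non-stationary
gait are the dominant error sources.

## Problem sizes and determinism

Default analyses use the study-sized cohort (84 birds, one or three
ages; a trial is 96 frames).  The recovery tests run one such cohort
for descriptive means and correlations and 100 seeded cohorts for
CI-coverage of the class effects.  Every stochastic stage draws from a
generator seeded by the single pipeline seed (child seeds < 2^31), so
a fixed seed reproduces every output byte-for-byte.  Single-cohort
checks at n = 84 remain ~2-SE lotteries: the angle–angle correlation
has a per-seed sd of ≈ 0.05, cohort feature means of ≈ 0.3–0.6 units,
so roughly one seed in ten misses some individual ±2 SE band even
though the estimators are centered.

## Known limitations

* Planar closure ties relative shank length to the other primitives
  (see above); shank_rel ≈ 0.48 rather than the printed 0.45.
* Pooled record-level SDs below published values for step height and
  tibiotarsus relative length (see Calibration).
* The spline stage is a generic cubic smoothing spline; no claim of
  equivalence to any specific pose-estimation post-filter is made, and
  it can be disabled (`clean.smoothing: none`).
* Temporal gait features (speed, cadence, stride length) and 3D angles
  are out of scope; so is running any pose-estimation network.
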