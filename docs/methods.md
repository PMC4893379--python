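# Methods

## Problem setting

A TAVI cannulation on an aortic-arch phantom is observed only through
video of the fluoroscopy monitor. The tip of the catheter/guidewire is
tracked in 2D pixel coordinates, the procedure is split into two stages —
stage 1: navigation from the descending aorta through the arch to ~2 cm
proximal to the valve; stage 2: crossing the stenotic valve into the
ventricle — and per-stage kinematic features are compared between
experience groups and equipment types. No recordings of the original
study are available, so a synthetic generator reproduces the *structure*
of the data; every quantitative claim the package makes is therefore a
property (directions of contrasts, exactness of oracles, accuracy bands),
never a reproduction of the study's printed medians.

## Feature definitions

For a stage interval of length `T_p` and a trajectory restricted to it:

- `PL` — sum of Euclidean steps between consecutive samples;
- `v_d = PL / T_p` — pauses lower it even though `PL` ignores them;
- `a_d` — mean over samples of `sqrt(a_x^2 + a_y^2)` (mean magnitude, not
  magnitude of the mean; a flag-free design choice, the alternative
  reading would cancel oscillating accelerations);
- `j_d = (0.5 ∫ x'''^2 + y'''^2 dt) · T_p^5 / PL^2` — dimensionless jerk.
  The normalization makes it invariant to spatial scaling and time
  dilation; a single minimum-jerk movement `s(τ) = 10τ^3 − 15τ^4 + 6τ^5`
  yields `0.5 ∫ (60 − 360τ + 360τ²)² dτ = 360` exactly;
- `d_tip`, `d_shape` — mean bilinear lookup of the wall-distance image at
  tip samples (resp. all annotated catheter-shape points) of the stage.

## Differentiation pipeline

Raw tracks are pixel-quantized, so derivatives are computed on a
preprocessed copy: linear resampling onto a uniform grid (default
dt = 1/25 s, the PAL video rate; the grid step is the nearest divisor of
the time span so both endpoints are kept), then Savitzky–Golay smoothing
(window 9 samples, order 3). Second and third derivatives use
Savitzky–Golay FIR differentiators (`mode="interp"`): these are the
least-squares generalization of central differences, and crucially their
boundary estimates come from the same local polynomial fit. Naive
repeated `np.gradient` has O(1) one-sided errors at interval edges that
alone cost ~1% on the analytic `j_d = 360` check; with the SG
differentiator the 1 kHz error is ~0.06% and decreases monotonically with
dt. When smoothing is disabled the fallback is repeated second-order
central differences. The jerk integral uses the trapezoidal rule over the
stage interval, with `T_p` and `PL` of the same interval. Stage cuts land
on the sample nearest each annotated boundary.

## Segmentation and distance image

Binarization is strictly `intensity > threshold`; `"auto"` maximizes
between-class variance (Otsu). The distance image is the exact Euclidean
distance transform (pixel-center metric), not a chamfer approximation, so
it is bit-identical to the O(N²) all-pairs definition — both compute the
square root of the same minimal integer squared distance. An optional
largest-connected-component filter handles salt noise; it is off by
default because clean phantom images do not need it.

## Tip tracking

Per frame, a square template (radius 7 px) is matched by brute-force
zero-normalized cross-correlation at every integer offset within a
15 px search window (ties: smallest offset norm, then row-major;
zero-variance patches score 0). Two accuracy measures follow from a
refresh-every-frame design, which matches appearance only *relatively*:

1. integer offsets quantize each frame-to-frame displacement and the
   residuals accumulate as drift, so after the integer match the ZNCC is
   re-evaluated against bilinearly interpolated patches on a two-stage
   fractional grid (0.1 px, then 0.02 px) around the peak, and the
   template's known sub-pixel residual is carried and added back;
2. interpolating sharp edges biases the fractional estimate in the
   direction of motion, so frames are band-limited with a Gaussian
   (sigma 1 px) before matching.

With both measures the round-trip error on rendered video is ~0.1 px RMS;
without them it exceeds several pixels over a few hundred frames. Frames
whose best score falls below 0.6 are flagged; a `{frame: (x, y)}` re-seed
mapping replays the interactive bootstrapping a live session would use.
Template/search radii and the threshold are configuration, as no
authoritative values exist.

## Exact small-sample tests

With 6 subjects per group, normal approximations are poor and cannot
produce the attainable floors, so both tests enumerate exactly on the
observed (possibly tied) values with mid-ranks: Mann–Whitney over all
C(n1+n2, n1) group assignments, Wilcoxon over all 2^n sign patterns after
dropping zero differences. Two-sided p doubles the smaller tail
(including the observed value), capped at 1. The n = 6 signed-rank floor
is 2/2^6 = 0.03125. Note that 0.008 is not an attainable exact two-sided
Mann–Whitney value at 6 vs 6 (the neighbourhood holds 2·4/924 ≈ 0.0087 and
2·2/924 ≈ 0.0043); the package reports exact values only.

## Clustering

k-means (k = 2) runs Lloyd iterations from 100 random 2-point
initializations; an emptied cluster is re-seeded at the point farthest
from the surviving center; the best within-cluster SSE wins. On 12-point
datasets this recovers the exhaustive-bipartition optimum essentially
always. EM fits a 2-component *diagonal* Gaussian mixture (full
covariances are singular at n = 12), initialized from the best k-means
partition, with a variance floor of 1e-4 of the column variance and a
per-iteration log-likelihood trace that is checked to be non-decreasing;
70% confidence-ellipse radii are reported for plotting. Accuracy against
known labels is maximized over the two cluster-to-label bijections.

Features fed to clustering are log10-transformed (when strictly positive)
and then z-scored. All four inputs (`T_p`, `v_d`, `a_d`, `j_d`) are
positive ratio-scale quantities, and `j_d` spans orders of magnitude —
its `T_p^5` normalization amplifies duration contrasts — so a linear
z-score would collapse such a column into a single outlier indicator and
k-means would split on within-group speed outliers instead of the group
structure. The transform is a package design choice (the study reports no
preprocessing at all, not even standardization) and can be disabled.

## Synthetic generator

**Geometry.** Canvas 720x576 (the normalized screen size). Descending
limb: vertical, 200 px, radius 18 px; arch: semicircle of radius 120 px;
ascending limb tapering from 18 px to a 6 px valve stenosis, then
widening into a 26 px ventricle chamber (a widened tube approximates the
chamber; its exact shape is immaterial to the features). Stage 2 begins
40 px proximal to the valve — 2 cm at an assumed 20 px/cm, since no image
scale is documented. The frame rate defaults to 25 fps (PAL, implied by
720x576); both are configuration.

**Trajectory model.** Arc-length progress along the centerline is a chain
of `n_submovements` minimum-jerk profiles with lognormal-jittered
durations, separated by pauses totalling `pause_fraction` of total time;
with probability `correction_prob` a sub-movement overshoots by 10–25%
and a corrective back-movement (40% of the duration) follows. Lateral
offset is an AR(1) process (coefficient 0.95 — catheters deflect
smoothly, not as white noise) with stationary sd `lateral_sd`, clipped
1.5 px inside the lumen; tremor is white positional noise. Equipment
scales durations by `1/speed_scale`.

**Defaults.** Expert: 6 sub-movements of 2.0 s, pause fraction 0.05,
tremor 0.5 px, correction probability 0.05, lateral sd 1 px. Novice: 18
sub-movements of 3.0 s, pause 0.35, tremor 1.5 px, corrections 0.4,
lateral sd 3 px. Robotic `speed_scale` 0.5 vs conventional 1.0.
Sub-movement counts/pauses/tremor/corrections and the speed scale encode
the qualitative expert-novice and equipment contrasts of the study;
durations and lateral sds are chosen to give plausible phantom completion
times (tens of seconds to minutes). Cohorts draw per-subject lognormal
multipliers (sigma 0.2) on duration, pause odds, sub-movement count and
tremor, shared across a subject's two runs so the equipment comparison is
genuinely paired. Shape annotations sample every 25th frame plus one
frame near each stage midpoint, resampled to 15 points along the
trailing centerline.

**What the generator does and does not emulate.** It reproduces the
*directions* the analysis relies on — experts faster and smoother,
robotic slower — and realistic nuisance structure (tremor, pauses,
corrections, between-subject spread). It does not calibrate magnitudes to
the study's medians (those depend on unknown scale/fps), does not model
contrast changes, occlusion, blur, catheter bending dynamics or
perfusion, and its tremor inflates the measured novice path length enough
that the novice `v_d` can exceed the expert's — the opposite of the
study's direction for that one feature. Passing tests therefore certify
the pipeline's correctness and the recoverability of the main contrasts,
not real-video performance.

## Determinism and problem sizes

Every stochastic step (simulation, clustering restarts, EM init) derives
from explicit integer seeds; cohort generation spawns per-run seeds from
one `SeedSequence`. Test and acceptance problem sizes — 100 cohorts for
the contrast-recovery property, 100 random 64x64 masks for the distance
oracle, 50 datasets for the k-means optimum, ~300-frame videos for
tracking — were chosen so each check is statistically meaningful while
the whole suite stays desk-scale.

## Known limitations

- The simulator's `v_d` direction issue above; `a_d` contrasts are weak.
- The tracker assumes a locally rigid appearance; it has no occlusion
  model, and near-wall templates can latch onto the static wall edge
  (exactly the failure mode the flag/re-seed protocol exists for).
- Exact tests are enumerative and sized for small n (MW ≲ 10 per group,
  Wilcoxon ≤ 20 pairs).
- Stage segmentation of simulated runs uses first boundary crossings;
  trajectories that regress across a stage boundary (strong corrections)
  keep the first-crossing time.
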