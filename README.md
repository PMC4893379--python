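# cathkin

Objective assessment of endovascular manipulation skill from catheter-tip
kinematics in fluoroscopy-style video, built around a phantom study of
transcatheter aortic valve implantation (TAVI): twelve surgeons (six
experts, six novices) cannulate a type-I aortic-arch phantom twice each,
once with conventional catheters and once with a robotic platform, and the
question is whether kinematic features of the tracked tip alone separate
experience levels and equipment types.

The package covers the whole chain, plus a synthetic generator that stands
in for recordings:

- **screen normalization** — a four-corner homography rectifies
  trajectories recorded off a skewed fluoroscopy monitor into the
  canonical 720x576 frame;
- **segmentation** — threshold binarization of the phantom image
  (strictly `intensity > threshold`, Otsu when `"auto"`) and the exact
  Euclidean distance of every lumen pixel to the nearest wall pixel;
- **tip tracking** — brute-force zero-normalized cross-correlation
  template matching with sub-pixel refinement, per-frame template refresh
  and low-confidence flagging for manual re-seeding;
- **kinematics** — per-stage procedure time `T_p`, path length `PL`,
  average speed `v_d = PL / T_p`, mean acceleration magnitude
  `a_d = mean sqrt(a_x^2 + a_y^2)`, mean tip/shape distance to the vessel
  wall, and the dimensionless jerk

  ```
  j_d = ( 0.5 * ∫ x'''(t)^2 + y'''(t)^2 dt ) * T_p^5 / PL^2
  ```

  a duration- and amplitude-free smoothness score: a single minimum-jerk
  movement gives exactly 360, hesitant or tremulous motion scores far
  higher;
- **statistics** — exact (full-enumeration) Mann-Whitney U and Wilcoxon
  signed-rank tests with mid-rank tie handling, sized for n = 6 per group,
  and the median summary table;
- **clustering** — 2-cluster k-means (Lloyd, 100 restarts) and a
  diagonal-covariance Gaussian mixture fitted by EM, scored against the
  known labels by permutation-matched accuracy;
- **synthetic data** — an arch phantom renderer and a trajectory simulator
  (minimum-jerk sub-movement chains with skill-dependent pauses, tremor,
  lateral drift and overshoot corrections; equipment enters as a speed
  scale) that generates whole cohorts with the statistical structure the
  analysis assumes.

## Worked example

```python
import cathkin as ck
from cathkin.segmentation import binarize, distance_image
from cathkin.stats import summarize_cohort
from cathkin.clustering import run_discrimination

geometry = ck.default_arch_geometry()
phantom, _ = ck.make_phantom(geometry)
dist = distance_image(binarize(phantom, "auto"))

cohort = ck.simulate_cohort(seed=1, geometry=geometry)   # 6 experts + 6 novices
features = ck.features_table(cohort, dist)               # 48 stage rows
print(summarize_cohort(features).head(2))
res = run_discrimination(features, "experience", algorithm="em", seed=1)
print(f"experience clustering: {res.n_correct}/{res.n}")
```

prints (seed 1):

```
 feature  stage  median_novice_conventional  median_expert_conventional  p_mw_conventional ...
     T_p      1                   70.884931                    9.072056           0.002165
     T_p      2                   11.298301                    1.179542           0.002165
experience clustering: 11/12
```

Novices take ~8x longer through the arch; the exact Mann-Whitney p of
0.0022 is the strongest value attainable at 6 vs 6 short of the absolute
floor, and unsupervised EM recovers the experience groups at 11/12 —
inside the 83–91% band such cohorts are expected to yield. The same
trajectories give expert dimensionless jerk orders of magnitude below the
novices' (pauses enter through the `T_p^5` normalization).

Longer narrative walk-throughs live in `examples/` (one script per
capability); a thin CLI (`cathkin simulate-phantom`, `track`, `features`,
`stats`, `cluster`, `run`, ...) wraps the same functions for shell use.

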