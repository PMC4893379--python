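"""Simulate expert vs novice tip trajectories and compare their kinematics.

A run is a chain of minimum-jerk sub-movements along the lumen centerline
with pauses, tremor and overshoot corrections. The dimensionless jerk
j_d = (0.5 * int x'''^2 + y'''^2 dt) * T_p^5 / PL^2 is amplitude- and
duration-free: a single perfect minimum-jerk movement scores exactly 360,
and every hesitation or correction drives it up.
"""

import cathkin as ck
from cathkin.kinematics import KinematicsConfig, dimensionless_jerk

geometry = ck.default_arch_geometry()
cfg = KinematicsConfig()

for group in ("expert", "novice"):
    profile = ck.DEFAULT_PROFILES[(group, "conventional")]
    traj, stages = ck.simulate_trajectory(geometry, profile, seed=1)
    fv1, fv2 = ck.extract_features(traj, stages, config=cfg)
    print(f"{group:7s} stage 1: T_p {fv1.T_p:7.1f} s  v_d {fv1.v_d:6.1f} px/s  "
          f"a_d {fv1.a_d:6.1f} px/s^2  j_d {fv1.j_d:.3g}")

# the smoothness floor: one isolated minimum-jerk movement
single = ck.MotionProfile(1, 2.0, 0.0, 0.0, 0.0, 0.0, 1.0)
straight = ck.straight_tube_geometry()
traj, _ = ck.simulate_trajectory(straight, single, dt=1e-3, seed=0)
jd = dimensionless_jerk(traj, (traj.t[0], traj.t[-1]), KinematicsConfig(dt=1e-3))
print(f"single minimum-jerk movement: j_d = {jd:.1f} (analytic value 360)")
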