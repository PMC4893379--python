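"""Phantom rendering, trajectory simulation and cohort structure."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import cathkin as ck
from cathkin.kinematics import KinematicsConfig, dimensionless_jerk
from cathkin.synthdata import DEFAULT_PROFILES


class TestMakePhantom:
    def test_straight_tube_mask_is_band_around_centerline(self):
        g = ck.straight_tube_geometry(length=200.0, radius=10.0, start=(30.0, 50.0))
        _, mask = ck.make_phantom(g, width=280, height=100)
        # away from the end caps the tube is a horizontal band of half-width 10
        for x in (60, 130, 200):
            col = mask[:, x]
            rows = np.flatnonzero(col)
            assert rows.min() == 40 and rows.max() == 60
        assert not mask[:, 10].any() and not mask[:, 260].any()

    def test_separable_intensities_recover_mask_by_threshold(self):
        g = ck.straight_tube_geometry(length=150.0, radius=8.0, start=(20.0, 40.0))
        img, mask = ck.make_phantom(g, width=200, height=80, fg_intensity=200, bg_intensity=50)
        assert np.array_equal(img > 125, mask)

    def test_arch_mask_matches_bruteforce_point_in_tube_oracle(self, arch_geometry, arch_phantom):
        # oracle: per-pixel minimum of ||p - c_i|| - r_i over the same dense
        # centerline sampling, computed by an independent chunked scan
        _, mask = arch_phantom
        _, pts, radii = arch_geometry.resample(0.25)
        h, w = mask.shape
        oracle = np.zeros((h, w), dtype=bool)
        xs = np.arange(w, dtype=float)
        for y0 in range(0, h, 16):
            rows = np.arange(y0, min(y0 + 16, h))
            grid = np.array([[x, y] for y in rows for x in xs])
            d = cdist(grid, pts)
            inside = (d <= radii[None, :]).any(axis=1)
            oracle[rows[0] : rows[-1] + 1] = inside.reshape(len(rows), w)
        assert int(mask.sum()) == int(oracle.sum())
        assert np.array_equal(mask, oracle)

    def test_geometry_exceeding_frame_reports_offending_point(self):
        g = ck.straight_tube_geometry(length=200.0, radius=10.0, start=(30.0, 50.0))
        with pytest.raises(ValueError, match="centerline point"):
            ck.make_phantom(g, width=100, height=100)

    def test_fg_must_exceed_bg(self):
        g = ck.straight_tube_geometry()
        with pytest.raises(ValueError):
            ck.make_phantom(g, fg_intensity=50, bg_intensity=200)


class TestVesselGeometry:
    def test_default_arch_valve_is_global_minimum_radius(self, arch_geometry):
        assert arch_geometry.radius_at(arch_geometry.valve_arclength) == pytest.approx(
            arch_geometry.radius_profile.min()
        )

    def test_stage_spans_are_consecutive(self, arch_geometry):
        assert arch_geometry.stage1_span[1] == arch_geometry.stage2_span[0]
        assert arch_geometry.stage2_span[1] == pytest.approx(arch_geometry.length)

    def test_non_minimal_valve_radius_rejected(self):
        line = np.column_stack([np.linspace(0, 100, 51), np.full(51, 20.0)])
        radii = np.linspace(5.0, 10.0, 51)  # minimum at s=0, not at the "valve"
        with pytest.raises(ValueError, match="global minimum"):
            ck.VesselGeometry(line, radii, 80.0, (0.0, 60.0), (60.0, 100.0))


class TestSimulateTrajectory:
    def test_same_seed_identical_output(self, arch_geometry):
        prof = DEFAULT_PROFILES[("novice", "conventional")]
        t1, s1 = ck.simulate_trajectory(arch_geometry, prof, seed=42)
        t2, s2 = ck.simulate_trajectory(arch_geometry, prof, seed=42)
        assert np.array_equal(t1.t, t2.t) and np.array_equal(t1.xy, t2.xy)
        assert s1.stage1 == s2.stage1 and s1.stage2 == s2.stage2

    def test_pure_minimum_jerk_movement_has_dimensionless_jerk_360(self):
        g = ck.straight_tube_geometry(length=300.0, radius=12.0, start=(40.0, 60.0))
        prof = ck.MotionProfile(1, 2.0, 0.0, 0.0, 0.0, 0.0, 1.0)
        traj, _ = ck.simulate_trajectory(g, prof, dt=1e-3, seed=0)
        jd = dimensionless_jerk(traj, (traj.t[0], traj.t[-1]), KinematicsConfig(dt=1e-3))
        assert jd == pytest.approx(360.0, rel=0.01)

    def test_minimum_jerk_progress_is_monotone_without_corrections(self, arch_geometry):
        prof = ck.MotionProfile(5, 1.5, 0.2, 0.0, 0.0, 0.0, 1.0)
        traj, _ = ck.simulate_trajectory(arch_geometry, prof, seed=3)
        # recover arc progress from positions: project onto the centerline
        s, pts, _ = arch_geometry.resample(0.5)
        d = cdist(traj.xy, pts)
        prog = s[d.argmin(axis=1)]
        assert np.all(np.diff(prog) >= -0.75)  # monotone up to projection quantization

    def test_noise_free_trajectory_stays_inside_lumen(self, arch_geometry, arch_phantom):
        _, mask = arch_phantom
        prof = dataclasses.replace(DEFAULT_PROFILES[("novice", "conventional")], tremor_sd=0.0)
        traj, _ = ck.simulate_trajectory(arch_geometry, prof, seed=5)
        cols = np.clip(np.rint(traj.x).astype(int), 0, mask.shape[1] - 1)
        rows = np.clip(np.rint(traj.y).astype(int), 0, mask.shape[0] - 1)
        assert mask[rows, cols].all()

    def test_stage_boundaries_are_within_span_and_consecutive(self, arch_geometry):
        prof = DEFAULT_PROFILES[("expert", "conventional")]
        traj, st = ck.simulate_trajectory(arch_geometry, prof, seed=8)
        assert st.stage1[1] == st.stage2[0]
        assert traj.t[0] <= st.stage1[0] < st.stage2[1] <= traj.t[-1]

    def test_expert_faster_and_smoother_than_novice(self, arch_geometry):
        cfg = KinematicsConfig()
        wins_tp = wins_jd = 0
        n = 100
        for s in range(n):
            te, _ = ck.simulate_trajectory(
                arch_geometry, DEFAULT_PROFILES[("expert", "conventional")], seed=s
            )
            tn, _ = ck.simulate_trajectory(
                arch_geometry, DEFAULT_PROFILES[("novice", "conventional")], seed=10_000 + s
            )
            wins_tp += te.duration < tn.duration
            iv_e, iv_n = (te.t[0], te.t[-1]), (tn.t[0], tn.t[-1])
            wins_jd += dimensionless_jerk(te, iv_e, cfg) < dimensionless_jerk(tn, iv_n, cfg)
        assert wins_tp >= 95
        assert wins_jd >= 95

    def test_bad_dt_rejected(self, arch_geometry):
        with pytest.raises(ValueError):
            ck.simulate_trajectory(arch_geometry, DEFAULT_PROFILES[("expert", "conventional")], dt=0)


class TestShapeAnnotations:
    def test_every_annotated_frame_has_exactly_n_points(self, arch_geometry):
        prof = DEFAULT_PROFILES[("expert", "conventional")]
        traj, _ = ck.simulate_trajectory(arch_geometry, prof, seed=2)
        shapes = ck.make_shape_annotations(traj, arch_geometry, n_points=15, frame_stride=20)
        assert shapes and all(s.points.shape == (15, 2) for s in shapes)

    def test_tip_at_insertion_gives_degenerate_polyline(self, straight_geometry):
        start = straight_geometry.point_at(0.0)
        traj = ck.Trajectory([0.0, 1.0], [start, start + [0.5, 0.0]])
        shapes = ck.make_shape_annotations(traj, straight_geometry, n_points=5, frames=[0])
        assert np.allclose(shapes[0].points, start, atol=0.5)

    def test_uniform_resampling_of_straight_segment(self):
        g = ck.straight_tube_geometry(length=200.0, radius=10.0, start=(50.0, 100.0))
        traj = ck.Trajectory([0.0, 1.0], [[50.0, 100.0], [150.0, 100.0]])
        shapes = ck.make_shape_annotations(traj, g, n_points=11, frames=[1])
        assert np.allclose(shapes[0].points[:, 0], 50.0 + np.arange(11) * 10.0, atol=0.5)
        assert np.allclose(shapes[0].points[:, 1], 100.0)

    def test_frame_beyond_trajectory_rejected(self, straight_geometry):
        traj = ck.Trajectory([0.0, 1.0], [[50.0, 60.0], [60.0, 60.0]])
        with pytest.raises(IndexError):
            ck.make_shape_annotations(traj, straight_geometry, frames=[5])


class TestRenderVideo:
    def test_stationary_trajectory_gives_identical_frames(self, straight_geometry):
        phantom, _ = ck.make_phantom(straight_geometry, width=380, height=120)
        traj = ck.Trajectory([0.0, 0.04, 0.08], [[100.0, 60.0]] * 3)
        vid = ck.render_video(phantom, traj)
        assert vid.shape[0] == 3
        assert np.array_equal(vid[0], vid[1]) and np.array_equal(vid[1], vid[2])

    def test_frame_differs_from_phantom_only_near_tip(self, straight_geometry):
        phantom, _ = ck.make_phantom(straight_geometry, width=380, height=120)
        traj = ck.Trajectory([0.0, 0.04], [[100.0, 60.0], [200.0, 58.0]])
        vid = ck.render_video(phantom, traj, tip_radius=4.0)
        diff = vid[1].astype(int) != phantom.astype(int)
        ys, xs = np.nonzero(diff)
        assert np.all(np.hypot(xs - 200.0, ys - 58.0) <= 5.0 + np.sqrt(0.5))

    def test_out_of_frame_trajectory_rejected(self, straight_geometry):
        phantom, _ = ck.make_phantom(straight_geometry, width=380, height=120)
        traj = ck.Trajectory([0.0, 0.04], [[2.0, 60.0], [100.0, 60.0]])
        with pytest.raises(ValueError):
            ck.render_video(phantom, traj)


class TestSimulateCohort:
    def test_twelve_subjects_two_equipment_conditions(self, default_cohort):
        assert len(default_cohort) == 24
        seen = {(r.subject_id, r.equipment) for r in default_cohort.runs}
        assert len(seen) == 24
        groups = {r.subject_id: r.group for r in default_cohort.runs}
        assert sum(g == "expert" for g in groups.values()) == 6
        assert sum(g == "novice" for g in groups.values()) == 6

    def test_seed_determinism(self, arch_geometry):
        c1 = ck.simulate_cohort(n_expert=2, n_novice=2, seed=7, geometry=arch_geometry)
        c2 = ck.simulate_cohort(n_expert=2, n_novice=2, seed=7, geometry=arch_geometry)
        for r1, r2 in zip(c1.runs, c2.runs):
            assert np.array_equal(r1.trajectory.xy, r2.trajectory.xy)

    def test_robotic_slower_than_conventional_within_group(self, arch_geometry):
        ratios = {"expert": [], "novice": []}
        for s in range(50):
            c = ck.simulate_cohort(n_expert=1, n_novice=1, seed=s, geometry=arch_geometry)
            durs = {(r.group, r.equipment): r.trajectory.duration for r in c.runs}
            for g in ratios:
                ratios[g].append(durs[(g, "robotic")] / durs[(g, "conventional")])
        assert np.median(ratios["expert"]) > 1.0
        assert np.median(ratios["novice"]) > 1.0
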