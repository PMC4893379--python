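"""Kinematic feature pipeline: resampling, smoothing, derivatives, jerk."""

import numpy as np
import pytest

import cathkin as ck
from cathkin.kinematics import (
    KinematicsConfig,
    average_acceleration,
    average_speed,
    dimensionless_jerk,
    path_length,
    procedure_time,
    resample_uniform,
    shape_wall_distance,
    smooth,
    tip_wall_distance,
)
from cathkin.segmentation import binarize, distance_image

from conftest import minimum_jerk_trajectory


def line_trajectory(speed=10.0, duration=10.0, dt=0.1, origin=(50.0, 80.0)):
    t = np.arange(0.0, duration + 1e-12, dt)
    xy = np.column_stack([origin[0] + speed * t, np.full_like(t, origin[1])])
    return ck.Trajectory(t, xy)


class TestResampleSmooth:
    def test_linear_trajectory_resamples_exactly(self):
        t = np.array([0.0, 0.3, 1.1, 2.0])
        xy = np.column_stack([2.0 + 3.0 * t, 1.0 - 0.5 * t])
        u = resample_uniform(ck.Trajectory(t, xy), 0.25)
        assert u.t[0] == 0.0 and u.t[-1] == 2.0
        assert np.allclose(u.x, 2.0 + 3.0 * u.t)
        assert np.allclose(u.y, 1.0 - 0.5 * u.t)

    def test_sinusoid_interpolation_error_bound(self):
        f, amp, dt = 2.0, 5.0, 0.01
        t = np.arange(0.0, 1.0 + 1e-12, dt)
        dense = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        traj = ck.Trajectory(t, np.column_stack([amp * np.sin(2 * np.pi * f * t), t]))
        u = resample_uniform(ck.Trajectory(dense, np.column_stack(
            [amp * np.sin(2 * np.pi * f * dense), dense])), dt)
        err = np.max(np.abs(u.x - amp * np.sin(2 * np.pi * f * u.t)))
        assert err <= (2 * np.pi * f * 1e-4) ** 2 / 8 * amp + 1e-12
        del traj

    def test_dt_larger_than_span_rejected(self):
        traj = line_trajectory(duration=1.0)
        with pytest.raises(ValueError):
            resample_uniform(traj, 5.0)

    def test_smooth_reproduces_cubic(self):
        t = np.arange(0.0, 2.0, 0.02)
        xy = np.column_stack([1 + t - 2 * t**2 + 0.5 * t**3, 3 - t**3])
        out = smooth(ck.Trajectory(t, xy), 9, 3)
        assert np.allclose(out.xy, xy, atol=1e-9)

    def test_smooth_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 20.0, 0.04)
        noise = rng.normal(0, 2.0, (t.size, 2))
        out = smooth(ck.Trajectory(t, 100.0 + noise), 9, 3)
        assert np.var(out.xy - 100.0) < np.var(noise)

    def test_smooth_window_validation(self):
        traj = line_trajectory()
        with pytest.raises(ValueError):
            smooth(traj, 8, 3)  # even window
        with pytest.raises(ValueError):
            smooth(traj, 1001, 3)  # window beyond samples


class TestPathSpeed:
    def test_straight_movement(self):
        traj = line_trajectory(speed=10.0, duration=10.0)
        assert procedure_time((0.0, 10.0)) == 10.0
        assert path_length(traj, (0.0, 10.0)) == pytest.approx(100.0)
        assert average_speed(traj, (0.0, 10.0)) == pytest.approx(10.0)

    def test_stationary_trajectory_zero_speed(self):
        t = np.arange(0.0, 10.0 + 1e-12, 0.1)
        traj = ck.Trajectory(t, np.tile([5.0, 5.0], (t.size, 1)))
        assert path_length(traj, (0.0, 10.0)) == 0.0
        assert average_speed(traj, (0.0, 10.0)) == 0.0

    def test_back_and_forth_counts_path_not_displacement(self):
        t = np.arange(0.0, 10.0 + 1e-12, 0.1)
        x = 50.0 + np.where(t <= 5.0, 10.0 * t, 10.0 * (10.0 - t))
        traj = ck.Trajectory(t, np.column_stack([x, np.full_like(t, 7.0)]))
        assert path_length(traj, (0.0, 10.0)) == pytest.approx(100.0)
        assert average_speed(traj, (0.0, 10.0)) == pytest.approx(10.0)

    def test_reversal_preserves_path_length_and_time(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0.0, 4.0, 120)
        xy = np.cumsum(rng.normal(0, 1, (120, 2)), axis=0)
        fwd = ck.Trajectory(t, xy)
        rev = ck.Trajectory(t, xy[::-1])
        iv = (0.0, 4.0)
        assert path_length(fwd, iv) == pytest.approx(path_length(rev, iv))
        assert procedure_time(iv) == procedure_time(iv)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            procedure_time((3.0, 3.0))


class TestAcceleration:
    def test_three_four_five(self):
        t = np.arange(0.0, 2.0 + 1e-12, 0.01)
        xy = np.column_stack([0.5 * 3.0 * t**2, 0.5 * 4.0 * t**2])
        a = average_acceleration(ck.Trajectory(t, xy), (0.0, 2.0), KinematicsConfig(dt=0.01))
        assert a == pytest.approx(5.0, rel=1e-6)

    def test_constant_velocity_zero_acceleration(self):
        a = average_acceleration(line_trajectory(), (0.0, 10.0), KinematicsConfig(dt=0.1))
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        traj = line_trajectory(duration=1.0, dt=0.5)
        with pytest.raises(ValueError):
            average_acceleration(traj, (0.0, 1.0), KinematicsConfig(dt=0.5))


class TestDimensionlessJerk:
    def test_minimum_jerk_movement_gives_360(self):
        for amp, dur in [(2.5, 1.3), (40.0, 0.7), (300.0, 3.0)]:
            traj = minimum_jerk_trajectory(amplitude=amp, duration=dur, dt=1e-3)
            jd = dimensionless_jerk(traj, (0.0, traj.t[-1]), KinematicsConfig(dt=1e-3))
            assert jd == pytest.approx(360.0, rel=0.01)

    def test_constant_velocity_gives_zero(self):
        jd = dimensionless_jerk(line_trajectory(), (0.0, 10.0), KinematicsConfig(dt=0.1))
        assert jd == pytest.approx(0.0, abs=1e-9)

    def test_scale_and_time_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = np.linspace(0.0, 3.0, 151)
            xy = np.cumsum(rng.normal(0, 1, (151, 2)), axis=0)
            traj = ck.Trajectory(t, xy)
            j1 = dimensionless_jerk(traj, (0.2, 2.8), KinematicsConfig(dt=0.02))
            c, k = rng.uniform(0.5, 5.0, 2)
            scaled = ck.Trajectory(t * k, xy * c)
            j2 = dimensionless_jerk(scaled, (0.2 * k, 2.8 * k), KinematicsConfig(dt=0.02 * k))
            assert abs(j2 - j1) / j1 < 1e-6

    def test_error_decreases_with_dt_over_a_decade(self):
        errs = []
        for dt in (0.01, 0.005, 0.002, 0.001):
            traj = minimum_jerk_trajectory(amplitude=2.5, duration=1.3, dt=dt)
            jd = dimensionless_jerk(traj, (0.0, traj.t[-1]), KinematicsConfig(dt=dt))
            errs.append(abs(jd - 360.0))
        assert errs == sorted(errs, reverse=True)

    def test_zero_path_length_rejected(self):
        t = np.arange(0.0, 2.0, 0.04)
        traj = ck.Trajectory(t, np.tile([5.0, 5.0], (t.size, 1)))
        with pytest.raises(ValueError):
            dimensionless_jerk(traj, (0.0, 1.96), KinematicsConfig(dt=0.04))


@pytest.fixture(scope="module")
def tube_distance():
    g = ck.straight_tube_geometry(length=300.0, radius=10.0, start=(40.0, 60.0))
    img, _ = ck.make_phantom(g, width=380, height=120)
    return distance_image(binarize(img, 125))


class TestWallDistances:
    def test_centerline_trajectory_distance_matches_radius(self, tube_distance):
        t = np.arange(0.0, 8.0 + 1e-12, 0.04)
        x = 60.0 + (250.0 / 8.0) * t
        traj = ck.Trajectory(t, np.column_stack([x, np.full_like(t, 60.0)]))
        d = tip_wall_distance(traj, (0.0, 8.0), tube_distance)
        assert d == pytest.approx(10.0, abs=1.0)

    def test_single_point_returns_its_own_value(self, tube_distance):
        traj = ck.Trajectory([0.0, 1.0], [[100.0, 60.0], [100.0, 60.0]])
        d = tip_wall_distance(traj, (0.0, 0.5), tube_distance)
        from cathkin.segmentation import lookup_distances

        assert d == pytest.approx(lookup_distances(tube_distance, [[100.0, 60.0]])[0])

    def test_wall_hugging_shape_closer_than_centerline_tip(self, tube_distance):
        t = np.arange(0.0, 4.0 + 1e-12, 0.04)
        center = ck.Trajectory(t, np.column_stack([60.0 + 40.0 * t, np.full_like(t, 60.0)]))
        hug = ck.CatheterShape(0, np.column_stack([np.linspace(60, 220, 20), np.full(20, 52.0)]))
        d_tip = tip_wall_distance(center, (0.0, 4.0), tube_distance)
        d_shape = shape_wall_distance([hug], tube_distance)
        assert d_shape < d_tip


class TestExtractFeatures:
    def test_internal_consistency_and_finiteness(self, arch_geometry, arch_distance):
        prof = ck.DEFAULT_PROFILES[("expert", "conventional")]
        traj, stages = ck.simulate_trajectory(arch_geometry, prof, seed=9)
        shapes = ck.make_shape_annotations(traj, arch_geometry, frame_stride=20)
        fvs = ck.extract_features(traj, stages, arch_distance, shapes)
        assert [fv.stage for fv in fvs] == [1, 2]
        for fv in fvs:
            vals = [fv.T_p, fv.PL, fv.v_d, fv.a_d, fv.j_d, fv.d_tip, fv.d_shape]
            assert all(np.isfinite(v) and v >= 0 for v in vals)
            assert fv.v_d * fv.T_p == pytest.approx(fv.PL, rel=1e-9)

    def test_cohort_table_has_48_stage_rows(self, default_features):
        assert len(default_features) == 48
        assert set(default_features["stage"]) == {1, 2}
        assert default_features.groupby(["equipment", "stage"]).size().eq(12).all()

    def test_expert_median_jerk_below_novice_in_stage1(self, default_features):
        s1 = default_features.query("stage == 1 and equipment == 'conventional'")
        med = s1.groupby("group")["j_d"].median()
        assert med["expert"] < med["novice"]
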