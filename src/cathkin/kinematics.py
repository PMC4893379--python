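"""Catheter-tip kinematic features.

Per-stage metrics computed from a tracked 2D tip trajectory: procedure time
``T_p``, path length ``PL``, average speed ``v_d = PL / T_p``, average
acceleration magnitude ``a_d`` (mean of ``sqrt(a_x^2 + a_y^2)``), the
dimensionless jerk

    j_d = (0.5 * int (x'''^2 + y'''^2) dt) * T_p^5 / PL^2,

which is invariant to movement duration and amplitude (lower = smoother),
and the mean distance of the tip (and of the annotated catheter shape) to
the nearest vessel-wall pixel.

Raw tracks are pixel-quantized, so derivative-based features are computed on
a uniformly resampled and Savitzky-Golay-smoothed copy of the trajectory;
the differentiation pipeline is configurable through :class:`KinematicsConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Trajectory",
    "StageSegmentation",
    "CatheterShape",
    "KinematicFeatureVector",
    "KinematicsConfig",
    "resample_uniform",
    "smooth",
    "procedure_time",
    "path_length",
    "average_speed",
    "average_acceleration",
    "dimensionless_jerk",
    "tip_wall_distance",
    "shape_wall_distance",
    "extract_features",
    "features_table",
]


@dataclass
class Trajectory:
    """Time-stamped 2D tip positions in canonical pixel coordinates.

    ``t`` in seconds, strictly increasing; ``xy`` an (n, 2) array of
    (x, y) = (column, row) pixel-center coordinates, origin top-left.
    """

    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("trajectory needs t of shape (n,) and xy of shape (n, 2)")
        if self.t.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValueError("trajectory contains non-finite values")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class StageSegmentation:
    """Temporal limits of the two TAVI stages (seconds).

    Stage 1 is arch navigation (descending aorta to ~2 cm proximal to the
    valve); stage 2 is valve crossing into the ventricle. Stage 1 must end
    no later than stage 2 starts.
    """

    stage1: tuple[float, float]
    stage2: tuple[float, float]

    def __post_init__(self) -> None:
        self.stage1 = (float(self.stage1[0]), float(self.stage1[1]))
        self.stage2 = (float(self.stage2[0]), float(self.stage2[1]))
        for name, (a, b) in (("stage1", self.stage1), ("stage2", self.stage2)):
            if not a < b:
                raise ValueError(f"{name} interval must have t_start < t_end, got {(a, b)}")
        if self.stage1[1] > self.stage2[0] + 1e-12:
            raise ValueError("stage1 must end no later than stage2 starts")

    def interval(self, stage: int) -> tuple[float, float]:
        if stage == 1:
            return self.stage1
        if stage == 2:
            return self.stage2
        raise ValueError(f"unknown stage {stage!r}; expected 1 or 2")


@dataclass
class CatheterShape:
    """Polyline annotation of the inserted catheter in one frame.

    All shapes of one recording carry the same number of points (spline
    resampling guarantees this at annotation time).
    """

    frame: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("shape points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("shape polyline needs at least 2 points")


@dataclass
class KinematicFeatureVector:
    """Per-stage feature set for one execution."""

    T_p: float
    PL: float
    v_d: float
    a_d: float
    j_d: float
    d_tip: float | None
    d_shape: float | None
    stage: int
    equipment: str | None = None

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "T_p": self.T_p,
            "PL": self.PL,
            "v_d": self.v_d,
            "a_d": self.a_d,
            "j_d": self.j_d,
            "d_tip": self.d_tip,
            "d_shape": self.d_shape,
        }


@dataclass
class KinematicsConfig:
    """Differentiation pipeline parameters.

    dt: uniform resampling step (s); default 1/25 s (PAL video rate).
    smoothing_window / smoothing_order: Savitzky-Golay local polynomial
    smoothing applied before finite differencing; window must be odd and
    larger than the order. Set ``smoothing_window`` to 0 to disable.
    """

    dt: float = 1.0 / 25.0
    smoothing_window: int = 9
    smoothing_order: int = 3


def resample_uniform(traj: Trajectory, dt: float) -> Trajectory:
    """Linearly interpolate onto a uniform grid spanning the original range.

    Both endpoints are preserved exactly: the actual step is the closest
    value to ``dt`` that divides the time span into a whole number of steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = traj.duration
    if dt > span:
        raise ValueError(f"dt={dt} exceeds trajectory span {span}")
    n = max(2, int(round(span / dt)) + 1)
    tg = np.linspace(traj.t[0], traj.t[-1], n)
    xi = np.interp(tg, traj.t, traj.x)
    yi = np.interp(tg, traj.t, traj.y)
    return Trajectory(tg, np.column_stack([xi, yi]))


def smooth(traj: Trajectory, window: int, order: int) -> Trajectory:
    """Savitzky-Golay (local least-squares polynomial) smoothing per axis.

    A polynomial of degree <= ``order`` passes through unchanged.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if window > len(traj):
        raise ValueError(f"window {window} exceeds sample count {len(traj)}")
    sm = np.column_stack(
        [savgol_filter(traj.x, window, order), savgol_filter(traj.y, window, order)]
    )
    return Trajectory(traj.t.copy(), sm)


def _check_interval(traj: Trajectory, interval: Sequence[float]) -> tuple[float, float]:
    a, b = float(interval[0]), float(interval[1])
    if not a < b:
        raise ValueError(f"empty or inverted interval {(a, b)}")
    if a < traj.t[0] - 1e-9 or b > traj.t[-1] + 1e-9:
        raise ValueError(f"interval {(a, b)} outside trajectory span")
    return a, b


def _slice_indices(t: np.ndarray, a: float, b: float) -> tuple[int, int]:
    # the sample nearest each boundary is the cut
    i0 = int(np.argmin(np.abs(t - a)))
    i1 = int(np.argmin(np.abs(t - b)))
    if i1 <= i0:
        raise ValueError("interval contains fewer than 2 samples")
    return i0, i1


def procedure_time(interval: Sequence[float]) -> float:
    """T_p = t_end - t_start (s)."""
    a, b = float(interval[0]), float(interval[1])
    if not a < b:
        raise ValueError(f"empty or inverted interval {(a, b)}")
    return b - a


def path_length(traj: Trajectory, interval: Sequence[float]) -> float:
    """PL: summed Euclidean step lengths of the samples inside the interval."""
    a, b = _check_interval(traj, interval)
    i0, i1 = _slice_indices(traj.t, a, b)
    steps = np.diff(traj.xy[i0 : i1 + 1], axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def average_speed(traj: Trajectory, interval: Sequence[float]) -> float:
    """v_d = PL / T_p (px/s); pauses lower v_d by construction."""
    return path_length(traj, interval) / procedure_time(interval)


def _prepared(traj: Trajectory, config: KinematicsConfig) -> Trajectory:
    u = resample_uniform(traj, config.dt)
    if config.smoothing_window:
        w = min(config.smoothing_window, len(u) - (1 - len(u) % 2))
        if w > config.smoothing_order and w % 2 == 1:
            u = smooth(u, w, config.smoothing_order)
    return u


def _derivative(v: np.ndarray, dt: float, order: int, config: KinematicsConfig) -> np.ndarray:
    """n-th time derivative of a uniformly sampled signal.

    With smoothing enabled this uses the Savitzky-Golay local-polynomial
    differentiator (a least-squares generalization of central differences
    whose boundary stencils come from the same window fit, avoiding the
    large one-sided errors of naive repeated differencing); otherwise
    repeated second-order central differences.
    """
    if config.smoothing_window:
        w = min(config.smoothing_window, len(v) - (1 - len(v) % 2))
        poly = max(config.smoothing_order, order)
        if w > poly and w % 2 == 1:
            return savgol_filter(v, w, poly, deriv=order, delta=dt, mode="interp")
    for _ in range(order):
        v = np.gradient(v, dt, edge_order=2)
    return v


def average_acceleration(
    traj: Trajectory,
    interval: Sequence[float],
    config: KinematicsConfig | None = None,
) -> float:
    """a_d: mean of sqrt(a_x^2 + a_y^2) over the interval (px/s^2).

    Central second differences on the smoothed, uniformly resampled track.
    """
    config = config or KinematicsConfig()
    a, b = _check_interval(traj, interval)
    u = _prepared(traj, config)
    dt = u.t[1] - u.t[0]
    i0, i1 = _slice_indices(u.t, a, b)
    if i1 - i0 + 1 < 5:
        raise ValueError("need at least 5 uniform samples in the interval")
    ax = _derivative(u.x, dt, 2, config)
    ay = _derivative(u.y, dt, 2, config)
    mag = np.hypot(ax, ay)[i0 : i1 + 1]
    return float(mag.mean())


def dimensionless_jerk(
    traj: Trajectory,
    interval: Sequence[float],
    config: KinematicsConfig | None = None,
) -> float:
    """j_d = (0.5 * int (x'''^2 + y'''^2) dt) * T_p^5 / PL^2 over the interval.

    Third derivatives by repeated central differences on the smoothed uniform
    trajectory; the integral by the trapezoidal rule. T_p and PL are those of
    the same interval. A single minimum-jerk movement gives j_d = 360.
    """
    config = config or KinematicsConfig()
    a, b = _check_interval(traj, interval)
    u = _prepared(traj, config)
    dt = u.t[1] - u.t[0]
    i0, i1 = _slice_indices(u.t, a, b)
    if i1 - i0 + 1 < 7:
        raise ValueError("need at least 7 uniform samples in the interval")
    seg = u.xy[i0 : i1 + 1]
    steps = np.diff(seg, axis=0)
    pl = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    if pl < 1e-9:  # tolerate smoothing round-off on exactly constant input
        raise ValueError("path length is zero; dimensionless jerk undefined")
    tp = b - a

    jx = _derivative(u.x, dt, 3, config)
    jy = _derivative(u.y, dt, 3, config)
    integrand = (jx**2 + jy**2)[i0 : i1 + 1]
    integral = float(np.trapezoid(integrand, dx=dt))
    return 0.5 * integral * tp**5 / pl**2


def tip_wall_distance(traj: Trajectory, interval: Sequence[float], dist) -> float:
    """Mean distance of the tip samples in the interval to the vessel wall (px)."""
    from .segmentation import lookup_distances

    a, b = _check_interval(traj, interval)
    sel = (traj.t >= a - 1e-9) & (traj.t <= b + 1e-9)
    if not sel.any():
        raise ValueError("no trajectory samples inside the interval")
    return float(np.mean(lookup_distances(dist, traj.xy[sel])))


def shape_wall_distance(shapes: Sequence[CatheterShape], dist) -> float:
    """Mean wall distance over all points of all annotated catheter shapes (px)."""
    from .segmentation import lookup_distances

    if not shapes:
        raise ValueError("no catheter shapes supplied")
    pts = np.vstack([s.points for s in shapes])
    return float(np.mean(lookup_distances(dist, pts)))


def extract_features(
    traj: Trajectory,
    stages: StageSegmentation,
    dist=None,
    shapes: Sequence[CatheterShape] | None = None,
    config: KinematicsConfig | None = None,
    equipment: str | None = None,
) -> list[KinematicFeatureVector]:
    """Assemble the full per-stage feature set (stages 1 and 2).

    ``dist`` is a :class:`~cathkin.segmentation.DistanceImage`; when omitted
    the wall-distance features are None. Shapes are assigned to a stage by
    the trajectory timestamp of their frame.
    """
    config = config or KinematicsConfig()
    out = []
    for stage in (1, 2):
        iv = stages.interval(stage)
        tp = procedure_time(iv)
        pl = path_length(traj, iv)
        fv = KinematicFeatureVector(
            T_p=tp,
            PL=pl,
            v_d=pl / tp,
            a_d=average_acceleration(traj, iv, config),
            j_d=dimensionless_jerk(traj, iv, config),
            d_tip=None if dist is None else tip_wall_distance(traj, iv, dist),
            d_shape=None,
            stage=stage,
            equipment=equipment,
        )
        if dist is not None and shapes:
            in_stage = [
                s
                for s in shapes
                if 0 <= s.frame < len(traj) and iv[0] - 1e-9 <= traj.t[s.frame] <= iv[1] + 1e-9
            ]
            if in_stage:
                fv.d_shape = shape_wall_distance(in_stage, dist)
        out.append(fv)
    return out


def features_table(cohort, dist=None, config: KinematicsConfig | None = None) -> pd.DataFrame:
    """Feature rows for every execution x stage of a cohort.

    Columns: subject_id, group, equipment, stage, T_p, PL, v_d, a_d, j_d,
    d_tip, d_shape. A 6+6 cohort yields 48 rows (12 subjects x 2 equipment
    conditions x 2 stages).
    """
    rows = []
    for run in cohort.runs:
        for fv in extract_features(
            run.trajectory, run.stages, dist, run.shapes, config, equipment=run.equipment
        ):
            rows.append(
                {
                    "subject_id": run.subject_id,
                    "group": run.group,
                    "equipment": run.equipment,
                    **fv.as_dict(),
                }
            )
    return pd.DataFrame(rows)
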