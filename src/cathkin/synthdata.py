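"""Synthetic phantom, trajectory and cohort generation.

The study conditions this module emulates: a silicone type-I aortic-arch
phantom imaged as a bright lumen on a dark background at 720x576 (PAL), a
TAVI cannulation split into two stages (arch navigation; valve crossing into
the ventricle through a stenosis), and a 12-surgeon cohort (6 experts, 6
novices) each executing once with conventional catheters and once with a
slower-scaled robotic platform.

Tip motion is modeled as a chain of minimum-jerk sub-movements along the
lumen centerline separated by pauses, with smooth lateral drift inside the
lumen, white positional tremor, and occasional overshoot-plus-correction
events. Skill enters through the sub-movement count and duration, the pause
fraction, tremor amplitude, lateral drift and correction probability;
equipment enters through a speed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter
from scipy.spatial import cKDTree

from .kinematics import CatheterShape, StageSegmentation, Trajectory

__all__ = [
    "VesselGeometry",
    "MotionProfile",
    "SubjectRun",
    "Cohort",
    "DEFAULT_PROFILES",
    "default_arch_geometry",
    "straight_tube_geometry",
    "make_phantom",
    "simulate_trajectory",
    "make_shape_annotations",
    "render_video",
    "simulate_cohort",
]

_AR_COEFF = 0.95  # lateral drift: first-order autoregressive (smooth deflection)
_WALL_MARGIN = 1.5  # px kept between the noise-free tip and the lumen boundary


@dataclass
class VesselGeometry:
    """Planar lumen geometry: a centerline with a half-width profile.

    ``centerline``: (n, 2) ordered points (px); ``radius_profile``: lumen
    half-width at each point (px); ``valve_arclength``: arc-length position
    of the stenotic valve, where the radius attains its global minimum;
    ``stage1_span`` / ``stage2_span``: disjoint consecutive arc-length
    intervals covering the two procedure stages.
    """

    centerline: np.ndarray
    radius_profile: np.ndarray
    valve_arclength: float
    stage1_span: tuple[float, float]
    stage2_span: tuple[float, float]

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (n, 2) array")
        if self.radius_profile.shape != (self.centerline.shape[0],):
            raise ValueError("radius_profile must match centerline length")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError("centerline points must be distinct and ordered")
        if np.any(self.radius_profile <= 0):
            raise ValueError("all radii must be positive")
        self._s = np.concatenate([[0.0], np.cumsum(steps)])
        if not 0 <= self.valve_arclength <= self._s[-1]:
            raise ValueError("valve_arclength outside the centerline")
        if self.radius_at(self.valve_arclength) > self.radius_profile.min() + 1e-9:
            raise ValueError("radius at the valve must be the global minimum (stenosis)")
        (a1, b1), (a2, b2) = self.stage1_span, self.stage2_span
        if not (a1 < b1 and a2 < b2 and b1 <= a2 + 1e-9):
            raise ValueError("stage spans must be disjoint with stage1 before stage2")

    @property
    def arclengths(self) -> np.ndarray:
        return self._s

    @property
    def length(self) -> float:
        return float(self._s[-1])

    def point_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self._s, self.centerline[:, 0])
        y = np.interp(s, self._s, self.centerline[:, 1])
        return np.stack([x, y], axis=-1)

    def radius_at(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        return np.interp(s, self._s, self.radius_profile)

    def normal_at(self, s) -> np.ndarray:
        """Unit normal (tangent rotated +90 deg) at arc position(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        eps = max(self.length * 1e-6, 1e-6)
        p0 = self.point_at(np.clip(s - eps, 0, self.length))
        p1 = self.point_at(np.clip(s + eps, 0, self.length))
        tan = p1 - p0
        norm = np.linalg.norm(tan, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        tan = tan / norm
        return np.stack([-tan[..., 1], tan[..., 0]], axis=-1)

    def resample(self, spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (arclengths, points, radii) at roughly the given spacing."""
        n = max(2, int(np.ceil(self.length / spacing)) + 1)
        s = np.linspace(0.0, self.length, n)
        return s, self.point_at(s), self.radius_at(s)


@dataclass(frozen=True)
class MotionProfile:
    """Skill/equipment parameters governing the trajectory simulator.

    n_submovements: ballistic segments composing the run; skilled movement
    uses few. mean_submovement_duration (s) before the equipment speed
    scale. pause_fraction: fraction of total time stationary, in [0, 1).
    tremor_sd (px): white positional noise. correction_prob: chance a
    sub-movement overshoots and a corrective back-movement is appended.
    lateral_sd (px): sd of the smooth drift off the centerline.
    speed_scale: unitless; durations scale as 1/speed_scale (robotic < 1
    means slower motion).
    """

    n_submovements: int
    mean_submovement_duration: float
    pause_fraction: float
    tremor_sd: float
    correction_prob: float
    lateral_sd: float
    speed_scale: float

    def __post_init__(self) -> None:
        if self.n_submovements < 1:
            raise ValueError("n_submovements must be >= 1")
        if not 0 <= self.pause_fraction < 1:
            raise ValueError("pause_fraction must be in [0, 1)")
        if not 0 <= self.correction_prob <= 1:
            raise ValueError("correction_prob must be in [0, 1]")
        for name in ("mean_submovement_duration", "tremor_sd", "lateral_sd", "speed_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mean_submovement_duration <= 0 or self.speed_scale <= 0:
            raise ValueError("durations and speed_scale must be positive")


#: Group x equipment defaults. Contrasts mirror the study's directions
#: (experts faster and smoother; robotic slower), not its magnitudes.
DEFAULT_PROFILES: dict[tuple[str, str], MotionProfile] = {
    ("expert", "conventional"): MotionProfile(6, 2.0, 0.05, 0.5, 0.05, 1.0, 1.0),
    ("expert", "robotic"): MotionProfile(6, 2.0, 0.05, 0.5, 0.05, 1.0, 0.5),
    ("novice", "conventional"): MotionProfile(18, 3.0, 0.35, 1.5, 0.4, 3.0, 1.0),
    ("novice", "robotic"): MotionProfile(18, 3.0, 0.35, 1.5, 0.4, 3.0, 0.5),
}


def default_arch_geometry() -> VesselGeometry:
    """Type-I aortic arch sized for the canonical 720x576 frame.

    Descending limb (vertical, 200 px, radius 18), semicircular arch
    (radius 120), ascending limb tapering into a valve stenosis (radius 6),
    then widening into a ventricle chamber. Stage 2 starts 40 px (2 cm at
    an assumed 20 px/cm) proximal to the valve.
    """
    pts: list[tuple[float, float]] = []
    # descending limb, insertion at the bottom
    for y in np.arange(400.0, 200.0, -2.0):
        pts.append((500.0, y))
    # arch: semicircle, center (380, 200), radius 120
    for a in np.linspace(0.0, np.pi, 95):
        pts.append((380.0 + 120.0 * np.cos(a), 200.0 - 120.0 * np.sin(a)))
    # ascending limb down through the valve into the ventricle
    for y in np.arange(202.0, 420.0 + 1e-9, 2.0):
        pts.append((260.0, y))
    centerline = np.array(pts)

    radii = np.full(len(pts), 18.0)
    ys = centerline[:, 1]
    on_ascending = np.arange(len(pts)) >= len(pts) - len(np.arange(202.0, 420.0 + 1e-9, 2.0))
    taper = on_ascending & (ys >= 270.0) & (ys <= 330.0)
    radii[taper] = 18.0 + (6.0 - 18.0) * (ys[taper] - 270.0) / 60.0
    widen = on_ascending & (ys > 330.0) & (ys <= 360.0)
    radii[widen] = 6.0 + (26.0 - 6.0) * (ys[widen] - 330.0) / 30.0
    chamber = on_ascending & (ys > 360.0)
    radii[chamber] = 26.0

    steps = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    valve_s = float(s[np.flatnonzero(on_ascending & np.isclose(ys, 330.0))[0]])
    total = float(s[-1])
    return VesselGeometry(
        centerline, radii, valve_s, (0.0, valve_s - 40.0), (valve_s - 40.0, total)
    )


def straight_tube_geometry(
    length: float = 400.0,
    radius: float = 10.0,
    start: tuple[float, float] = (50.0, 100.0),
    stage_split: float = 0.6,
) -> VesselGeometry:
    """Horizontal constant-radius tube; handy for tests and examples."""
    xs = np.linspace(start[0], start[0] + length, max(2, int(length // 2) + 1))
    centerline = np.column_stack([xs, np.full_like(xs, start[1])])
    radii = np.full(xs.size, float(radius))
    return VesselGeometry(
        centerline,
        radii,
        valve_arclength=0.75 * length,
        stage1_span=(0.0, stage_split * length),
        stage2_span=(stage_split * length, length),
    )


def make_phantom(
    geometry: VesselGeometry,
    width: int = 720,
    height: int = 576,
    fg_intensity: int = 200,
    bg_intensity: int = 50,
    noise_sd: float = 0.0,
    seed: int | Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the lumen as a bright tube on a dark background.

    A pixel is foreground iff its center lies within the local lumen radius
    of the centerline (union of discs along a densely resampled centerline).
    Returns (uint8 image with optional Gaussian noise, noise-free boolean
    ground-truth mask).
    """
    if fg_intensity <= bg_intensity:
        raise ValueError("fg_intensity must exceed bg_intensity")
    _, pts, radii = geometry.resample(0.25)
    lo_x, hi_x = pts[:, 0] - radii, pts[:, 0] + radii
    lo_y, hi_y = pts[:, 1] - radii, pts[:, 1] + radii
    bad = (lo_x < 0) | (hi_x > width - 1) | (lo_y < 0) | (hi_y > height - 1)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"geometry exceeds frame bounds at centerline point {tuple(pts[i])} "
            f"with radius {radii[i]:.2f} (frame {width}x{height})"
        )
    mask = np.zeros((height, width), dtype=bool)
    for (cx, cy), r in zip(pts, radii):
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
        yy, xx = np.ogrid[y0 : y1 + 1, x0 : x1 + 1]
        mask[y0 : y1 + 1, x0 : x1 + 1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img = np.where(mask, float(fg_intensity), float(bg_intensity))
    if noise_sd > 0:
        rng = seed if isinstance(seed, Generator) else default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) = 10t^3 - 15t^4 + 6t^5."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def simulate_trajectory(
    geometry: VesselGeometry,
    profile: MotionProfile,
    dt: float = 1.0 / 25.0,
    seed: int | Generator = 0,
) -> tuple[Trajectory, StageSegmentation]:
    """Simulate a tip run along the full centerline.

    Arc-length progress is a chain of minimum-jerk sub-movement profiles
    separated by pauses totalling ``pause_fraction`` of total time; with
    probability ``correction_prob`` a sub-movement overshoots by 10-25% and
    a corrective back-movement follows. Lateral offset is an AR(1) process
    (coefficient 0.95) with stationary sd ``lateral_sd``, clipped to stay
    inside the lumen; tremor is white noise. Stage times are the first
    crossings of the stage-span boundaries. Deterministic under ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    total_len = geometry.length
    if total_len <= 0:
        raise ValueError("profile/geometry imply zero total displacement")

    n = profile.n_submovements
    disp = rng.dirichlet(np.full(n, 5.0)) * total_len
    durations = (
        profile.mean_submovement_duration * rng.lognormal(0.0, 0.25, n) / profile.speed_scale
    )
    corrections = rng.random(n) < profile.correction_prob
    over_fracs = rng.uniform(0.1, 0.25, n)

    units: list[list[tuple[float, float, float]]] = []  # per unit: (dur, s0, amp)
    s = 0.0
    for i in range(n):
        if corrections[i]:
            over = disp[i] * over_fracs[i]
            units.append(
                [
                    (durations[i], s, disp[i] + over),
                    (0.4 * durations[i], s + disp[i] + over, -over),
                ]
            )
        else:
            units.append([(durations[i], s, disp[i])])
        s += disp[i]
    active = sum(d for unit in units for d, _, _ in unit)
    pause_total = active * profile.pause_fraction / (1.0 - profile.pause_fraction)
    gaps = rng.dirichlet(np.full(n, 2.0)) * pause_total if pause_total > 0 else np.zeros(n)

    sched: list[tuple[float, float, float, float]] = []
    t = 0.0
    for unit, gap in zip(units, gaps):
        for dur, s0, amp in unit:
            sched.append((t, t + dur, s0, amp))
            t += dur
        t += gap
    total_t = t

    n_samp = max(2, int(round(total_t / dt)) + 1)
    times = np.linspace(0.0, total_t, n_samp)
    svals = np.zeros_like(times)
    for t0, t1, s0, amp in sched:
        m = (times >= t0) & (times < t1)
        tau = (times[m] - t0) / (t1 - t0)
        svals[m] = s0 + amp * _minimum_jerk(tau)
        svals[times >= t1] = s0 + amp
    svals = np.clip(svals, 0.0, total_len)

    noise = rng.normal(0.0, 1.0, (times.size, 3))  # drawn unconditionally: stable stream
    if profile.lateral_sd > 0:
        innov = noise[:, 0] * profile.lateral_sd * np.sqrt(1.0 - _AR_COEFF**2)
        lat = lfilter([1.0], [1.0, -_AR_COEFF], innov)
    else:
        lat = np.zeros(times.size)
    max_lat = np.maximum(geometry.radius_at(svals) - _WALL_MARGIN, 0.0)
    lat = np.clip(lat, -max_lat, max_lat)

    pos = geometry.point_at(svals) + geometry.normal_at(svals) * lat[:, None]
    if profile.tremor_sd > 0:
        pos = pos + noise[:, 1:] * profile.tremor_sd

    tol = max(1e-9, 1e-12 * total_len)

    def first_cross(boundary: float) -> float:
        idx = int(np.argmax(svals >= boundary - tol))
        return float(times[idx])

    t1a = first_cross(geometry.stage1_span[0])
    t1b = first_cross(geometry.stage1_span[1])
    t2b = first_cross(geometry.stage2_span[1])
    stages = StageSegmentation((t1a, t1b), (t1b, t2b))
    return Trajectory(times, pos), stages


def make_shape_annotations(
    trajectory: Trajectory,
    geometry: VesselGeometry,
    n_points: int = 15,
    frame_stride: int = 25,
    frames: Sequence[int] | None = None,
) -> list[CatheterShape]:
    """Trailing-catheter polylines: centerline from insertion to the tip.

    For each selected frame the tip is projected onto the centerline and the
    polyline from arc 0 to the tip is resampled to exactly ``n_points``
    points, mirroring spline-resampled manual annotations.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if frames is None:
        frames = range(0, len(trajectory), frame_stride)
    frames = list(frames)
    for f in frames:
        if not 0 <= f < len(trajectory):
            raise IndexError(f"frame {f} beyond trajectory of length {len(trajectory)}")
    _, dense_pts, _ = geometry.resample(1.0)
    dense_s = np.linspace(0.0, geometry.length, dense_pts.shape[0])
    tree = cKDTree(dense_pts)
    _, idx = tree.query(trajectory.xy[frames])
    shapes = []
    for f, i in zip(frames, np.atleast_1d(idx)):
        s_tip = dense_s[int(i)]
        targets = np.linspace(0.0, s_tip, n_points)
        shapes.append(CatheterShape(int(f), geometry.point_at(targets)))
    return shapes


def render_video(
    phantom: np.ndarray,
    trajectory: Trajectory,
    tip_intensity: int = 30,
    tip_radius: float = 4.0,
) -> np.ndarray:
    """Stamp a dark tip disc on the phantom for every trajectory sample.

    The disc edge is anti-aliased (coverage-weighted blend) so sub-pixel tip
    positions leave a usable intensity footprint. Returns a (n_frames, h, w)
    uint8 stack.
    """
    h, w = phantom.shape
    x, y = trajectory.x, trajectory.y
    r = float(tip_radius)
    if np.any((x - r < 0) | (x + r > w - 1) | (y - r < 0) | (y + r > h - 1)):
        raise ValueError("trajectory (with tip radius) leaves the frame")
    frames = np.repeat(phantom[None, :, :], len(trajectory), axis=0)
    pad = int(np.ceil(r)) + 1
    for i, (cx, cy) in enumerate(trajectory.xy):
        x0, x1 = int(np.floor(cx)) - pad, int(np.ceil(cx)) + pad
        y0, y1 = int(np.floor(cy)) - pad, int(np.ceil(cy)) + pad
        yy, xx = np.ogrid[y0 : y1 + 1, x0 : x1 + 1]
        d = np.hypot(xx - cx, yy - cy)
        wgt = np.clip(r + 0.5 - d, 0.0, 1.0)
        patch = frames[i, y0 : y1 + 1, x0 : x1 + 1].astype(float)
        patch = (1.0 - wgt) * patch + wgt * float(tip_intensity)
        frames[i, y0 : y1 + 1, x0 : x1 + 1] = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    return frames


@dataclass
class SubjectRun:
    """One execution: a subject with one equipment condition."""

    subject_id: str
    group: str
    equipment: str
    trajectory: Trajectory
    stages: StageSegmentation
    shapes: list[CatheterShape]


@dataclass
class Cohort:
    """All executions of a simulated study cohort."""

    runs: list[SubjectRun]

    def __len__(self) -> int:
        return len(self.runs)


def simulate_cohort(
    n_expert: int = 6,
    n_novice: int = 6,
    profiles: dict[tuple[str, str], MotionProfile] | None = None,
    between_subject_sd: float = 0.2,
    geometry: VesselGeometry | None = None,
    dt: float = 1.0 / 25.0,
    shape_points: int = 15,
    shape_stride: int = 25,
    seed: int = 0,
) -> Cohort:
    """Simulate a full cohort: every subject runs both equipment conditions.

    Per-subject skill parameters (sub-movement count/duration, pause odds,
    tremor) are the group defaults perturbed by shared lognormal multipliers
    with sigma ``between_subject_sd``, so a subject's two executions are
    correlated as in a paired design. Deterministic under ``seed``.
    """
    if n_expert < 1 or n_novice < 1:
        raise ValueError("group sizes must be >= 1")
    profiles = profiles or DEFAULT_PROFILES
    geometry = geometry or default_arch_geometry()
    ss = SeedSequence(seed)
    subj_rng = default_rng(ss.spawn(1)[0])
    runs: list[SubjectRun] = []
    subjects = [("expert", f"E{i + 1:02d}") for i in range(n_expert)] + [
        ("novice", f"N{i + 1:02d}") for i in range(n_novice)
    ]
    for group, sid in subjects:
        m_n, m_dur, m_pause, m_trem = subj_rng.lognormal(0.0, between_subject_sd, 4)
        for equipment in ("conventional", "robotic"):
            base = profiles[(group, equipment)]
            prof = replace(
                base,
                n_submovements=max(1, int(round(base.n_submovements * m_n))),
                mean_submovement_duration=base.mean_submovement_duration * m_dur,
                pause_fraction=min(0.9, base.pause_fraction * m_pause),
                tremor_sd=base.tremor_sd * m_trem,
            )
            run_rng = default_rng(ss.spawn(1)[0])
            traj, stages = simulate_trajectory(geometry, prof, dt, run_rng)
            # strided frames plus one frame near each stage midpoint, so
            # both stages always carry at least one shape annotation
            frames = set(range(0, len(traj), shape_stride))
            for a, b in (stages.stage1, stages.stage2):
                frames.add(int(np.argmin(np.abs(traj.t - 0.5 * (a + b)))))
            shapes = make_shape_annotations(
                traj, geometry, shape_points, frames=sorted(frames)
            )
            runs.append(SubjectRun(sid, group, equipment, traj, stages, shapes))
    return Cohort(runs)
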