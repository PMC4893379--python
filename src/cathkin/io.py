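"""Readers and writers for the artifact's file formats.

Coordinates are 0-based pixel centers, x = column rightward, y = row
downward, origin top-left, in every format. Numeric round-trips are
lossless at 1e-6 px / 1e-6 s.

Formats: trajectory CSV (frame,time_s,x_px,y_px; columns matched by name),
catheter shapes JSON ({frame: [[x, y] x n_points]}), stage annotation JSON
({"stage1": [t0, t1], "stage2": [t0, t1]}), 8-bit grayscale PNG images and
0/255 PNG masks, 32-bit float TIFF distance images, features CSV, and
generic results JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .kinematics import CatheterShape, StageSegmentation, Trajectory
from .segmentation import DistanceImage

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_shapes",
    "write_shapes",
    "read_stages",
    "write_stages",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_distance",
    "write_distance",
    "read_features",
    "write_features",
    "write_results",
]

_TRAJ_COLUMNS = ["frame", "time_s", "x_px", "y_px"]


def read_trajectory(path) -> Trajectory:
    """Parse a trajectory CSV; columns are matched by name in any order."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: trajectory file has no data rows")
    for col in _TRAJ_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    return Trajectory(df["time_s"].to_numpy(), df[["x_px", "y_px"]].to_numpy())


def write_trajectory(traj: Trajectory, path, frames: Sequence[int] | None = None) -> None:
    if frames is None:
        frames = np.arange(len(traj))
    df = pd.DataFrame(
        {"frame": np.asarray(frames, dtype=int), "time_s": traj.t, "x_px": traj.x, "y_px": traj.y}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_shapes(path) -> list[CatheterShape]:
    with open(path) as fh:
        raw = json.load(fh)
    shapes = [CatheterShape(int(frame), np.asarray(pts, dtype=float)) for frame, pts in raw.items()]
    shapes.sort(key=lambda s: s.frame)
    n_points = {s.points.shape[0] for s in shapes}
    if len(n_points) > 1:
        raise ValueError(f"{path}: inconsistent point counts across frames: {sorted(n_points)}")
    return shapes


def write_shapes(shapes: Sequence[CatheterShape], path) -> None:
    payload = {str(s.frame): np.round(s.points, 6).tolist() for s in shapes}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_stages(path) -> StageSegmentation:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return StageSegmentation(tuple(raw["stage1"]), tuple(raw["stage2"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing stage annotation {exc}") from None


def write_stages(stages: StageSegmentation, path) -> None:
    with open(path, "w") as fh:
        json.dump({"stage1": list(stages.stage1), "stage2": list(stages.stage2)}, fh)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img, dtype=np.uint8)


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return read_image(path) > 127


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_distance(path) -> DistanceImage:
    return DistanceImage(tifffile.imread(path).astype(float))


def write_distance(dist: DistanceImage, path) -> None:
    tifffile.imwrite(path, dist.distances.astype(np.float32))


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: features file has no rows")
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format="%.6f")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
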