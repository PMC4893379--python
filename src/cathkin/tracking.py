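"""Semi-automated catheter-tip tracking.

Frame-to-frame template matching by brute-force zero-normalized cross-
correlation (ZNCC) within a square search window around the previous tip
position. Low-confidence frames (score below a threshold) are flagged so a
user can re-seed the tracker there; in batch mode a re-seed mapping
{frame: (x, y)} substitutes for that interaction. The template is refreshed
from the newly found position each frame, which keeps it current as the
catheter deforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .kinematics import Trajectory

__all__ = ["TrackerState", "ncc_match", "track_tip"]


@dataclass
class TrackerState:
    """Tracker configuration and current estimate."""

    template: np.ndarray
    position: tuple[float, float]
    search_radius: int = 15
    score_threshold: float = 0.6

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.ndim != 2 or self.template.shape[0] != self.template.shape[1]:
            raise ValueError("template must be square")
        if self.template.shape[0] % 2 == 0:
            raise ValueError("template side must be odd (2r + 1)")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


def ncc_match(
    template: np.ndarray,
    frame: np.ndarray,
    center: Sequence[int],
    search_radius: int,
    return_scores: bool = False,
):
    """Best ZNCC offset of ``template`` around ``center`` in ``frame``.

    Evaluates the zero-normalized cross-correlation at every integer offset
    (dx, dy) with ``|dx|, |dy| <= search_radius``; the whole search window
    must lie inside the frame. Zero-variance template or window patches
    score 0. Ties are broken by the smallest offset norm, then row-major
    (dy, dx) order. Returns ((dx, dy), score).
    """
    tpl = np.asarray(template, dtype=float)
    frm = np.asarray(frame, dtype=float)
    if tpl.ndim != 2 or tpl.shape[0] != tpl.shape[1] or tpl.shape[0] % 2 == 0:
        raise ValueError("template must be square with odd side")
    r = tpl.shape[0] // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    s = int(search_radius)
    y0, y1 = cy - s - r, cy + s + r
    x0, x1 = cx - s - r, cx + s + r
    if y0 < 0 or x0 < 0 or y1 >= frm.shape[0] or x1 >= frm.shape[1]:
        raise ValueError("search window extends beyond the frame")

    region = frm[y0 : y1 + 1, x0 : x1 + 1]
    windows = sliding_window_view(region, tpl.shape)  # (2s+1, 2s+1, side, side)
    win = windows.reshape(windows.shape[0], windows.shape[1], -1)
    tvec = tpl.ravel() - tpl.mean()
    tnorm = np.linalg.norm(tvec)
    wmean = win.mean(axis=2, keepdims=True)
    wcent = win - wmean
    wnorm = np.linalg.norm(wcent, axis=2)
    denom = tnorm * wnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (wcent @ tvec) / np.where(denom > 0, denom, 1.0), 0.0)

    best = float(scores.max())
    ties = np.argwhere(scores >= best - 1e-12)
    offs = ties - s  # rows are (dy, dx)
    norms = (offs**2).sum(axis=1)
    order = np.lexsort((offs[:, 1], offs[:, 0], norms))
    dy, dx = offs[order[0]]
    if return_scores:
        return (int(dx), int(dy)), best, scores
    return (int(dx), int(dy)), best


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    av = a.ravel() - a.mean()
    bv = b.ravel() - b.mean()
    denom = np.linalg.norm(av) * np.linalg.norm(bv)
    return float(av @ bv / denom) if denom > 0 else 0.0


def _subpixel_peak(
    template: np.ndarray,
    frame: np.ndarray,
    cx: int,
    cy: int,
    step: float = 0.1,
) -> tuple[float, float]:
    """Fractional refinement of an integer ZNCC peak.

    Integer-offset matching quantizes each frame-to-frame displacement;
    with a refreshed template those residuals accumulate into unbounded
    drift on slowly moving targets (a parabolic fit does not help much:
    the ZNCC peak of a compact blob is conical, so the fit pixel-locks).
    Instead the ZNCC is evaluated directly against bilinearly interpolated
    patches, first on a ``step``-spaced grid within +-0.5 px of the peak,
    then on a 5x-finer grid around the coarse optimum (the scan resolution
    otherwise sets the per-frame error floor).
    """
    from scipy.ndimage import map_coordinates

    side = template.shape[0]
    r = side // 2
    base_y, base_x = np.mgrid[-r : r + 1, -r : r + 1]

    def scan(cx0: float, cy0: float, half: float, st: float) -> tuple[float, float]:
        offs = np.arange(-half, half + 1e-9, st)
        best = (-2.0, 0.0, 0.0)
        for fy in offs:
            for fx in offs:
                patch = map_coordinates(
                    frame,
                    [base_y + cy0 + fy, base_x + cx0 + fx],
                    order=1,
                    mode="nearest",
                )
                score = _zncc(template, patch)
                if score > best[0]:
                    best = (score, fx, fy)
        return best[1], best[2]

    fx, fy = scan(cx, cy, 0.5, step)
    gx, gy = scan(cx + fx, cy + fy, step, step / 5.0)
    return fx + gx, fy + gy


def track_tip(
    frames: np.ndarray | Sequence[np.ndarray],
    seed_point: Sequence[float],
    template_radius: int = 7,
    search_radius: int = 15,
    score_threshold: float = 0.6,
    dt: float = 1.0 / 25.0,
    reseed: Mapping[int, Sequence[float]] | None = None,
    prefilter_sigma: float = 1.0,
) -> tuple[Trajectory, list[int]]:
    """Track the tip through a frame sequence from a seed point.

    The template is cut around the seed in frame 0, matched in each
    subsequent frame around the previous position (integer search plus a
    fractional ZNCC scan), and refreshed from the new position after every
    frame. Frames whose best score falls below ``score_threshold`` are
    flagged (and the position is carried through the match result
    regardless); ``reseed`` entries override the position at the given
    frames, standing in for interactive bootstrapping. Timestamps are
    frame_index * dt.

    Frames are band-limited with a Gaussian of ``prefilter_sigma`` px
    before matching (0 disables); without it, sub-pixel interpolation of
    sharp edges carries a small motion-correlated bias that the per-frame
    template refresh accumulates into drift.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, h, w) stack of equally sized images")
    n, h, w = frames.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    if prefilter_sigma > 0:
        from scipy.ndimage import gaussian_filter

        frames = np.stack([gaussian_filter(f.astype(float), prefilter_sigma) for f in frames])
    reseed = {int(k): v for k, v in (reseed or {}).items()}
    r = int(template_radius)
    x, y = float(seed_point[0]), float(seed_point[1])
    if not (r <= x < w - r and r <= y < h - r):
        raise ValueError("seed point too close to the frame border for the template")

    def cut(frame: np.ndarray, px: float, py: float) -> tuple[np.ndarray, float, float]:
        """Template at the rounded position plus the tip's residual offset
        inside it; the residual must be added back after the next match or
        it accumulates as drift."""
        ix, iy = int(round(px)), int(round(py))
        return frame[iy - r : iy + r + 1, ix - r : ix + r + 1], px - ix, py - iy

    template, ox, oy = cut(frames[0], x, y)
    positions = [(x, y)]
    flagged: list[int] = []
    for i in range(1, n):
        if i in reseed:
            x, y = float(reseed[i][0]), float(reseed[i][1])
        else:
            # clamp so the search window stays inside the frame
            margin = r + search_radius
            qx = min(max(x, margin), w - 1 - margin)
            qy = min(max(y, margin), h - 1 - margin)
            (dx, dy), score = ncc_match(template, frames[i], (qx, qy), search_radius)
            fx, fy = _subpixel_peak(
                template, frames[i], int(round(qx)) + dx, int(round(qy)) + dy
            )
            x = round(qx) + dx + fx + ox
            y = round(qy) + dy + fy + oy
            x = min(max(x, r), w - 1 - r)
            y = min(max(y, r), h - 1 - r)
            if score < score_threshold:
                flagged.append(i)
        positions.append((x, y))
        template, ox, oy = cut(frames[i], x, y)
    times = np.arange(n) * dt
    return Trajectory(times, np.asarray(positions, dtype=float)), flagged
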