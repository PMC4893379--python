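"""Screen rectification into the canonical 720x576 frame.

Recordings of a fluoroscopy monitor captured by an external camera carry
perspective distortion. Given the four marked screen corners, a plane
projective map sends them onto the canonical rectangle so trajectories and
shape annotations from different recordings share one coordinate frame.
When the recorded screen is a parallelogram (fronto-parallel camera) the
map degenerates to an affine transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import ProjectiveTransform

__all__ = ["ScreenCalibration", "fit_screen_transform", "apply_transform"]

CANONICAL_SIZE = (720, 576)


@dataclass
class ScreenCalibration:
    """Projective map from recorded-screen pixels to the canonical frame.

    ``src_corners``: the four screen corners in the recording, ordered
    TL, TR, BR, BL; ``dst_size``: (width, height) of the canonical frame;
    ``matrix``: the 3x3 homography (normalized so H[2, 2] = 1, hence 8 free
    coefficients).
    """

    src_corners: np.ndarray
    dst_size: tuple[int, int]
    matrix: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        """The 8 free parameters, row-major, excluding the fixed H[2, 2] = 1."""
        return self.matrix.ravel()[:8]

    @property
    def is_affine(self) -> bool:
        return bool(np.allclose(self.matrix[2, :2], 0.0, atol=1e-9))


def _dst_corners(dst_size: Sequence[int]) -> np.ndarray:
    w, h = dst_size
    return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])


def fit_screen_transform(
    src_corners: Sequence[Sequence[float]],
    dst_size: Sequence[int] = CANONICAL_SIZE,
) -> ScreenCalibration:
    """Fit the unique homography sending the 4 screen corners onto the
    canonical rectangle (0,0), (W,0), (W,H), (0,H).

    Corners must be distinct and non-collinear (positive quadrilateral
    area). For a parallelogram source the projective terms vanish.
    """
    src = np.asarray(src_corners, dtype=float)
    if src.shape != (4, 2):
        raise ValueError("src_corners must be four 2D points (TL, TR, BR, BL)")
    if len({tuple(p) for p in src.tolist()}) < 4:
        raise ValueError("src_corners contains duplicate points")
    # shoelace area of the quadrilateral; zero area means collinear corners
    x, y = src[:, 0], src[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area < 1e-9:
        raise ValueError("src_corners are collinear (degenerate quadrilateral)")
    dst = _dst_corners(dst_size)
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        if not tform:
            raise ValueError(f"homography estimation failed: {tform}")
    else:  # older scikit-image
        tform = ProjectiveTransform()
        if not tform.estimate(src, dst):
            raise ValueError("homography estimation failed for the given corners")
    matrix = tform.params / tform.params[2, 2]
    calib = ScreenCalibration(src, (int(dst_size[0]), int(dst_size[1])), matrix)
    check = apply_transform(calib, src)
    if np.max(np.abs(check - dst)) > 1e-6:
        raise ValueError("fitted map does not reproduce the canonical corners")
    return calib


def apply_transform(calib: ScreenCalibration, points) -> np.ndarray:
    """Map points (n, 2) through the calibration homography.

    Homogeneous application; point order is preserved and timestamps are
    untouched (this function only sees coordinates). Points mapping to or
    beyond the plane at infinity (denominator <= 0) raise.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    hom = np.column_stack([pts, np.ones(pts.shape[0])])
    mapped = hom @ calib.matrix.T
    denom = mapped[:, 2]
    bad = denom <= 0
    if bad.any():
        raise ValueError(
            f"point index {int(np.argmax(bad))} maps to the plane at infinity (denominator <= 0)"
        )
    return mapped[:, :2] / denom[:, None]
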