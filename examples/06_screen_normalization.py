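"""Rectify trajectory coordinates recorded off a skewed fluoroscopy screen.

When a monitor is filmed by an external camera the screen appears as a
perspective-distorted quadrilateral. Marking its four corners fixes the
homography onto the canonical 720x576 frame; trajectories from different
recordings then share one coordinate system.
"""

import numpy as np

from cathkin.screen_norm import apply_transform, fit_screen_transform

# screen corners as seen by the camera (TL, TR, BR, BL), slightly keystoned
src_corners = [[102.0, 64.0], [838.0, 90.0], [804.0, 668.0], [76.0, 610.0]]
cal = fit_screen_transform(src_corners, (720, 576))

print("projective coefficients (h31, h32):", cal.matrix[2, :2].round(6))
print("degenerates to affine?", cal.is_affine)

corners_mapped = apply_transform(cal, src_corners)
print("corners map to:", corners_mapped.round(6).tolist())

recorded = np.array([[450.0, 350.0], [470.0, 352.0], [500.0, 360.0]])
canonical = apply_transform(cal, recorded)
print("recorded tip points", recorded.tolist())
print("  -> canonical frame", canonical.round(2).tolist())
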