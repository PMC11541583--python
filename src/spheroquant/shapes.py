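"""Sub-pixel shape descriptors shared by the pipelines.

Circularity is 4πA/P² (1 for a perfect disc); a digitised boundary makes
the perimeter P the delicate part.  The estimator here extracts the 0.5
iso-contour of the binary mask (marching squares, sub-pixel vertices) and
low-pass filters the vertex chain with a circular Gaussian before summing
segment lengths.  The filtering removes the staircase excess that would
otherwise bias smooth shapes (a raw marching-squares contour overestimates a
disc's perimeter by ~5%) while leaving straight edges essentially exact:
with the default smoothing a rasterised r=100 disc measures C=0.998 and a
200-px square C=0.796 (ideal π/4 ≈ 0.785).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import measure

from .errors import ValidationError

__all__ = ["perimeter_subpixel", "circularity", "sphericity_value"]

#: Gaussian sigma (in contour vertices ≈ pixels) of the contour low-pass.
CONTOUR_SMOOTHING = 2.0


def perimeter_subpixel(mask: np.ndarray, smoothing: float = CONTOUR_SMOOTHING) -> float:
    """Perimeter (in pixels) of a binary mask by smoothed sub-pixel contours.

    All 0.5-level contours are summed, so hole boundaries count; pass a
    hole-filled mask to measure the outer boundary only.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0.0
    # pad so objects touching the border still yield closed contours
    padded = np.pad(mask, 1).astype(float)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        closed = bool(np.allclose(contour[0], contour[-1]))
        pts = contour[:-1] if closed else contour
        if len(pts) < 4:
            # degenerate speck: fall back to raw polygon length
            total += float(np.sqrt((np.diff(contour, axis=0) ** 2).sum(1)).sum())
            continue
        mode = "wrap" if closed else "nearest"
        sm = np.column_stack(
            [
                gaussian_filter1d(pts[:, 0], smoothing, mode=mode),
                gaussian_filter1d(pts[:, 1], smoothing, mode=mode),
            ]
        )
        if closed:
            sm = np.vstack([sm, sm[:1]])
        total += float(np.sqrt((np.diff(sm, axis=0) ** 2).sum(1)).sum())
    return total


def circularity(mask: np.ndarray, smoothing: float = CONTOUR_SMOOTHING) -> float:
    """4πA/P² of a binary mask, clamped to [0, 1].

    Dimensionless, so pixel calibration cancels.  Raises on an empty mask.
    """
    mask = np.asarray(mask, bool)
    area = int(mask.sum())
    if area == 0:
        raise ValidationError("circularity of an empty mask is undefined")
    perim = perimeter_subpixel(mask, smoothing)
    if perim == 0.0:
        return 1.0
    return float(np.clip(4.0 * np.pi * area / perim**2, 0.0, 1.0))


def sphericity_value(volume: float, surface_area: float) -> float:
    """ψ = π^{1/3} (6V)^{2/3} / A, clamped to [0, 1]."""
    if volume <= 0 or surface_area <= 0:
        raise ValidationError("sphericity needs positive volume and area")
    psi = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area
    return float(np.clip(psi, 0.0, 1.0))
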