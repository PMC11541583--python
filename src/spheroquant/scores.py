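"""Closed-form scalar scores: caliper tumour volume and composite IHC score.

Tumour volume uses the ellipse-volume caliper formula
``V = π/6 (d1·d2)^{3/2}`` with the two perpendicular dimensions in mm, so V
is in mm³.  The composite immunohistochemistry score sums a percent-positive
bin (0-4) and a staining-intensity grade (0-3) into a 0-7 total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedRatioError, ValidationError

__all__ = ["IHCScore", "tumour_volume", "ihc_score", "relative_to_control"]

#: right-closed percent-positive bin edges: 0 → 0, (0,25] → 1, (25,50] → 2,
#: (50,75] → 3, (75,100] → 4
_BIN_EDGES = (0.0, 25.0, 50.0, 75.0)


@dataclass
class IHCScore:
    """Composite staining score: positivity bin + intensity grade."""

    percent_positive: float
    positivity_bin: int
    intensity_grade: int
    total: int


def tumour_volume(d1, d2):
    """Caliper tumour volume V = π/6 (d1·d2)^{3/2} (dimensions mm, V mm³).

    Accepts scalars or array-likes (elementwise); all inputs must be
    positive.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValidationError("caliper dimensions must be positive")
    v = np.pi / 6.0 * (d1 * d2) ** 1.5
    return float(v) if v.ndim == 0 else v


def ihc_score(percent_positive: float, intensity_grade: int) -> IHCScore:
    """Composite IHC score: percent-positive bin (0-4) + intensity grade (0-3).

    The percent-positive axis is binned right-closed: exactly 0% scores 0,
    (0,25]% scores 1, (25,50]% scores 2, (50,75]% scores 3 and anything
    above 75% scores 4.  The total is the sum of bin and grade (0-7).
    """
    if not 0.0 <= percent_positive <= 100.0:
        raise ValidationError("percent_positive must lie in [0, 100]")
    if intensity_grade not in (0, 1, 2, 3):
        raise ValidationError("intensity_grade must be an integer 0-3")
    pbin = int(sum(percent_positive > edge for edge in _BIN_EDGES))
    return IHCScore(
        percent_positive=float(percent_positive),
        positivity_bin=pbin,
        intensity_grade=int(intensity_grade),
        total=pbin + int(intensity_grade),
    )


def relative_to_control(values, control_mean: float):
    """Elementwise value / control_mean (errors on a zero control)."""
    if control_mean == 0:
        raise UndefinedRatioError("control mean is zero: ratios undefined")
    arr = np.asarray(values, float) / control_mean
    return arr.tolist() if isinstance(values, (list, tuple)) else arr
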