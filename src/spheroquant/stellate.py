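"""Stellate-spheroid invasion cytometry.

A single spheroid embedded in matrix grows a dense round core and sends
strands of cells invading outward.  The pipeline converts the image to
grey, removes uneven illumination with a local (rolling-ball) background
reduction, detects foreground objects by thresholding, derives a local
foreground-density image, and decomposes the foreground into three disjoint
compartments:

* inner core — the densest central region,
* outer core — the surrounding high-density ring,
* periphery — everything else: detached invading cells.

The invasion read-outs are the circularity of the inner core (1 = round,
least invasive) and the areas of the outer core and periphery in µm².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import DegenerateHistogramError, NoSpheroidError, ValidationError
from .frames import ImageFrame
from .shapes import circularity

__all__ = [
    "SpheroidZones",
    "StellateMetrics",
    "to_grey",
    "subtract_background",
    "detect_foreground",
    "density_map",
    "split_zones",
    "stellate_metrics",
    "analyze_stellate",
]

log = logging.getLogger(__name__)


@dataclass
class SpheroidZones:
    """The three disjoint spheroid compartments plus their inputs.

    Invariants: ``inner_core``, ``outer_core`` and ``periphery`` are
    pairwise disjoint and their union equals ``foreground``; density values
    lie in [0, 1].
    """

    inner_core: np.ndarray
    outer_core: np.ndarray
    periphery: np.ndarray
    foreground: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if (self.inner_core & self.outer_core).any() or (
            (self.inner_core | self.outer_core) & self.periphery
        ).any():
            raise ValidationError("zones must be pairwise disjoint")
        union = self.inner_core | self.outer_core | self.periphery
        if not np.array_equal(union, self.foreground):
            raise ValidationError("zones must partition the foreground exactly")


@dataclass
class StellateMetrics:
    """Invasion read-outs (areas in µm², circularity dimensionless)."""

    inner_circularity: float
    inner_area: float
    outer_area: float
    peripheral_area: float


def to_grey(frame: ImageFrame) -> ImageFrame:
    """Collapse 1-4 channels to grey by unweighted mean, rounded half-up."""
    if frame.n_channels == 1:
        return frame.with_pixels(frame.pixels.copy())
    if not 1 <= frame.n_channels <= 4:
        raise ValidationError(f"expected 1-4 channels, got {frame.n_channels}")
    mean = frame.pixels.astype(float).mean(axis=2)
    rounded = np.floor(mean + 0.5)  # round half-up, preserving bit depth
    return frame.with_pixels(rounded.astype(frame.pixels.dtype))


def subtract_background(
    grey: ImageFrame, ball_radius: float = 50.0, invert: bool | None = None
) -> ImageFrame:
    """Local background reduction by morphological rolling ball.

    Grey opening with a disc structuring element of ``ball_radius`` (µm)
    estimates the smooth background, which is subtracted (white top-hat);
    the result is non-negative everywhere.  ``ball_radius`` must exceed the
    radius of the largest object of interest — a disc the structuring
    element fits inside is absorbed into the background estimate and
    erased.  For whole-spheroid imaging that means a ball larger than the
    spheroid core (the stellate pipeline defaults to 250 µm), not merely
    larger than single cells.

    Brightfield spheroids are darker than their background; frames whose
    channel is ``"brightfield"`` (or with ``invert=True``) are inverted
    first so that positive objects are uniformly bright.
    """
    radius_px = ball_radius / grey.pixel_size
    if radius_px < 1:
        raise ValidationError(
            f"ball_radius {ball_radius} µm is below one pixel ({grey.pixel_size} µm)"
        )
    pixels = grey.pixels.astype(float)
    do_invert = invert if invert is not None else grey.channel == "brightfield"
    if do_invert:
        pixels = grey.max_value - pixels
    # edge-replicate padding: grey opening otherwise leaves a slope artefact
    # one ball-radius wide along the borders
    r = int(round(radius_px))
    footprint = morphology.disk(r, decomposition="sequence")
    padded = np.pad(pixels, r, mode="edge")
    background = morphology.opening(padded, footprint)[r:-r, r:-r]
    out = np.clip(pixels - background, 0.0, None)
    return grey.with_pixels(out)


def detect_foreground(
    grey: ImageFrame,
    method: str = "otsu",
    threshold: float | None = None,
    return_threshold: bool = False,
):
    """Mask of pixels strictly above an automatic (Otsu) or fixed threshold."""
    pixels = np.asarray(grey.pixels, float)
    if method == "otsu":
        if pixels.size == 0 or pixels.min() == pixels.max():
            raise DegenerateHistogramError(
                "constant image: Otsu threshold is undefined"
            )
        thr = float(filters.threshold_otsu(pixels))
    elif method == "fixed":
        if threshold is None:
            raise ValidationError('method "fixed" requires a threshold value')
        thr = float(threshold)
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    mask = pixels > thr
    log.info("foreground threshold (%s): %.6g", method, thr)
    if return_threshold:
        return mask, thr
    return mask


def density_map(
    foreground: np.ndarray, sigma: float = 20.0, pixel_size: float = 1.0
) -> np.ndarray:
    """Local foreground fraction: Gaussian-smoothed indicator in [0, 1].

    ``sigma`` is in µm; boundary handling is reflective so edge densities
    are unbiased.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    dens = ndimage.gaussian_filter(
        np.asarray(foreground, float), sigma / pixel_size, mode="reflect"
    )
    return np.clip(dens, 0.0, 1.0)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    if n > 1:
        log.info("multiple high-density blobs (%d); keeping the largest", n)
    # ties resolved by lowest label (deterministic scan order)
    return labels == (int(np.argmax(counts)) + 1)


def split_zones(
    foreground: np.ndarray,
    density: np.ndarray,
    d_hi: float = 0.75,
    d_lo: float = 0.35,
) -> SpheroidZones:
    """Decompose the foreground into inner core / outer core / periphery.

    The inner core is the hole-filled largest connected component of
    ``density >= d_hi`` (within the foreground); the outer core is the
    hole-filled largest component of ``density >= d_lo`` minus the inner
    core; the periphery is the remaining foreground.  Density-relative
    thresholds make the split invariant to global illumination scaling.
    """
    if not 0 < d_lo < d_hi <= 1:
        raise ValidationError(f"need 0 < d_lo < d_hi <= 1, got d_lo={d_lo}, d_hi={d_hi}")
    fg = np.asarray(foreground, bool)
    lo_sel = (density >= d_lo) & fg
    if not lo_sel.any():
        raise NoSpheroidError(f"no foreground pixel reaches density {d_lo}: no spheroid")
    lo_region = ndimage.binary_fill_holes(_largest_component(lo_sel))
    hi_sel = (density >= d_hi) & fg
    if hi_sel.any():
        hi_region = ndimage.binary_fill_holes(_largest_component(hi_sel))
    else:
        hi_region = np.zeros_like(fg)
    inner = hi_region & fg
    outer = lo_region & fg & ~inner
    periphery = fg & ~inner & ~outer
    return SpheroidZones(inner, outer, periphery, fg, density)


def stellate_metrics(zones: SpheroidZones, pixel_size: float) -> StellateMetrics:
    """Areas (µm²) of the three zones and inner-core circularity."""
    if not zones.inner_core.any():
        raise ValidationError("empty inner core: circularity undefined")
    px2 = pixel_size**2
    return StellateMetrics(
        inner_circularity=circularity(zones.inner_core),
        inner_area=float(zones.inner_core.sum() * px2),
        outer_area=float(zones.outer_core.sum() * px2),
        peripheral_area=float(zones.periphery.sum() * px2),
    )


def analyze_stellate(
    frame: ImageFrame,
    ball_radius: float = 250.0,
    sigma: float = 20.0,
    d_hi: float = 0.75,
    d_lo: float = 0.35,
    invert: bool | None = None,
    threshold_method: str = "otsu",
    threshold: float | None = None,
    exclude_mask: np.ndarray | None = None,
) -> tuple[StellateMetrics, SpheroidZones]:
    """Full pipeline: grey → background reduction → threshold → density → zones.

    ``exclude_mask`` (optional) marks artefact pixels to remove from the
    foreground before any measurement — the non-interactive stand-in for
    manual artefact correction.
    """
    grey = to_grey(frame)
    corrected = subtract_background(grey, ball_radius, invert=invert)
    fg = detect_foreground(corrected, method=threshold_method, threshold=threshold)
    if exclude_mask is not None:
        fg = fg & ~np.asarray(exclude_mask, bool)
    dens = density_map(fg, sigma=sigma, pixel_size=frame.pixel_size)
    zones = split_zones(fg, dens, d_hi=d_hi, d_lo=d_lo)
    return stellate_metrics(zones, frame.pixel_size), zones
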