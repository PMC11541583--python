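"""Calibrated image containers and standard-format I/O.

Every pipeline in the package consumes :class:`ImageFrame` (a single
calibrated 2D intensity plane) or :class:`ImageStack` (an ordered z- or
t-collection of frames).  Coordinates are 0-based pixel indices with
``x = column``, ``y = row`` and the origin at the top-left; physical areas
are reported in µm² via ``pixel_size**2`` and lengths in µm.

Calibration (``pixel_size``) is always supplied by the caller, never parsed
from TIFF tags: tag dialects are too inconsistent to trust silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "ImageFrame",
    "ImageStack",
    "RegionMetrics",
    "read_image",
    "write_image",
    "write_metrics",
]


@dataclass
class ImageFrame:
    """A single calibrated intensity plane.

    Parameters
    ----------
    pixels:
        2D array (grey) or 3D ``(H, W, C)`` array (multi-channel) of
        non-negative intensities.
    bit_depth:
        8 or 16; intensities must fit in ``[0, 2**bit_depth - 1]``.
    pixel_size:
        Isotropic calibration in µm per pixel; must be positive.
    channel:
        Free-text label, e.g. ``"brightfield"``, ``"calcein"``,
        ``"ethidium"``, ``"mKO2"``.  Frames labelled ``"brightfield"`` are
        inverted by the stellate pipeline before thresholding.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = 1.0
    channel: str = "grey"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(
                f"pixels must be 2D or 2D multi-channel, got ndim={self.pixels.ndim}"
            )
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.pixels.size:
            lo = float(self.pixels.min())
            hi = float(self.pixels.max())
            if lo < 0 or hi > self.max_value:
                raise ValidationError(
                    f"intensities [{lo}, {hi}] exceed [0, {self.max_value}] "
                    f"for bit_depth {self.bit_depth}"
                )

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray, **kw) -> "ImageFrame":
        """Copy of this frame with new pixel data (metadata preserved)."""
        return replace(self, pixels=pixels, **kw)


@dataclass
class ImageStack:
    """An ordered z- or t-collection of same-shaped frames.

    ``spacing`` is µm between planes for ``axis="z"`` and seconds between
    frames for ``axis="t"``.
    """

    frames: list[ImageFrame]
    axis: str = "z"
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.axis not in ("z", "t"):
            raise ValidationError(f'axis must be "z" or "t", got {self.axis!r}')
        if not self.spacing > 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        if len(self.frames) < 1:
            raise ValidationError("stack needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != first.shape:
                raise ValidationError("all frames in a stack must share dimensions")
            if f.pixel_size != first.pixel_size:
                raise ValidationError("all frames in a stack must share pixel_size")
            if f.channel != first.channel:
                raise ValidationError("all frames in a stack must share channel")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    def as_array(self) -> np.ndarray:
        """Frames stacked along a leading axis."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class RegionMetrics:
    """Per-object shape/intensity read-out (areas µm², lengths µm)."""

    area: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]
    mean_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.area < 0 or self.perimeter < 0:
            raise ValidationError("area and perimeter must be non-negative")
        if not 0.0 <= self.circularity <= 1.0:
            raise ValidationError("circularity must lie in [0, 1]")


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    return 16


def read_image(
    path: str | Path,
    pixel_size: float,
    channel: str = "grey",
    axis: str = "z",
    spacing: float = 1.0,
) -> ImageFrame | ImageStack:
    """Read a single- or multi-page TIFF as a calibrated frame or stack.

    Multi-page files return an :class:`ImageStack` with the given ``axis``
    and ``spacing``; single-page files return an :class:`ImageFrame`.
    TIFF resolution tags, if present, are ignored in favour of the explicit
    ``pixel_size`` argument.
    """
    if not pixel_size > 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no image pages")
    frames = [
        ImageFrame(p, bit_depth=_bit_depth_of(p), pixel_size=pixel_size, channel=channel)
        for p in pages
    ]
    if len(frames) == 1:
        return frames[0]
    return ImageStack(frames, axis=axis, spacing=spacing)


def write_image(image: ImageFrame | ImageStack, path: str | Path) -> None:
    """Write a frame or stack as an (8/16-bit) TIFF, preserving dtype."""
    path = Path(path)
    if isinstance(image, ImageFrame):
        data = image.pixels
        dtype = np.uint8 if image.bit_depth == 8 else np.uint16
        tifffile.imwrite(path, np.asarray(data).astype(dtype))
    else:
        dtype = np.uint8 if image.frames[0].bit_depth == 8 else np.uint16
        tifffile.imwrite(path, image.as_array().astype(dtype))


def write_metrics(
    records: Sequence[Mapping] | Iterable[Mapping],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write metric rows to a UTF-8, comma-separated, dot-decimal CSV.

    An empty record list with explicit ``columns`` produces a header-only
    file.  Returns the DataFrame that was written.
    """
    records = list(records)
    if records:
        df = pd.DataFrame(records)
        if columns is not None:
            df = df[list(columns)]
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False, encoding="utf-8")
    return df
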