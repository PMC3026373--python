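"""Binarization of color images into the positive/negative pixel grids
consumed by the density-based clusterer.

The default configuration (luminance channel, Otsu threshold, dark
lesion polarity) reflects the dermoscopy setting: pigmented lesions are
darker than the surrounding skin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import BinaryMask, RasterImage

__all__ = ["BinarizationConfig", "to_intensity", "otsu_threshold", "binarize"]

Channel = Literal["luminance", "red", "green", "blue"]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class BinarizationConfig:
    channel: Channel = "luminance"
    method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: int | None = None
    lesion_polarity: Literal["dark", "bright"] = "dark"

    def __post_init__(self) -> None:
        if self.method == "fixed":
            if self.fixed_threshold is None:
                raise ValueError("fixed_threshold is required for method='fixed'")
            if not 0 <= self.fixed_threshold <= 255:
                raise ValueError("fixed_threshold must lie in [0, 255]")


def to_intensity(image: RasterImage, channel: Channel = "luminance") -> np.ndarray:
    """Reduce an RGB image to an H×W uint8 intensity grid.

    ``luminance`` is the Rec.601 weighting round(0.299·R + 0.587·G +
    0.114·B); a named channel is returned verbatim.
    """
    px = image.pixels
    if channel == "luminance":
        lum = 0.299 * px[:, :, 0] + 0.587 * px[:, :, 1] + 0.114 * px[:, :, 2]
        return np.rint(lum).astype(np.uint8)
    try:
        return px[:, :, _CHANNEL_INDEX[channel]].copy()
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None


def otsu_threshold(intensity: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold on the 256-bin histogram.

    Returns the smallest t in [0, 254] maximizing the between-class
    variance of the partition {≤ t} / {> t}.  A constant image has no
    separating threshold and raises ``ValueError``.
    """
    hist = np.bincount(np.asarray(intensity, dtype=np.uint8).ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: intensity is constant, no Otsu threshold")
    hist = hist.astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels with value <= t
    m0 = np.cumsum(hist * levels)  # first moment of that class
    total, grand = w0[-1], m0[-1]
    w1 = total - w0
    # between-class variance for t = 0..254 (both classes non-empty)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (grand * w0 - total * m0) ** 2 / (w0 * w1)
    sigma_b = sigma_b[:255]
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))  # argmax takes the smallest tie


def binarize(image: RasterImage, config: BinarizationConfig | None = None) -> BinaryMask:
    """Threshold an image into a binary (segmented) mask.

    ``lesion_polarity='dark'`` marks pixels with intensity ≤ t positive;
    ``'bright'`` marks intensity > t.  Deterministic for a given image
    and config.
    """
    config = config or BinarizationConfig()
    intensity = to_intensity(image, config.channel)
    if config.method == "otsu":
        t = otsu_threshold(intensity)
    else:
        t = int(config.fixed_threshold)  # type: ignore[arg-type]
    if config.lesion_polarity == "dark":
        return BinaryMask(intensity <= t)
    return BinaryMask(intensity > t)
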