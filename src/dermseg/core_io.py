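"""Raster image / binary mask containers and PNG-level I/O.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left
pixel throughout the package.  Images are 24-bit RGB (``H×W×3`` uint8);
masks are boolean grids of the same shape whose ``True`` cells are the
positive (lesion) pixels.  ``Area()`` in the evaluation sense is the
number of positive pixels, exposed as :attr:`BinaryMask.positive_count`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "RasterImage",
    "BinaryMask",
    "OverlayLayer",
    "OverlaySpec",
    "load_image",
    "load_mask",
    "save_mask",
    "render_overlay",
]


@dataclass(frozen=True)
class RasterImage:
    """An H×W×3 8-bit color grid, row-major, top-left origin."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryMask:
    """An H×W boolean grid; True marks a positive (lesion) pixel."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"expected 2-D mask, got shape {v.shape}")
        if v.dtype != bool:
            v = v.astype(bool)
        object.__setattr__(self, "values", v)

    @property
    def positive_count(self) -> int:
        """Number of positive pixels (the Area() of the mask)."""
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.values, other.values))

    def __hash__(self) -> int:  # frozen dataclass wants one; identity is fine
        return id(self)


@dataclass(frozen=True)
class OverlayLayer:
    mask: BinaryMask
    color: tuple[int, int, int]
    style: Literal["filled-region", "contour-only"] = "contour-only"
    opacity: float = 1.0


@dataclass(frozen=True)
class OverlaySpec:
    """Ordered mask layers drawn over a base image, later layers on top."""

    layers: Sequence[OverlayLayer] = field(default_factory=tuple)


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/JPEG/TIFF/BMP raster as an RGB image.

    Grayscale sources are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder errors variously
        raise OSError(f"could not read image {path}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported channel layout {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        # 16-bit PNGs etc.: rescale to the 8-bit range
        arr = (arr.astype(np.float64) / arr.max() * 255.0).round().astype(np.uint8)
    return RasterImage(arr)


def load_mask(path: str | Path) -> BinaryMask:
    """Read a raster as a binary mask: first-channel value > 127 is positive."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"could not read mask {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask(arr > 127)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with 255 for positive, 0 for negative."""
    out = np.where(mask.values, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out, extension=".png")


def _contour(values: np.ndarray) -> np.ndarray:
    # boundary = mask minus its 4-neighbour erosion
    struct = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(values, structure=struct, border_value=0)
    return values & ~eroded


def render_overlay(image: RasterImage, spec: OverlaySpec, path: str | Path) -> None:
    """Draw mask layers over an image and write the result as a PNG.

    ``contour-only`` layers paint the mask's 4-neighbour boundary in the
    layer color; ``filled-region`` layers alpha-blend the whole region at
    the layer's opacity.  Later layers are drawn over earlier ones.
    """
    canvas = image.pixels.astype(np.float64).copy()
    for layer in spec.layers:
        if layer.mask.shape != image.shape:
            raise ValueError(
                f"layer mask shape {layer.mask.shape} does not match image {image.shape}"
            )
        color = np.asarray(layer.color, dtype=np.float64)
        if layer.style == "filled-region":
            region = layer.mask.values
            a = float(layer.opacity)
            canvas[region] = (1.0 - a) * canvas[region] + a * color
        else:
            canvas[_contour(layer.mask.values)] = color
    out = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out, extension=".png")
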