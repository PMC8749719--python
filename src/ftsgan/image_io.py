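"""Grayscale image containers and paired-directory I/O.

Pixels live on a unit scale: an 8-bit level ``k`` maps to ``k/255`` on read
and a value ``x`` is stored as ``round(255*x)`` (half-up) on write.  The
loss functions stay resolution- and scale-stable on this range, while the
entropy metric re-quantizes to 256 levels where a gray-level histogram is
required.  RGB inputs collapse to grayscale by the channel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Union

import imageio.v3 as iio
import numpy as np

from .exceptions import AlignmentError, DecodeError, DimensionError

__all__ = ["GrayImage", "ImagePair", "read_gray", "write_gray", "load_pairs", "as_pixels"]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity grid with values in [0, 1].

    Both dimensions must be at least 2 so that gradient-based metrics have
    neighboring pixels to difference.
    """

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise DimensionError(f"expected a 2-D pixel grid, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise DimensionError(f"image must be at least 2x2, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("pixel values must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def as_pixels(img: Union[GrayImage, np.ndarray]) -> np.ndarray:
    """Coerce a GrayImage or bare 2-D array to a float64 pixel array."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D pixel grid, got ndim={arr.ndim}")
    return np.asarray(arr, dtype=np.float64)


@dataclass(frozen=True)
class ImagePair:
    """Pixel-aligned visible/infrared image pair."""

    visible: GrayImage
    infrared: GrayImage
    pair_id: str = field(default="pair")

    def __post_init__(self):
        if not self.pair_id:
            raise ValueError("pair_id must be non-empty")
        if self.visible.shape != self.infrared.shape:
            raise AlignmentError(
                f"pair {self.pair_id!r}: visible {self.visible.shape} vs "
                f"infrared {self.infrared.shape}"
            )

    @property
    def shape(self) -> tuple:
        return self.visible.shape


def read_gray(path) -> GrayImage:
    """Read an 8/16-bit raster as a unit-scale grayscale image.

    RGB(A) inputs are reduced to a single channel by averaging the color
    channels (the alpha channel, if present, is dropped).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises backend-specific errors
        raise DecodeError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise DimensionError(f"zero-sized image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise DecodeError(f"unsupported image layout {arr.shape} in {path}")
    return GrayImage(arr)


def write_gray(img: Union[GrayImage, np.ndarray], path) -> Path:
    """Write a unit-scale image as an 8-bit grayscale file (half-up rounding)."""
    pixels = as_pixels(img)
    path = Path(path)
    levels = np.floor(255.0 * pixels + 0.5).astype(np.uint8)
    iio.imwrite(path, levels)
    return path


def load_pairs(visible_dir, infrared_dir) -> List[ImagePair]:
    """Assemble aligned pairs from two directories by matching filename stems.

    Only stems present in both directories form pairs; output is sorted by
    stem so the pairing is deterministic across runs.
    """
    visible_dir, infrared_dir = Path(visible_dir), Path(infrared_dir)
    vis = {p.stem: p for p in visible_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES}
    ir = {p.stem: p for p in infrared_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES}
    pairs = []
    for stem in sorted(vis.keys() & ir.keys()):
        v = read_gray(vis[stem])
        i = read_gray(ir[stem])
        if v.shape != i.shape:
            raise AlignmentError(
                f"pair {stem!r}: visible {v.shape} vs infrared {i.shape}"
            )
        pairs.append(ImagePair(visible=v, infrared=i, pair_id=stem))
    return pairs
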