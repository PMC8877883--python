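"""Grayscale image I/O, histograms and binary masks.

Images are 8-bit single-channel rasters with gray values in [0, 255].
All threshold selection downstream operates on the 256-bin histogram
only, so this module is the single place where pixels are touched.

Gray-level indexing convention
------------------------------
Externally (files, thresholds reported to the user, masks) gray values
live on the 0-255 scale. Internally, every mean and objective
computation uses the shifted scale ``i = g + 1`` so that levels run over
[1, 256]: this keeps logarithms, geometric and harmonic means, and
negative-order power means well defined without epsilon hacks. The
shift is applied when a histogram slice is turned into a
:class:`~hetmcet.mean_filters.ModeRegion` and undone when thresholds
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

from .errors import ImageReadError, UnsupportedBitDepthError

#: Number of representable gray levels.
N_LEVELS = 256

#: Rec.601 luma weights for RGB -> gray conversion.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale image.

    Parameters
    ----------
    pixels
        2-D integer array with values in [0, 255].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be integer-valued")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Histogram:
    """256-bin gray-level histogram of a :class:`GrayImage`.

    ``counts[g]`` is the number of pixels with gray value ``g`` on the
    0-255 scale; ``n_pixels`` is the total pixel count.
    """

    counts: np.ndarray
    n_pixels: int = field(default=0)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_LEVELS,):
            raise ValueError(f"counts must have shape ({N_LEVELS},)")
        if (c < 0).any():
            raise ValueError("histogram counts must be non-negative")
        total = int(c.sum())
        n = self.n_pixels or total
        if n != total:
            raise ValueError("n_pixels does not match sum of counts")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "n_pixels", n)

    @property
    def occupied_levels(self) -> np.ndarray:
        """Gray values (0-255 scale) with at least one pixel."""
        return np.flatnonzero(self.counts)


@dataclass(frozen=True)
class BinaryMask:
    """A two-region label map: 0 = background, 1 = foreground."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        uniq = np.unique(lab)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


def _to_gray(arr: np.ndarray, conversion: Union[str, int]) -> np.ndarray:
    """Reduce a (H, W, C) array to single channel per the conversion rule."""
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ImageReadError(f"expected 2-D or 3-D image data, got shape {arr.shape}")
    # Drop an alpha channel before converting.
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if isinstance(conversion, int):
        if not 0 <= conversion < arr.shape[2]:
            raise ValueError(f"channel index {conversion} out of range")
        return arr[:, :, conversion]
    if conversion == "mean":
        return arr.astype(np.float64).mean(axis=2)
    if conversion == "luminance":
        if arr.shape[2] != 3:
            raise ImageReadError("luminance conversion requires 3 channels")
        w = np.asarray(REC601_WEIGHTS)
        return arr.astype(np.float64) @ w
    raise ValueError(f"unknown conversion rule {conversion!r}")


def load_gray_image(
    path: Union[str, Path],
    conversion: Union[str, int] = "luminance",
    *,
    rescale: bool = False,
) -> GrayImage:
    """Read a raster file as an 8-bit grayscale image.

    Parameters
    ----------
    path
        PNG / TIFF / JPEG / BMP file.
    conversion
        How multi-channel inputs are reduced: ``"luminance"`` (Rec.601,
        the default), ``"mean"`` (unweighted channel average) or an
        integer channel index.
    rescale
        If True, deeper-than-8-bit integer images are linearly rescaled
        to [0, 255] (by the dtype's full range) and floats in [0, 1] are
        scaled by 255. If False such inputs raise
        :class:`UnsupportedBitDepthError`.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise ImageReadError(f"no such image file: {path}") from None
    except Exception as exc:  # decoder errors vary by plugin
        raise ImageReadError(f"cannot decode image file {path}: {exc}") from exc

    gray = _to_gray(np.asarray(arr), conversion)

    if np.issubdtype(gray.dtype, np.floating):
        # Float channels from conversion of uint8 data are fine; true
        # float images need the rescale flag.
        src_dtype = np.asarray(arr).dtype
        if np.issubdtype(src_dtype, np.floating):
            if not rescale:
                raise UnsupportedBitDepthError(
                    f"{path}: float image; pass rescale=True to map [0,1] -> [0,255]"
                )
            gray = gray * 255.0
        elif src_dtype != np.uint8:
            info = np.iinfo(src_dtype)
            if not rescale:
                raise UnsupportedBitDepthError(
                    f"{path}: {src_dtype} image; pass rescale=True to rescale to 8 bits"
                )
            gray = gray * (255.0 / info.max)
        return GrayImage(np.clip(np.rint(gray), 0, 255).astype(np.uint8))

    if gray.dtype != np.uint8:
        info = np.iinfo(gray.dtype)
        if not rescale:
            raise UnsupportedBitDepthError(
                f"{path}: {gray.dtype} image; pass rescale=True to rescale to 8 bits"
            )
        gray = np.rint(gray.astype(np.float64) * (255.0 / info.max))
    return GrayImage(np.clip(gray, 0, 255).astype(np.uint8))


def compute_histogram(img: GrayImage) -> Histogram:
    """Tally gray values into a 256-bin histogram."""
    counts = np.bincount(img.pixels.ravel(), minlength=N_LEVELS)
    return Histogram(counts.astype(np.int64))


def apply_threshold(img: GrayImage, t: int, *, invert: bool = False) -> BinaryMask:
    """Binarize an image at gray level ``t`` (0-255 scale).

    Foreground (label 1) is ``pixel > t``; with ``invert=True`` the
    polarity flips (useful when the object of interest is darker than
    the background, e.g. lesions on skin).
    """
    if not 0 <= int(t) <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    fg = img.pixels > int(t)
    if invert:
        fg = ~fg
    return BinaryMask(fg.astype(np.uint8))


def load_mask(path: Union[str, Path]) -> BinaryMask:
    """Read a ground-truth mask; any nonzero pixel counts as foreground."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise ImageReadError(f"no such mask file: {path}") from None
    except Exception as exc:
        raise ImageReadError(f"cannot decode mask file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[:, :, :3].max(axis=2)
    return BinaryMask((arr != 0).astype(np.uint8))


def save_mask(path: Union[str, Path], mask: BinaryMask) -> None:
    """Write a mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(Path(path), (mask.labels * np.uint8(255)))
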