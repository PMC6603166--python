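"""Raster image I/O, center-cropping, and value-range handling.

All pixel-space work in the package uses one container: an RGB float array
with intensities in [0, 1]. Grayscale sources (CLE frames are monochrome)
are stored with three equal channels so a single code path feeds the
feature extractor.

Coordinate convention: row-major, origin at the top-left, half-open index
ranges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio


class ImageFormatError(ValueError):
    """Unsupported bit depth, channel count, or pixel range."""


@dataclass(frozen=True)
class Image:
    """An H×W×3 intensity array in [0, 1] plus an opaque source label."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"Image requires an H×W×3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("Image dimensions must be positive")
        if not np.all(np.isfinite(px)):
            raise ImageFormatError("Image intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImageFormatError(
                f"Image intensities must lie in [0,1]; got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_grayscale(self) -> bool:
        """True when all three channels are identical."""
        px = self.pixels
        return bool(
            np.array_equal(px[..., 0], px[..., 1])
            and np.array_equal(px[..., 1], px[..., 2])
        )


_SUPPORTED_DTYPES = {
    np.dtype(np.uint8): 255.0,
    np.dtype(np.uint16): 65535.0,
}


def load_image(path: str | os.PathLike) -> Image:
    """Read an 8- or 16-bit PNG/TIFF as an Image with intensities in [0,1].

    Single-channel sources are replicated to three equal channels; an
    alpha channel, if present, is dropped.
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises various backend errors
        raise IOError(f"could not read image file {path!r}: {exc}") from exc

    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ImageFormatError(
            f"{path!r}: unsupported pixel dtype {arr.dtype}; expected 8- or "
            "16-bit unsigned integer PNG/TIFF"
        )
    scale = _SUPPORTED_DTYPES[arr.dtype]

    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ImageFormatError(f"{path!r}: unsupported array rank {arr.ndim}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path!r}: unsupported channel count {arr.shape[2]}; expected 1 or 3"
        )
    pixels = arr.astype(np.float64) / scale
    return Image(pixels=pixels, source_id=os.path.basename(path))


def save_image(img: Image, path: str | os.PathLike) -> None:
    """Write an Image as an 8-bit PNG.

    Intensities are clamped to [0,1] and mapped by round(v*255) with
    half-away-from-zero rounding, so save/load round-trips within 1/255
    per channel.
    """
    path = os.fspath(path)
    clamped = np.clip(img.pixels, 0.0, 1.0)
    # np.round is half-to-even; floor(x+0.5) is half-away-from-zero for x >= 0
    quantized = np.floor(clamped * 255.0 + 0.5).astype(np.uint8)
    try:
        iio.imwrite(path, quantized, extension=".png")
    except Exception as exc:
        raise IOError(f"could not write image file {path!r}: {exc}") from exc


def center_crop(img: Image, fraction: float) -> Image:
    """Take the centered window with side round(fraction * dim) on each axis.

    Any off-by-one slack from centering goes to the bottom/right. Used to
    focus raters on a manageable number of structures per field of view.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"crop fraction must be in (0, 1]; got {fraction}")
    out_h = int(round(fraction * img.height))
    out_w = int(round(fraction * img.width))
    if out_h < 1 or out_w < 1:
        raise ValueError(
            f"crop fraction {fraction} yields an empty window for a "
            f"{img.height}×{img.width} image"
        )
    top = (img.height - out_h) // 2
    left = (img.width - out_w) // 2
    cropped = img.pixels[top : top + out_h, left : left + out_w, :].copy()
    return Image(pixels=cropped, source_id=img.source_id)
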