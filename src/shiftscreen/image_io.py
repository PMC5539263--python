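"""Reading, writing and preparing image matrices.

Every algorithm in this package operates on an *image matrix*: a 2-D
integer array of gray levels in ``0..255`` (the familiar 0–1 intensity
scale of an 8-bit image times 255).  Integer levels make "identical
pixels" an exact integer comparison with no floating-point tolerance.

Monochrome regions (typically pure white and pure black) match each
other trivially and would swamp the shift statistics with false
positives, so :func:`mask_monochrome` replaces them with unique negative
sentinel values that can never equal anything — including themselves in
a self-comparison, because comparisons treat any negative value as a
non-match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ImageFormatError",
    "LossyCompressionWarning",
    "AlphaChannelWarning",
    "MaskedImage",
    "DEFAULT_MONO_LEVELS",
    "read_image",
    "write_image",
    "rgb_to_gray",
    "mask_monochrome",
    "as_image_matrix",
    "write_heatmap_png",
]

#: ITU-R BT.601 luminance weights used for RGB → gray conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Levels masked by default: pure black and pure white.
DEFAULT_MONO_LEVELS = frozenset({0, 255})


class ImageFormatError(ValueError):
    """Raised for undecodable files or formats outside PNG/JPEG."""


class LossyCompressionWarning(UserWarning):
    """Emitted when a JPEG is read: lossy compression alters pixel data."""


class AlphaChannelWarning(UserWarning):
    """Emitted when an alpha channel is discarded."""


@dataclass(frozen=True)
class MaskedImage:
    """Image matrix whose monochrome pixels carry unmatchable sentinels.

    ``values`` holds either a valid gray level in ``0..255`` or a
    negative sentinel.  Sentinels are the consecutive integers
    ``-1, -2, ...`` assigned in row-major order, unique by construction.
    """

    values: np.ndarray
    sentinel_count: int

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


def as_image_matrix(arr) -> np.ndarray:
    """Validate and convert ``arr`` to an int32 image matrix.

    Raises :class:`ValueError` unless ``arr`` is a non-empty 2-D integer
    grid with every level in ``[0, 255]``.
    """
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("an image matrix must be a non-empty 2-D array")
    if not np.issubdtype(a.dtype, np.integer):
        if not np.all(a == np.floor(a)):
            raise ValueError("image levels must be integers")
    a = a.astype(np.int32)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("image levels must lie in [0, 255]")
    return a


def rgb_to_gray(red, green, blue):
    """Convert RGB levels (0..255 each) to a rounded gray level.

    Uses BT.601 luminance ``0.299 R + 0.587 G + 0.114 B`` with
    round-half-up, so equal-channel pixels ``(g, g, g)`` map exactly to
    ``g`` and the result is monotone in each channel.  Accepts scalars
    or arrays (broadcast elementwise).
    """
    r = np.asarray(red, dtype=np.float64)
    g = np.asarray(green, dtype=np.float64)
    b = np.asarray(blue, dtype=np.float64)
    for ch in (r, g, b):
        if ch.size and (ch.min() < 0 or ch.max() > 255):
            raise ValueError("RGB channel values must lie in [0, 255]")
    wr, wg, wb = GRAY_WEIGHTS
    y = np.floor(wr * r + wg * g + wb * b + 0.5).astype(np.int32)
    if y.ndim == 0:
        return int(y)
    return y


def read_image(path) -> np.ndarray:
    """Read a PNG or JPEG file into an 8-bit gray image matrix.

    Color images are converted through :func:`rgb_to_gray`; 16-bit
    grayscale PNGs are rescaled to 8 bits with rounding; an alpha
    channel is dropped with an :class:`AlphaChannelWarning`.  JPEG input
    is accepted but triggers a :class:`LossyCompressionWarning`, since
    lossy compression destroys the exact pixel identities the counting
    algorithms rely on — lossless PNG is preferred.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    try:
        with Image.open(p) as im:
            im.load()
            fmt = im.format
            if fmt not in ("PNG", "JPEG"):
                raise ImageFormatError(
                    f"unsupported image format {fmt!r} for {p}; PNG or JPEG required"
                )
            if fmt == "JPEG":
                warnings.warn(
                    f"{p}: JPEG uses lossy compression; exact-identity screening "
                    "is unreliable on re-encoded data. Prefer lossless PNG.",
                    LossyCompressionWarning,
                    stacklevel=2,
                )
            if im.mode == "P":
                im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            if im.mode in ("RGBA", "LA"):
                warnings.warn(
                    f"{p}: discarding alpha channel", AlphaChannelWarning, stacklevel=2
                )
                im = im.convert("RGB" if im.mode == "RGBA" else "L")
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode image file {p}: {exc}") from exc
    except OSError as exc:
        raise ImageFormatError(f"cannot read image file {p}: {exc}") from exc

    if arr.ndim == 3:
        levels = rgb_to_gray(arr[..., 0], arr[..., 1], arr[..., 2])
    elif arr.dtype.itemsize > 1:
        # deeper-than-8-bit grayscale: rescale to 0..255 with rounding
        peak = 65535.0 if arr.max() > 255 else 255.0
        levels = np.floor(arr.astype(np.float64) / peak * 255.0 + 0.5).astype(np.int32)
    else:
        levels = arr.astype(np.int32)
    return as_image_matrix(levels)


def write_image(img, path) -> None:
    """Write an image matrix as an 8-bit grayscale PNG (always lossless)."""
    a = as_image_matrix(img)
    Image.fromarray(a.astype(np.uint8), mode="L").save(Path(path), format="PNG")


def mask_monochrome(img, mono_levels=DEFAULT_MONO_LEVELS) -> MaskedImage:
    """Replace pixels at the given levels with unique negative sentinels.

    ``mono_levels`` defaults to pure black and white.  Sentinels are
    ``-1, -2, ...`` in row-major order over the masked pixels; they lie
    outside the gray range, so a masked pixel never equals any pixel,
    masked or not.
    """
    a = as_image_matrix(img)
    levels = sorted(set(int(v) for v in mono_levels))
    if any(v < 0 or v > 255 for v in levels):
        raise ValueError("mono_levels must be gray levels in [0, 255]")
    out = a.copy()
    if levels:
        flat = out.ravel()
        idx = np.flatnonzero(np.isin(flat, levels))
        flat[idx] = -1 - np.arange(idx.size, dtype=np.int32)
        count = int(idx.size)
    else:
        count = 0
    return MaskedImage(values=out, sentinel_count=count)


def write_heatmap_png(grid, path) -> None:
    """Write any 2-D numeric grid as a 16-bit grayscale PNG heatmap.

    Values are linearly rescaled so the grid minimum maps to 0 and the
    maximum to 65535 (a constant grid maps to all zeros).  Intended for
    visual inspection of shift grids and localization matrices.
    """
    a = np.asarray(grid, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("heatmap input must be a non-empty 2-D array")
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        scaled = (a - lo) / (hi - lo) * 65535.0
    else:
        scaled = np.zeros_like(a)
    im = Image.fromarray(np.floor(scaled + 0.5).astype(np.uint16))
    im.save(Path(path), format="PNG")
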