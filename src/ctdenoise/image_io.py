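"""Grayscale image container and PNG/TIFF round-trip I/O.

Every other module operates on :class:`Image`: a 2-D array of *real-valued*
intensities on the canonical domain ``[0, gray_range]``.  The gray range
``L`` (255 for 8-bit sources, 65535 for 16-bit) is carried as metadata
because the peak signal-to-noise ratio needs it explicitly; pixels are never
silently rescaled to ``[0, 1]``.  Quantization happens only on write.

Indexing is row-major: ``pixels[row, col]`` = ``(y, x)``, 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

from .errors import ChannelError, DimensionError, FormatError, ParameterError

__all__ = ["Image", "read_image", "write_image", "normalize"]

#: ITU-R BT.601 luminance weights used when collapsing RGB to gray.
_LUMA = np.array([0.299, 0.587, 0.114])

_READABLE_EXT = {".png", ".tif", ".tiff"}


@dataclass
class Image:
    """A 2-D grayscale image with an explicit gray range.

    Parameters
    ----------
    pixels : numpy.ndarray
        2-D float array, shape ``(A, B)`` = (rows, cols).  Values are real
        intensities; they may exceed ``[0, gray_range]`` transiently (e.g.
        after noise degradation) and are clipped only on write.
    gray_range : float
        Maximum representable intensity ``L`` (> 0), e.g. 255.0.
    origin : str
        Free-text provenance tag.
    """

    pixels: np.ndarray
    gray_range: float = 255.0
    origin: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not self.gray_range > 0:
            raise ParameterError(f"gray_range must be > 0, got {self.gray_range}")
        self.pixels = px
        self.gray_range = float(self.gray_range)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self, **changes) -> "Image":
        out = replace(self, **changes)
        if "pixels" not in changes:
            out.pixels = self.pixels.copy()
        return out


def read_image(path: str | os.PathLike, force_gray: bool = False) -> Image:
    """Read an 8- or 16-bit PNG/TIFF into a canonical :class:`Image`.

    ``gray_range`` is set from the stored bit depth (255 or 65535).
    Multi-channel inputs are collapsed to luminance when ``force_gray`` is
    set and rejected otherwise.  DICOM is not supported in this build.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".dcm", ".dicom"}:
        raise FormatError("DICOM reading is not supported in this build (pydicom unavailable)")
    if ext not in _READABLE_EXT:
        raise FormatError(f"unsupported image format: {ext!r} (PNG or TIFF required)")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises assorted per-plugin errors
        raise FormatError(f"could not read {path}: {exc}") from exc

    if arr.ndim == 3:
        if not force_gray:
            raise ChannelError(
                f"{path} has {arr.shape[-1]} channels; pass force_gray=True to collapse to luminance"
            )
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise FormatError(f"expected a 2-D image, got array of shape {arr.shape}")

    if arr.dtype == np.uint8:
        gray_range = 255.0
    elif arr.dtype == np.uint16:
        gray_range = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        # luminance path, or float TIFF: infer range from the 8-bit default
        gray_range = 255.0 if arr.max() <= 255 else 65535.0
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype}")
    return Image(np.asarray(arr, dtype=np.float64), gray_range, origin=str(path))


def write_image(img: Image, path: str | os.PathLike, bit_depth: int = 8) -> None:
    """Quantize to ``bit_depth`` bits and write losslessly as PNG/TIFF.

    Intensities are clipped to ``[0, L]``, linearly mapped to
    ``[0, 2**bit_depth - 1]`` and rounded half-away-from-zero.
    """
    if bit_depth not in (8, 16):
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _READABLE_EXT:
        raise FormatError(f"unsupported output format: {ext!r} (PNG or TIFF required)")
    max_code = 2**bit_depth - 1
    scaled = np.clip(img.pixels, 0.0, img.gray_range) * (max_code / img.gray_range)
    # values are non-negative, so floor(x + 0.5) rounds half away from zero
    codes = np.floor(scaled + 0.5)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    try:
        iio.imwrite(path, codes.astype(dtype))
    except (OSError, PermissionError) as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def normalize(img: Image, new_L: float) -> Image:
    """Linearly rescale so the range ``[0, L]`` maps onto ``[0, new_L]``."""
    if not new_L > 0:
        raise ParameterError(f"new_L must be > 0, got {new_L}")
    scale = float(new_L) / img.gray_range
    return Image(img.pixels * scale, float(new_L), origin=img.origin)
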