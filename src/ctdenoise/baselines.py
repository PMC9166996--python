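"""Classical spatial filters used as comparison baselines.

Box (mean), median and locally adaptive Wiener filtering with reflect
padding throughout.  These are the traditional denoisers the ICA and
wavelet methods are benchmarked against.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import Image

__all__ = ["mean_filter", "median_filter", "wiener_filter"]


def _check_kernel(img: Image, k: int) -> None:
    if k < 3 or k % 2 == 0:
        raise ParameterError(f"kernel size must be an odd integer >= 3, got {k}")
    if k > min(img.shape):
        raise ParameterError(f"kernel size {k} exceeds image extent {img.shape}")


def mean_filter(img: Image, k: int = 3) -> Image:
    """k x k box average, reflect padding."""
    _check_kernel(img, k)
    out = ndimage.uniform_filter(img.pixels, size=k, mode="reflect")
    return Image(out, img.gray_range, origin=f"mean_filter(k={k}) <- {img.origin}")


def median_filter(img: Image, k: int = 3) -> Image:
    """k x k window median, reflect padding."""
    _check_kernel(img, k)
    out = ndimage.median_filter(img.pixels, size=k, mode="reflect")
    return Image(out, img.gray_range, origin=f"median_filter(k={k}) <- {img.origin}")


def wiener_filter(img: Image, k: int = 3, noise_var: float | str = "auto") -> Image:
    """Locally adaptive (Lee-style) Wiener filter.

    With local mean ``m`` and variance ``s^2`` over a k x k window, the
    output is ``m + max(0, s^2 - v) / max(s^2, v) * (x - m)`` where ``v`` is
    the noise variance (``"auto"``: the mean of the local variances, the
    usual global estimate).  Flat regions collapse to their local mean;
    ``noise_var=0`` is the identity.
    """
    _check_kernel(img, k)
    x = img.pixels
    m = ndimage.uniform_filter(x, size=k, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=k, mode="reflect")
    s2 = np.maximum(m2 - m * m, 0.0)
    if noise_var == "auto":
        v = float(s2.mean())
    else:
        v = float(noise_var)
        if v < 0:
            raise ParameterError(f"noise_var must be >= 0, got {noise_var}")
    num = np.maximum(s2 - v, 0.0)
    den = np.maximum(s2, v)
    gain = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if v == 0.0:  # no assumed noise: pass the image through untouched
        out = x.copy()
    else:
        out = m + gain * (x - m)
    return Image(out, img.gray_range, origin=f"wiener_filter(k={k}, v={v:.4g}) <- {img.origin}")
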