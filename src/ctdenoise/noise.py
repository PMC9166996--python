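"""Gaussian degradation models and noise-statistics estimators.

Quantum and photon noise in X-ray CT are both modelled as pixelwise
independent Gaussian fields (no spatial correlation).  Two degradation
models are supported:

* additive:        ``g = z + n``
* multiplicative:  ``g = z * (1 + n)``

The multiplicative model becomes additive under a log transform
(``log g = log z + log(1 + n)``); to keep that transform defined, the
multiplicative sampler truncates draws at ``n > -1`` by resampling.

Noise mean and variance use the population (1/AB) normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError
from .image_io import Image

__all__ = [
    "NoiseSpec",
    "sample_noise",
    "degrade",
    "noise_mean",
    "noise_variance",
    "estimate_sigma",
]

KINDS = ("additive_gaussian", "multiplicative_gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one degradation model.

    mu and sigma are the mean and standard deviation of the Gaussian noise
    field n(x, y); for the multiplicative kind they apply to the relative
    fluctuation, so sigma=0.1 means ~10% intensity variation.
    """

    kind: str
    mu: float = 0.0
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mu": self.mu, "sigma": self.sigma, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(
            kind=d["kind"],
            mu=float(d.get("mu", 0.0)),
            sigma=float(d.get("sigma", 0.0)),
            seed=d.get("seed"),
        )


def sample_noise(spec: NoiseSpec, shape: tuple[int, int]) -> np.ndarray:
    """Draw an i.i.d. Gaussian noise field, deterministic given ``spec.seed``.

    For the multiplicative kind, draws with ``n <= -1`` are resampled so
    that ``1 + n`` stays strictly positive (keeps the log transform defined).
    """
    if len(shape) != 2 or shape[0] < 1 or shape[1] < 1:
        raise DimensionError(f"shape must be a positive (A, B) pair, got {shape}")
    rng = np.random.default_rng(spec.seed)
    field = spec.mu + spec.sigma * rng.standard_normal(shape)
    if spec.kind == "multiplicative_gaussian" and spec.sigma > 0:
        bad = field <= -1.0
        while np.any(bad):
            field[bad] = spec.mu + spec.sigma * rng.standard_normal(int(bad.sum()))
            bad = field <= -1.0
    return field


def degrade(img: Image, spec: NoiseSpec) -> Image:
    """Apply the degradation model; output is NOT clipped (clip on write)."""
    n = sample_noise(spec, img.shape)
    if spec.kind == "additive_gaussian":
        g = img.pixels + n
    else:
        g = img.pixels * (1.0 + n)
    tag = f"degrade({spec.kind}, mu={spec.mu}, sigma={spec.sigma}, seed={spec.seed})"
    return Image(g, img.gray_range, origin=f"{tag} <- {img.origin}")


def _as_field(field) -> np.ndarray:
    arr = np.asarray(getattr(field, "pixels", field), dtype=np.float64)
    if arr.size == 0:
        raise DimensionError("empty noise field")
    return arr


def noise_mean(field) -> float:
    """Mean total noise intensity: (1/AB) sum n(x, y)."""
    return float(np.mean(_as_field(field)))


def noise_variance(field) -> float:
    """Fluctuation of noise intensity: (1/AB) sum (n - mu)^2 (population)."""
    arr = _as_field(field)
    return float(np.mean((arr - arr.mean()) ** 2))


def estimate_sigma(img: Image | np.ndarray) -> float:
    """Robust noise-std estimate from the finest diagonal wavelet band.

    Uses the median absolute deviation of the level-1 diagonal detail
    coefficients, ``median(|d|) / 0.6745`` — consistent for the std of
    additive Gaussian noise and insensitive to the underlying image, since
    the finest diagonal band of a piecewise-smooth image is noise-dominated.
    """
    from .wavelet import WaveletConfig, wavelet_decompose

    arr = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DimensionError(f"need a 2-D image of at least 2x2, got shape {arr.shape}")
    image = img if isinstance(img, Image) else Image(arr)
    pyr = wavelet_decompose(image, WaveletConfig(levels=1))
    diag = pyr.details[0][2]
    return float(np.median(np.abs(diag)) / 0.6745)
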