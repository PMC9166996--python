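"""Synthetic kidney-CT-like phantoms with exact clean references.

The phantom is piecewise constant in the Shepp-Logan tradition: a dark
background, a bright rotated-ellipse "parenchyma" organ, and an embedded
elliptical "lesion", optionally overlaid with low-amplitude band-limited
texture.  Sharp ellipse boundaries exercise the edge-preservation claims of
the denoisers, and the construction gives an exact ground truth for
PSNR/RMSE scoring.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import Image
from .noise import NoiseSpec, degrade

__all__ = ["Ellipse", "PhantomSpec", "generate_phantom", "make_fixture_set", "DEFAULT_SIGMAS"]

#: Noise levels of the standard benchmark sweep.
DEFAULT_SIGMAS = (10.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class Ellipse:
    """A rotated ellipse in (row, col) pixel coordinates.

    ``axes`` are the semi-axes (before rotation, along row/col);
    ``rotation`` is in radians, counter-clockwise in (row, col) space.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ParameterError(f"ellipse semi-axes must be > 0, got {self.axes}")

    def quadratic(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(u/a)^2 + (v/b)^2 in the ellipse frame; <= 1 means inside."""
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        u = ct * dr + st * dc
        v = -st * dr + ct * dc
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        return self.quadratic(rows, cols) <= 1.0

    def boundary(self, n: int = 360) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        u = self.axes[0] * np.cos(t)
        v = self.axes[1] * np.sin(t)
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        return self.center[0] + ct * u - st * v, self.center[1] + st * u + ct * v

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])


def _default_organ(shape: tuple[int, int]) -> Ellipse:
    A, B = shape
    return Ellipse(center=(A / 2.0, B / 2.0), axes=(0.38 * A, 0.30 * B), rotation=0.4)


def _default_lesion(shape: tuple[int, int]) -> Ellipse:
    A, B = shape
    return Ellipse(
        center=(A / 2.0 - 0.08 * A, B / 2.0 + 0.06 * B),
        axes=(0.09 * A, 0.06 * B),
        rotation=0.8,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity levels and texture of one synthetic phantom.

    Default levels (30 / 120 / 200 on an 8-bit range) give CT-like contrast
    between background, parenchyma and lesion; ``texture_amp`` is the std of
    the smooth intra-organ texture in gray levels (0 disables it).
    """

    shape: tuple[int, int] = (256, 256)
    gray_range: float = 255.0
    background_level: float = 30.0
    parenchyma_level: float = 120.0
    lesion_level: float = 200.0
    organ: Ellipse | None = None
    lesion: Ellipse | None = None
    texture_amp: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ParameterError(f"phantom shape must be at least 8x8, got {self.shape}")
        for name in ("background_level", "parenchyma_level", "lesion_level"):
            v = getattr(self, name)
            if not 0 <= v <= self.gray_range:
                raise ParameterError(f"{name}={v} outside [0, {self.gray_range}]")
        if self.texture_amp < 0:
            raise ParameterError(f"texture_amp must be >= 0, got {self.texture_amp}")

    def resolved(self) -> tuple[Ellipse, Ellipse]:
        organ = self.organ or _default_organ(self.shape)
        lesion = self.lesion or _default_lesion(self.shape)
        return organ, lesion


def generate_phantom(spec: PhantomSpec | None = None) -> Image:
    """Rasterize the phantom; with ``texture_amp=0`` it is exactly 3-valued."""
    spec = spec or PhantomSpec()
    organ, lesion = spec.resolved()

    br, bc = lesion.boundary()
    if np.any(organ.quadratic(br, bc) > 1.0):
        raise ParameterError("lesion ellipse must lie entirely inside the organ ellipse")

    img = np.full(spec.shape, spec.background_level, dtype=np.float64)
    img[organ.mask(spec.shape)] = spec.parenchyma_level
    img[lesion.mask(spec.shape)] = spec.lesion_level

    if spec.texture_amp > 0:
        rng = np.random.default_rng(spec.seed)
        tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=4.0, mode="reflect")
        tex *= spec.texture_amp / tex.std()
        img = np.clip(img + tex, 0.0, spec.gray_range)

    return Image(img, spec.gray_range, origin=f"phantom(seed={spec.seed})")


def make_fixture_set(
    sigmas: list[float] | tuple[float, ...] | None = None,
    base: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[Image, Image, float]]:
    """One clean phantom plus one additive-Gaussian copy per noise level.

    Returns ``(clean, noisy, sigma)`` triples; the clean image is shared.
    Noise seeds are derived deterministically from ``seed``.
    """
    sigmas = DEFAULT_SIGMAS if sigmas is None else tuple(sigmas)
    if len(sigmas) == 0:
        raise ParameterError("sigmas must be non-empty")
    base = base or PhantomSpec(seed=seed)
    clean = generate_phantom(base)
    noise_seeds = np.random.SeedSequence(seed).generate_state(len(sigmas))
    out = []
    for s, nseed in zip(sigmas, noise_seeds):
        spec = NoiseSpec("additive_gaussian", mu=0.0, sigma=float(s), seed=int(nseed) % 2**31)
        out.append((clean, degrade(clean, spec), float(s)))
    return out
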