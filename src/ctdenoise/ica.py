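"""FastICA and patch-based sparse-code-shrinkage denoising.

The estimator is classical fixed-point FastICA with deflation: data are
centered and whitened by eigen-decomposition, then each unmixing vector
``w`` (unit norm in whitened space) is refined by

    w  <-  E[x g(w^T x)] - E[g'(w^T x)] w,

orthogonalized against previously found components and renormalized, until
``|<w_k, w_{k-1}>| > 1 - tol``.  Non-Gaussianity is measured through a
smooth contrast ``G`` — log-cosh (``G1``, the robust general-purpose
choice) or the Gaussian kernel (``G2``) — whose negentropy proxy is
``|E[G(y)] - E[G(v)]|^p`` with ``v`` standard normal.

Denoising a *single* image treats its (DC-removed) patches as mixtures of
independent sparse sources plus Gaussian noise: an ICA basis is fitted to
the noisy patches themselves, patch codes are soft-thresholded per
component at ``t_j = sigma_j^2 / scale_j`` (``sigma_j`` = image noise std
propagated through the analysis filter, ``scale_j`` = robust MAD scale of
that component's responses), and the patches are re-synthesized and
overlap-added.  A two-observation separation mode (several registered noisy
copies of the same scene) is provided as a secondary entry point.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate

from .errors import DimensionError, ParameterError
from .image_io import Image

__all__ = [
    "ICAModel",
    "PatchConfig",
    "PatchGrid",
    "contrast_eval",
    "center_whiten",
    "fastica_fit",
    "negentropy_objective",
    "extract_patches",
    "reconstruct_patches",
    "shrink_code",
    "ica_denoise",
    "ica_separate",
]

_MAD_TO_STD = 0.6745  # Phi^{-1}(3/4): MAD -> std for a Gaussian


# ---------------------------------------------------------------------------
# contrast functions
# ---------------------------------------------------------------------------

def _check_contrast_params(kind: str, a1: float, a2: float) -> None:
    if kind not in ("G1", "G2"):
        raise ParameterError(f"contrast kind must be 'G1' or 'G2', got {kind!r}")
    if kind == "G1" and not (1.0 <= a1 <= 2.0):
        raise ParameterError(f"a1 must lie in [1, 2], got {a1}")
    if kind == "G2" and not a2 > 0:
        raise ParameterError(f"a2 must be > 0, got {a2}")


def contrast_eval(
    u: np.ndarray, kind: str = "G1", a1: float = 1.0, a2: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the contrast ``G`` with its first two derivatives ``g, g'``.

    G1(u) = (1/a1) log cosh(a1 u),  g1 = tanh(a1 u),  g1' = a1 (1 - tanh^2)
    G2(u) = -(1/a2) exp(-a2 u^2/2), g2 = u exp(-a2 u^2/2),
                                    g2' = (1 - a2 u^2) exp(-a2 u^2/2)
    """
    _check_contrast_params(kind, a1, a2)
    u = np.asarray(u, dtype=np.float64)
    if kind == "G1":
        th = np.tanh(a1 * u)
        # log cosh via logaddexp avoids overflow for large |u|
        G = (np.logaddexp(a1 * u, -a1 * u) - math.log(2.0)) / a1
        return G, th, a1 * (1.0 - th * th)
    e = np.exp(-a2 * u * u / 2.0)
    return -e / a2, u * e, (1.0 - a2 * u * u) * e


@lru_cache(maxsize=None)
def _gaussian_expectation(kind: str, a1: float, a2: float) -> float:
    """E[G(v)] for standard normal v, by adaptive quadrature (cached)."""

    def integrand(t: float) -> float:
        G, _, _ = contrast_eval(np.array([t]), kind, a1, a2)
        return float(G[0]) * math.exp(-t * t / 2.0) / math.sqrt(2.0 * math.pi)

    val, _ = integrate.quad(integrand, -12.0, 12.0, limit=200)
    return val


def negentropy_objective(
    y: np.ndarray, kind: str = "G1", a1: float = 1.0, a2: float = 1.0, p: float = 2.0
) -> float:
    """Non-Gaussianity proxy ``|E[G(y)] - E[G(v)]|^p`` (zero for Gaussian y).

    ``y`` should be approximately zero-mean, unit-variance.  ``p`` only
    rescales the objective monotonically; default 2.
    """
    G, _, _ = contrast_eval(np.asarray(y, dtype=np.float64).ravel(), kind, a1, a2)
    gap = abs(float(G.mean()) - _gaussian_expectation(kind, float(a1), float(a2)))
    return gap**p


# ---------------------------------------------------------------------------
# whitening and the fixed-point iteration
# ---------------------------------------------------------------------------

def center_whiten(
    data: np.ndarray, eig_rtol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center rows-as-observations data and whiten to identity covariance.

    Returns ``(Z, K, mean)`` with ``Z = (data - mean) @ K.T`` having zero
    mean and (population) covariance equal to the identity.  Directions with
    eigenvalue below ``eig_rtol`` times the largest are dropped, so ``K`` may
    be rectangular (k x d with k <= d).
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise DimensionError(f"data must be 2-D (observations x dimensions), got {X.shape}")
    n, d = X.shape
    if n <= d:
        raise DimensionError(f"need more observations than dimensions, got {n} x {d}")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_rtol * max(evals[0], 0.0)
    if not np.any(keep):
        raise np.linalg.LinAlgError("covariance is numerically zero; nothing to whiten")
    evals, evecs = evals[keep], evecs[:, keep]
    K = evecs.T / np.sqrt(evals)[:, None]
    return Xc @ K.T, K, mean


@dataclass
class ICAModel:
    """Fitted unmixing state.

    ``components`` has unit-norm, mutually orthogonal rows in whitened
    space; ``whitening``/``dewhitening`` map centered data to whitened space
    and back.  ``converged[i]`` is False when component ``i`` hit
    ``max_iter`` without the fixed point stabilizing (typical for
    near-Gaussian directions; the basis is still orthonormal and usable).
    """

    data_mean: np.ndarray
    whitening: np.ndarray
    dewhitening: np.ndarray
    components: np.ndarray
    contrast: str = "G1"
    a1: float = 1.0
    a2: float = 1.0
    n_iter: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    converged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def analysis_matrix(self) -> np.ndarray:
        """Rows are the filters mapping centered data to source codes."""
        return self.components @ self.whitening

    def synthesis_matrix(self) -> np.ndarray:
        """Columns are the basis patches mapping codes back to centered data."""
        return self.dewhitening @ self.components.T

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project observations (rows) onto the independent components."""
        return (np.asarray(data, dtype=np.float64) - self.data_mean) @ self.analysis_matrix().T

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "data_mean": self.data_mean.tolist(),
            "whitening": self.whitening.tolist(),
            "dewhitening": self.dewhitening.tolist(),
            "components": self.components.tolist(),
            "contrast": self.contrast,
            "a1": self.a1,
            "a2": self.a2,
            "n_iter": self.n_iter.tolist(),
            "converged": self.converged.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ICAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            data_mean=np.asarray(d["data_mean"], dtype=np.float64),
            whitening=np.asarray(d["whitening"], dtype=np.float64),
            dewhitening=np.asarray(d["dewhitening"], dtype=np.float64),
            components=np.asarray(d["components"], dtype=np.float64),
            contrast=d["contrast"],
            a1=float(d["a1"]),
            a2=float(d["a2"]),
            n_iter=np.asarray(d["n_iter"], dtype=int),
            converged=np.asarray(d["converged"], dtype=bool),
        )


def fastica_fit(
    data: np.ndarray,
    n_components: int | None = None,
    kind: str = "G1",
    a1: float = 1.0,
    a2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = None,
) -> ICAModel:
    """Fit FastICA by deflation on rows-as-observations data.

    Whitening is applied internally.  ``n_components=None`` extracts one
    component per retained whitened dimension.  Non-convergence of a
    component is flagged in ``model.converged``, not raised.
    """
    _check_contrast_params(kind, a1, a2)
    if max_iter < 1:
        raise ParameterError(f"max_iter must be >= 1, got {max_iter}")
    Z, K, mean = center_whiten(data)
    n, k_white = Z.shape
    if n_components is None:
        n_components = k_white
    if not 1 <= n_components <= k_white:
        raise ParameterError(
            f"n_components must lie in [1, {k_white}] (whitened dimension), got {n_components}"
        )

    rng = np.random.default_rng(seed)
    W = np.zeros((n_components, k_white))
    n_iter = np.zeros(n_components, dtype=int)
    converged = np.zeros(n_components, dtype=bool)

    for i in range(n_components):
        w = rng.standard_normal(k_white)
        if i:
            w -= W[:i].T @ (W[:i] @ w)
        w /= np.linalg.norm(w)
        for it in range(1, max_iter + 1):
            wx = Z @ w
            _, g, gp = contrast_eval(wx, kind, a1, a2)
            w_new = (Z.T @ g) / n - gp.mean() * w
            if i:
                w_new -= W[:i].T @ (W[:i] @ w_new)
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-12:  # degenerate direction, restart from random
                w_new = rng.standard_normal(k_white)
                if i:
                    w_new -= W[:i].T @ (W[:i] @ w_new)
                nrm = np.linalg.norm(w_new)
            w_new /= nrm
            done = abs(float(w_new @ w)) > 1.0 - tol
            w = w_new
            if done:
                converged[i] = True
                break
        n_iter[i] = it
        # fix sign: largest-magnitude entry positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        W[i] = w

    dewhitening = np.linalg.pinv(K)
    return ICAModel(
        data_mean=mean,
        whitening=K,
        dewhitening=dewhitening,
        components=W,
        contrast=kind,
        a1=a1,
        a2=a2,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchConfig:
    """Square sliding-patch extraction parameters."""

    patch_size: int = 8
    stride: int = 4
    remove_dc: bool = True

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ParameterError(f"patch_size must be >= 2, got {self.patch_size}")
        if not 1 <= self.stride <= self.patch_size:
            raise ParameterError(
                f"stride must lie in [1, patch_size={self.patch_size}], got {self.stride}"
            )


@dataclass(frozen=True)
class PatchGrid:
    """Geometry needed to overlap-add patches back into an image."""

    origins_r: tuple[int, ...]
    origins_c: tuple[int, ...]
    patch_size: int
    image_shape: tuple[int, int]
    gray_range: float
    origin: str = ""


def _origins(dim: int, p: int, stride: int) -> tuple[int, ...]:
    starts = list(range(0, dim - p + 1, stride))
    if starts[-1] != dim - p:  # clamp a final patch to the border
        starts.append(dim - p)
    return tuple(starts)


def extract_patches(
    img: Image, cfg: PatchConfig | None = None
) -> tuple[np.ndarray, np.ndarray, PatchGrid]:
    """Flatten sliding square patches into rows of a data matrix.

    Returns ``(patches, means, grid)`` where ``patches`` is
    ``(n_patches, patch_size**2)`` with patches flattened row-major.  With
    ``remove_dc`` each patch's mean is subtracted and returned in ``means``
    (zeros otherwise).  Right/bottom borders are covered by a final patch
    clamped to the edge.
    """
    cfg = cfg or PatchConfig()
    A, B = img.shape
    p = cfg.patch_size
    if p > min(A, B):
        raise DimensionError(f"patch_size {p} exceeds image extent {img.shape}")
    rows = _origins(A, p, cfg.stride)
    cols = _origins(B, p, cfg.stride)
    patches = np.empty((len(rows) * len(cols), p * p), dtype=np.float64)
    i = 0
    for r in rows:
        for c in cols:
            patches[i] = img.pixels[r : r + p, c : c + p].ravel()
            i += 1
    if cfg.remove_dc:
        means = patches.mean(axis=1)
        patches -= means[:, None]
    else:
        means = np.zeros(len(patches))
    grid = PatchGrid(rows, cols, p, (A, B), img.gray_range, img.origin)
    return patches, means, grid


def reconstruct_patches(
    patches: np.ndarray, means: np.ndarray, grid: PatchGrid
) -> Image:
    """Overlap-add patches, averaging each pixel by its coverage count."""
    p = grid.patch_size
    n_expected = len(grid.origins_r) * len(grid.origins_c)
    if patches.shape != (n_expected, p * p) or means.shape != (n_expected,):
        raise DimensionError(
            f"patch matrix {patches.shape} / means {means.shape} inconsistent with "
            f"grid of {n_expected} patches of {p}x{p}"
        )
    acc = np.zeros(grid.image_shape)
    cnt = np.zeros(grid.image_shape)
    i = 0
    for r in grid.origins_r:
        for c in grid.origins_c:
            acc[r : r + p, c : c + p] += (patches[i] + means[i]).reshape(p, p)
            cnt[r : r + p, c : c + p] += 1.0
            i += 1
    return Image(acc / cnt, grid.gray_range, origin=grid.origin)


# ---------------------------------------------------------------------------
# shrinkage denoising
# ---------------------------------------------------------------------------

def shrink_code(code: np.ndarray, sigma: float, component_scale: float) -> np.ndarray:
    """Soft-threshold one component's codes at ``t = sigma^2 / scale``.

    ``sigma`` is the noise std seen by this component (image noise
    propagated through its analysis filter); ``component_scale`` is the
    scale of the component's *signal* content (``ica_denoise`` estimates it
    robustly from the MAD of the responses).  A zero scale with positive
    sigma means the component carries no signal: it is zeroed.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    code = np.asarray(code, dtype=np.float64)
    if sigma == 0.0:
        return code.copy()
    if component_scale <= 0.0:
        return np.zeros_like(code)
    t = sigma * sigma / component_scale
    return np.sign(code) * np.maximum(np.abs(code) - t, 0.0)


def ica_denoise(
    img: Image,
    cfg: PatchConfig | None = None,
    sigma: float | str = "auto",
    model: ICAModel | str = "fit",
    seed: int | None = None,
    n_components: int | None = None,
    kind: str = "G1",
    a1: float = 1.0,
    a2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Image:
    """Denoise one image by sparse code shrinkage in a patch ICA basis.

    Pipeline: extract patches -> fit FastICA on the noisy patches (or reuse
    ``model``) -> project onto components -> soft-threshold each component's
    codes -> re-synthesize -> overlap-add.  ``sigma="auto"`` estimates the
    noise level from the finest diagonal wavelet band.
    """
    cfg = cfg or PatchConfig()
    if sigma == "auto":
        from .noise import estimate_sigma

        sigma = estimate_sigma(img)
    sigma = float(sigma)
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")

    patches, means, grid = extract_patches(img, cfg)
    if model == "fit":
        model = fastica_fit(
            patches,
            n_components=n_components,
            kind=kind,
            a1=a1,
            a2=a2,
            tol=tol,
            max_iter=max_iter,
            seed=seed,
        )
    elif not isinstance(model, ICAModel):
        raise ParameterError(f"model must be an ICAModel or 'fit', got {model!r}")

    analysis = model.analysis_matrix()  # (k, d)
    codes = (patches - model.data_mean) @ analysis.T
    filter_norms = np.linalg.norm(analysis, axis=1)
    # robust total scale of each component's responses, then the noise
    # contribution is subtracted in quadrature to leave the signal scale
    # (BayesShrink-style); noise-dominated components get scale 0 => zeroed
    mad_scales = np.median(np.abs(codes - np.median(codes, axis=0)), axis=0) / _MAD_TO_STD
    for j in range(codes.shape[1]):
        sigma_j = sigma * filter_norms[j]
        signal_scale = math.sqrt(max(mad_scales[j] ** 2 - sigma_j**2, 0.0))
        codes[:, j] = shrink_code(codes[:, j], sigma_j, signal_scale)

    patches_hat = codes @ model.synthesis_matrix().T + model.data_mean
    out = reconstruct_patches(patches_hat, means, grid)
    tag = f"ica_denoise(patch={cfg.patch_size}, stride={cfg.stride}, sigma={sigma:.4g})"
    return Image(out.pixels, img.gray_range, origin=f"{tag} <- {img.origin}")


def ica_separate(
    images: list[Image],
    seed: int | None = None,
    kind: str = "G1",
    a1: float = 1.0,
    a2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[list[Image], ICAModel]:
    """Unmix >= 2 registered observations of the same scene pixelwise.

    Each pixel is treated as one observation of an m-dimensional mixture
    (m = number of images); FastICA recovers m maximally independent source
    images (unit variance, arbitrary sign/order).  This is the classical
    blind-separation reading of a polluted image as a mixture of the source
    image and noise.
    """
    if len(images) < 2:
        raise ParameterError("separation mode needs at least 2 registered images")
    shape = images[0].shape
    L = images[0].gray_range
    for im in images[1:]:
        if im.shape != shape:
            raise DimensionError(f"all images must share a shape, got {shape} vs {im.shape}")
    X = np.stack([im.pixels.ravel() for im in images], axis=1)
    model = fastica_fit(X, kind=kind, a1=a1, a2=a2, tol=tol, max_iter=max_iter, seed=seed)
    S = model.transform(X)
    sources = [
        Image(S[:, j].reshape(shape), L, origin=f"ica_separate component {j}")
        for j in range(S.shape[1])
    ]
    return sources, model
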