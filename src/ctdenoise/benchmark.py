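"""Benchmark harness: degrade a phantom, run denoisers, score, tabulate.

`run_sweep` reproduces the standard experiment grid — additive Gaussian
noise at several sigma levels, several seeds each — for any subset of the
methods {ica, wavelet, mean, median, wiener, none} ("none" scores the raw
noisy image).  Denoisers receive the true simulation sigma; blind "auto"
estimation is a property of the individual modules, not of the benchmark.
Results come back as a tidy pandas table, one row per (method, sigma, seed).
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import baselines
from .errors import EmptyInputError, ParameterError
from .ica import PatchConfig, ica_denoise
from .image_io import Image
from .metrics import quality_report
from .noise import NoiseSpec, degrade
from .phantom import DEFAULT_SIGMAS, PhantomSpec, generate_phantom
from .wavelet import WaveletConfig, wavelet_denoise

__all__ = ["METHODS", "run_sweep", "summarize", "write_csv", "plot_sweep", "CSV_COLUMNS"]

CSV_COLUMNS = ["method", "sigma", "seed", "psnr", "rmse", "mse", "runtime_s"]

METHODS = ("ica", "wavelet", "mean", "median", "wiener", "none")


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0]) % 2**31


def _apply_method(
    name: str,
    noisy: Image,
    sigma: float,
    seed: int,
    k: int,
    patch_cfg: PatchConfig,
    wavelet_cfg: WaveletConfig,
) -> Image:
    if name == "none":
        return noisy
    if name == "ica":
        return ica_denoise(noisy, patch_cfg, sigma=sigma, seed=seed)
    if name == "wavelet":
        cfg = WaveletConfig(
            wavelet_name=wavelet_cfg.wavelet_name,
            levels=wavelet_cfg.levels,
            threshold_rule=wavelet_cfg.threshold_rule,
            threshold_value=wavelet_cfg.threshold_value,
            mode=wavelet_cfg.mode,
            noise_sigma=sigma,
        )
        return wavelet_denoise(noisy, cfg)
    if name == "mean":
        return baselines.mean_filter(noisy, k)
    if name == "median":
        return baselines.median_filter(noisy, k)
    if name == "wiener":
        return baselines.wiener_filter(noisy, k, noise_var=sigma * sigma)
    raise ParameterError(f"unknown method {name!r}; choose from {METHODS}")


def run_sweep(
    methods: list[str],
    sigmas: list[float] | tuple[float, ...] | None = None,
    n_seeds: int = 3,
    base: PhantomSpec | None = None,
    seed: int = 0,
    k: int = 3,
    patch_cfg: PatchConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
) -> pd.DataFrame:
    """Run every (method, sigma, seed) cell and score against the clean phantom.

    Fully deterministic given ``seed``: the noise field of cell (sigma_i,
    seed_j) and the ICA initialization each use a seed derived from
    ``(seed, i, j)``.  Returns a DataFrame with columns ``CSV_COLUMNS``
    sorted by (method, sigma, seed); an empty ``sigmas`` list yields an
    empty table.
    """
    for m in methods:
        if m not in METHODS:
            raise ParameterError(f"unknown method {m!r}; choose from {METHODS}")
    if n_seeds < 1:
        raise ParameterError(f"n_seeds must be >= 1, got {n_seeds}")
    sigmas = DEFAULT_SIGMAS if sigmas is None else tuple(sigmas)
    base = base or PhantomSpec(seed=seed)
    patch_cfg = patch_cfg or PatchConfig()
    wavelet_cfg = wavelet_cfg or WaveletConfig()

    clean = generate_phantom(base)
    rows = []
    for i, sigma in enumerate(sigmas):
        for j in range(n_seeds):
            noise_seed = _derive_seed(seed, i, j)
            noisy = degrade(clean, NoiseSpec("additive_gaussian", 0.0, float(sigma), noise_seed))
            for method in methods:
                fit_seed = _derive_seed(seed, i, j, METHODS.index(method))
                t0 = time.perf_counter()
                result = _apply_method(method, noisy, float(sigma), fit_seed, k, patch_cfg, wavelet_cfg)
                elapsed = time.perf_counter() - t0
                q = quality_report(clean, result)
                rows.append(
                    {
                        "method": method,
                        "sigma": float(sigma),
                        "seed": j,
                        "psnr": q.psnr,
                        "rmse": q.rmse,
                        "mse": q.mse,
                        "runtime_s": elapsed,
                    }
                )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df.sort_values(["method", "sigma", "seed"], ignore_index=True)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(method, sigma) mean and sd of PSNR and RMSE over seeds.

    Population sd (ddof=0): a single seed reports sd 0, not NaN.
    """
    if len(table) == 0:
        raise EmptyInputError("cannot summarize an empty benchmark table")
    grouped = table.groupby(["method", "sigma"], sort=True)
    out = grouped.agg(
        psnr_mean=("psnr", "mean"),
        psnr_sd=("psnr", lambda s: float(np.std(s, ddof=0))),
        rmse_mean=("rmse", "mean"),
        rmse_sd=("rmse", lambda s: float(np.std(s, ddof=0))),
        n=("seed", "size"),
    )
    return out.reset_index()


def write_csv(table: pd.DataFrame, path) -> None:
    """Write the benchmark table with the exact canonical column order."""
    table.loc[:, CSV_COLUMNS].to_csv(path, index=False)


def plot_sweep(table: pd.DataFrame, path) -> None:
    """PSNR-vs-sigma curve per method (mean over seeds), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize(table)
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in summary.groupby("method"):
        ax.errorbar(grp["sigma"], grp["psnr_mean"], yerr=grp["psnr_sd"], marker="o", label=method)
    ax.set_xlabel("noise sigma (gray levels)")
    ax.set_ylabel("PSNR (dB)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
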