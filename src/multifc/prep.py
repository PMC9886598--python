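"""Post-estimation cleaning of BOLD runs.

The steps applied after motion estimation and denoising-component
extraction (which are upstream of this package): nuisance regression
against motion-artifact components and mean WM/CSF signals, hard FFT
band-pass filtering to 0.01-0.1 Hz, Gaussian spatial smoothing, and map
z-standardization.  Regression and filtering are applied sequentially
(regression first).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoldRun

__all__ = ["regress_confounds", "bandpass", "smooth_gaussian", "zscore_map", "clean_run"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


def _design_matrix(confounds: np.ndarray, n_volumes: int) -> np.ndarray:
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != n_volumes:
        raise ValueError(
            f"confound table has {confounds.shape[0]} rows but the run has "
            f"{n_volumes} volumes"
        )
    if not np.isfinite(confounds).all():
        raise ValueError("confound matrix contains non-finite values")
    design = np.column_stack([np.ones(n_volumes), confounds])
    # drop collinear columns (keep first of any dependent set)
    keep = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return design[:, keep]


def regress_confounds(run: BoldRun, confounds: np.ndarray | pd.DataFrame | None = None) -> BoldRun:
    """Replace every voxel series by its least-squares residual against
    [intercept | confounds], with the voxel temporal mean re-added."""
    if confounds is None:
        confounds = run.confounds
    if isinstance(confounds, pd.DataFrame):
        confounds = confounds.to_numpy(dtype=float)
    design = _design_matrix(confounds, run.n_volumes)
    mask = run.brain_mask
    series = run.data[mask]  # (N, T)
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    resid = series - (design @ beta).T
    resid += series.mean(axis=1, keepdims=True)
    data = run.data.copy()
    data[mask] = resid
    return replace(run, data=data)


def bandpass(
    x: np.ndarray,
    low: float = 0.01,
    high: float = 0.1,
    tr: float | None = None,
) -> np.ndarray:
    """Hard frequency-domain band-pass along the last axis.

    Retains FFT bins with ``low <= f <= high`` (the DC bin is always
    removed); length is preserved.  ``tr`` is the sampling interval in
    seconds.
    """
    if tr is None or tr <= 0:
        raise ValueError("tr (seconds) must be provided and positive")
    nyquist = 1.0 / (2.0 * tr)
    if high >= nyquist:
        raise ValueError(
            f"upper band edge {high} Hz must lie below the Nyquist frequency "
            f"{nyquist:.4g} Hz at TR={tr} s"
        )
    if low >= high:
        raise ValueError("low must be < high")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def bandpass_run(run: BoldRun, low: float = 0.01, high: float = 0.1) -> BoldRun:
    """Band-pass every in-mask voxel series of a run (means are removed
    with the DC bin)."""
    data = run.data.copy()
    mask = run.brain_mask
    data[mask] = bandpass(data[mask], low=low, high=high, tr=run.tr)
    data[~mask] = 0.0
    return replace(run, data=data)


def smooth_gaussian(
    volume: np.ndarray,
    fwhm: float = 4.5,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Separable Gaussian smoothing with a kernel of ``fwhm`` mm.

    With a mask, values outside are treated as missing and the result is
    renormalized by the smoothed mask so edge voxels average only over
    in-mask neighbors.  ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm == 0:
        return volume.copy()
    sigmas = [fwhm / (_FWHM_TO_SIGMA * d) for d in voxel_size]
    if mask is None:
        return ndimage.gaussian_filter(volume, sigmas, mode="constant")
    m = mask.astype(float)
    num = ndimage.gaussian_filter(volume * m, sigmas, mode="constant")
    den = ndimage.gaussian_filter(m, sigmas, mode="constant")
    out = np.zeros_like(volume)
    inside = mask.astype(bool) & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def zscore_map(
    volume: np.ndarray,
    standardization_mask: np.ndarray,
    value_mask: np.ndarray | None = None,
) -> np.ndarray:
    """(map - mean) / sd with moments taken over ``standardization_mask``;
    values returned inside ``value_mask`` (defaults to the standardization
    mask), zero elsewhere."""
    volume = np.asarray(volume, dtype=float)
    vals = volume[standardization_mask]
    if vals.size < 2:
        raise ValueError("standardization mask needs at least 2 voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance over the standardization mask; z map undefined")
    z = np.zeros_like(volume)
    out_mask = standardization_mask if value_mask is None else value_mask
    z[out_mask] = (volume[out_mask] - vals.mean()) / sd
    return z


def clean_run(
    run: BoldRun,
    low: float = 0.01,
    high: float = 0.1,
    confounds: np.ndarray | pd.DataFrame | None = None,
) -> BoldRun:
    """Confound regression followed by band-pass filtering."""
    return bandpass_run(regress_confounds(run, confounds), low=low, high=high)
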