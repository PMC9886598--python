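"""Raw-data image quality metrics for 4D BOLD runs.

Four metrics computed on the raw (un-preprocessed) data:

* tSNR — per-voxel temporal mean over temporal sample sd, summarized by the
  in-mask median;
* FWHM — intrinsic spatial smoothness from the lag-1 spatial
  autocorrelation under a Gaussian autocorrelation model;
* standardized DVARS — RMS of the volume-to-volume intensity change,
  normalized so the metric is invariant to affine intensity rescaling;
* FD — Power-style framewise displacement from the rigid-body motion
  trace, rotations converted to mm on a 50 mm sphere.

Runs with mean FD above 0.25 mm are flagged as high-motion and excluded
from downstream feature analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import BoldRun

__all__ = [
    "IqmRecord",
    "compute_tsnr",
    "compute_fd",
    "compute_dvars",
    "estimate_fwhm",
    "flag_high_motion",
    "compute_iqm",
    "FD_EXCLUSION_MM",
    "ROTATION_RADIUS_MM",
]

FD_EXCLUSION_MM = 0.25
ROTATION_RADIUS_MM = 50.0
_LN2 = np.log(2.0)


@dataclass
class IqmRecord:
    """The four quality metrics for one run plus the exclusion flag."""

    subject_id: str
    site_id: str
    tsnr_median: float
    fwhm_mean: float
    dvars_mean: float
    fd_mean: float
    high_motion: bool

    def to_dict(self) -> dict:
        return asdict(self)


def compute_tsnr(run: BoldRun) -> tuple[np.ndarray, float]:
    """Per-voxel tSNR map (zero where temporally constant) and the median
    over in-mask voxels with nonzero temporal variance."""
    if run.n_volumes < 2:
        raise ValueError("tSNR needs at least 2 volumes")
    mask = run.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    series = run.data[mask]
    mean = series.mean(axis=1)
    sd = series.std(axis=1, ddof=1)
    valid = sd > 0
    if not valid.any():
        raise ValueError("all in-mask voxels are temporally constant; tSNR undefined")
    tsnr = np.zeros(sd.shape)
    tsnr[valid] = mean[valid] / sd[valid]
    tsnr_map = np.zeros(mask.shape)
    tsnr_map[mask] = tsnr
    return tsnr_map, float(np.median(tsnr[valid]))


def compute_fd(motion: np.ndarray) -> tuple[np.ndarray, float]:
    """Framewise displacement series and its mean.

    FD(t) = sum |d translation_i| + 50 * sum |d rotation_j| for t >= 2;
    the first frame is 0 by convention and excluded from the mean.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 volumes")
    if not np.isfinite(motion).all():
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    series = np.concatenate([[0.0], fd])
    return series, float(fd.mean())


def compute_dvars(run: BoldRun) -> tuple[np.ndarray, float]:
    """Standardized DVARS series (t = 2..T) and its mean.

    Raw DVARS(t) is the RMS over in-mask voxels of the backward temporal
    difference; it is divided by the RMS of the per-voxel difference-series
    sample sds, which makes the result exactly invariant to affine
    intensity rescaling of the data.
    """
    if run.n_volumes < 2:
        raise ValueError("DVARS needs at least 2 volumes")
    mask = run.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    diffs = np.diff(run.data[mask], axis=1)
    raw = np.sqrt((diffs**2).mean(axis=0))
    if diffs.shape[1] >= 2:
        voxel_sd = diffs.std(axis=1, ddof=1)
        scale = np.sqrt((voxel_sd**2).mean())
    else:
        scale = np.sqrt((diffs**2).mean())
    if scale == 0:
        raise ValueError("temporally constant data; standardized DVARS undefined")
    series = raw / scale
    return series, float(series.mean())


def estimate_fwhm(run: BoldRun) -> float:
    """Mean intrinsic spatial smoothness (mm) across volumes.

    After removing each voxel's temporal mean, the lag-1 spatial
    autocorrelation along axis k is estimated as
    ``rho_k = 1 - s2_diff_k / (2 s2)`` from in-mask first differences; under
    a Gaussian spatial autocorrelation, ``FWHM_k = delta_k *
    sqrt(-2 ln 2 / ln rho_k)``.  Axes with rho outside (0, 1) are skipped;
    the per-volume FWHM is the geometric mean of the available axes and the
    result averages over volumes.
    """
    if run.n_volumes < 2:
        raise ValueError("FWHM estimation needs at least 2 volumes")
    mask = run.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    data = run.data
    resid = data - data.mean(axis=-1, keepdims=True)

    vals = resid[mask]  # (N, T)
    s2 = vals.var(axis=0, ddof=1)
    if not np.any(s2 > 0):
        raise ValueError("spatially constant volumes; FWHM undefined")

    log_fwhm_sum = np.zeros(run.n_volumes)
    n_axes = np.zeros(run.n_volumes, dtype=int)
    for axis, delta in enumerate(run.voxel_size):
        # voxel pairs (i, i+1) along this axis with both voxels in-mask
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        if pair.sum() < 2:
            continue
        d = resid[tuple(sl_hi)][pair] - resid[tuple(sl_lo)][pair]  # (Npairs, T)
        s2_diff = d.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = 1.0 - s2_diff / (2.0 * s2)
            ok = (s2 > 0) & (rho > 0) & (rho < 1)
            fwhm_axis = delta * np.sqrt(-2.0 * _LN2 / np.log(rho))
        log_fwhm_sum[ok] += np.log(fwhm_axis[ok])
        n_axes[ok] += 1

    valid = n_axes > 0
    if not valid.any():
        raise ValueError("no volume yields a valid smoothness estimate")
    per_volume = np.exp(log_fwhm_sum[valid] / n_axes[valid])
    return float(per_volume.mean())


def flag_high_motion(fd_mean: float, threshold: float = FD_EXCLUSION_MM) -> bool:
    """True iff mean FD strictly exceeds the exclusion threshold (mm);
    a run at exactly the threshold is retained."""
    return bool(fd_mean > threshold)


def compute_iqm(run: BoldRun, fd_threshold: float = FD_EXCLUSION_MM) -> IqmRecord:
    """All four metrics plus the high-motion flag for one run."""
    _, tsnr_median = compute_tsnr(run)
    _, fd_mean = compute_fd(run.motion)
    _, dvars_mean = compute_dvars(run)
    fwhm_mean = estimate_fwhm(run)
    return IqmRecord(
        subject_id=run.subject_id,
        site_id=run.site_id,
        tsnr_median=tsnr_median,
        fwhm_mean=fwhm_mean,
        dvars_mean=dvars_mean,
        fd_mean=fd_mean,
        high_motion=flag_high_motion(fd_mean, fd_threshold),
    )
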