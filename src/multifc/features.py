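"""Functional-connectivity and intrinsic-activity features.

Per subject: seven within-network functional connectivity values (mean of
the positive Fisher-z correlations between parcels of the same network)
and three whole-GM summaries of voxelwise maps — ALFF (spectral amplitude
in 0.01-0.1 Hz, computed before band-pass filtering), ReHo (Kendall's
coefficient of concordance with the 26 nearest neighbors), and weighted
degree centrality (sum of supra-threshold correlations, r > 0.25).  The
three maps are z-standardized, smoothed with a 4.5 mm Gaussian kernel and
averaged across the GM mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BoldRun, FEATURE_COLUMNS, NETWORK_NAMES, N_NETWORKS, PhantomAtlas
from .prep import clean_run, regress_confounds, smooth_gaussian, zscore_map

__all__ = [
    "ConnectivityMatrix",
    "parcel_timeseries",
    "connectivity_matrix",
    "network_fc",
    "alff_map",
    "reho_map",
    "dc_map",
    "global_mean",
    "extract_features",
]

R_CLIP = 1.0 - 1e-7
DC_THRESHOLD = 0.25


@dataclass
class ConnectivityMatrix:
    """P x P Fisher-z connectivity with parcel -> network labels.

    The diagonal is undefined and stored as NaN; off-diagonal correlations
    are clipped to +/-(1 - 1e-7) before the atanh transform so degenerate
    (perfectly correlated) parcels stay finite.
    """

    z_matrix: np.ndarray
    parcel_networks: dict[int, int]

    @property
    def n_parcels(self) -> int:
        return self.z_matrix.shape[0]


def parcel_timeseries(run: BoldRun, atlas: PhantomAtlas) -> np.ndarray:
    """Mean time series per parcel, rows ordered by parcel id (P x T)."""
    parcels = sorted(atlas.parcel_networks)
    out = np.empty((len(parcels), run.n_volumes))
    empty = []
    for i, p in enumerate(parcels):
        vox = (atlas.labels == p) & run.brain_mask
        if not vox.any():
            empty.append(p)
            continue
        out[i] = run.data[vox].mean(axis=0)
    if empty:
        raise ValueError(f"parcels with no in-mask voxels: {empty}")
    return out


def connectivity_matrix(ts: np.ndarray, parcel_networks: dict[int, int]) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of parcel series, Fisher z-transformed."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlations")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance parcel series at rows {bad}")
    r = np.corrcoef(ts)
    r = (r + r.T) / 2.0  # exact symmetry despite floating-point round-off
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z_matrix=z, parcel_networks=dict(parcel_networks))


def network_fc(cm: ConnectivityMatrix) -> dict[str, float]:
    """Mean of strictly positive within-network Fisher-z values per network
    (unique upper-triangle pairs).  A network whose within-network edges
    are all non-positive gets NaN with a warning."""
    parcels = sorted(cm.parcel_networks)
    index = {p: i for i, p in enumerate(parcels)}
    values: dict[str, float] = {}
    for k in range(1, N_NETWORKS + 1):
        members = [p for p in parcels if cm.parcel_networks[p] == k]
        edges = [
            cm.z_matrix[index[a], index[b]]
            for a, b in itertools.combinations(members, 2)
        ]
        if not edges:
            raise ValueError(f"network {k} has no within-network edge")
        pos = [z for z in edges if z > 0]
        name = f"fc_{NETWORK_NAMES[k - 1]}"
        if not pos:
            warnings.warn(
                f"network {NETWORK_NAMES[k - 1]} has no positive within-network "
                "edge; feature flagged missing"
            )
            values[name] = float("nan")
        else:
            values[name] = float(np.mean(pos))
    return values


def alff_map(
    run: BoldRun,
    low: float = 0.01,
    high: float = 0.1,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Amplitude of low-frequency fluctuations per voxel.

    Mean of the single-sided FFT amplitudes ``2 |X_k| / T`` over bins with
    ``low <= f_k <= high``; computed on confound-regressed data *before*
    band-pass filtering.  Linear in signal amplitude.
    """
    if run.n_volumes < 20:
        raise ValueError("ALFF needs at least 20 volumes")
    mask = run.brain_mask if mask is None else mask
    freqs = np.fft.rfftfreq(run.n_volumes, d=run.tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ValueError(
            f"band [{low}, {high}] Hz contains no FFT bin at "
            f"T={run.n_volumes}, TR={run.tr}"
        )
    series = run.data[mask]
    amp = 2.0 * np.abs(np.fft.rfft(series, axis=1)[:, keep]) / run.n_volumes
    out = np.zeros(mask.shape)
    out[mask] = amp.mean(axis=1)
    return out


def _neighborhood_offsets() -> list[tuple[int, int, int]]:
    return [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]


def reho_map(run: BoldRun, mask: np.ndarray | None = None) -> np.ndarray:
    """Regional homogeneity: Kendall's coefficient of concordance W of each
    voxel with its (up to) 26 in-mask neighbors.

    W = 12 sum_t (R_t - Rbar)^2 / (K^2 (T^3 - T)) with R_t the sum over the
    K neighborhood series of their within-series ranks at time t; no tie
    correction.  Edge voxels use the neighbors they have (K >= 2 required,
    else the voxel is NaN).
    """
    if run.n_volumes < 3:
        raise ValueError("ReHo needs at least 3 time points")
    mask = run.brain_mask if mask is None else mask
    T = run.n_volumes
    ranks = np.zeros(mask.shape + (T,))
    ranks[mask] = stats.rankdata(run.data[mask], axis=1)

    rank_sum = np.zeros(mask.shape + (T,))
    count = np.zeros(mask.shape, dtype=int)
    m = mask.astype(float)
    for dx, dy, dz in _neighborhood_offsets():
        shifted = np.roll(np.roll(np.roll(ranks, dx, 0), dy, 1), dz, 2)
        shifted_m = np.roll(np.roll(np.roll(m, dx, 0), dy, 1), dz, 2)
        # zero out wrap-around
        for axis, d in ((0, dx), (1, dy), (2, dz)):
            if d == 0:
                continue
            sl = [slice(None)] * 3
            sl[axis] = slice(0, d) if d > 0 else slice(d, None)
            shifted[tuple(sl)] = 0.0
            shifted_m[tuple(sl)] = 0.0
        rank_sum += shifted
        count += shifted_m.astype(int)

    out = np.full(mask.shape, np.nan)
    K = count[mask]
    R = rank_sum[mask]  # (N, T)
    Rbar = R.mean(axis=1, keepdims=True)
    ss = ((R - Rbar) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * ss / (K**2 * (T**3 - T))
    w[K < 2] = np.nan
    out[mask] = w
    return out


def dc_map(
    run: BoldRun,
    mask: np.ndarray | None = None,
    r_threshold: float = DC_THRESHOLD,
) -> np.ndarray:
    """Weighted degree centrality: per in-mask voxel, the sum of Pearson
    correlations with every other in-mask voxel that exceed
    ``r_threshold`` (self excluded).  Zero-variance voxels are dropped from
    both roles with a warning and reported as 0."""
    mask = run.brain_mask if mask is None else mask
    if run.n_volumes < 3:
        raise ValueError("degree centrality needs at least 3 time points")
    series = run.data[mask]
    if series.shape[0] < 2:
        raise ValueError("degree centrality needs at least 2 in-mask voxels")
    sd = series.std(axis=1)
    valid = sd > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} zero-variance voxels excluded from degree centrality"
        )
    z = series[valid]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    r = (z @ z.T) / z.shape[1]
    np.fill_diagonal(r, 0.0)
    weights = np.where(r > r_threshold, r, 0.0)
    dc = weights.sum(axis=1)
    vals = np.zeros(series.shape[0])
    vals[valid] = dc
    out = np.zeros(mask.shape)
    out[mask] = vals
    return out


def global_mean(
    volume: np.ndarray,
    standardization_mask: np.ndarray,
    gm_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    smooth_fwhm: float = 4.5,
) -> float:
    """Whole-GM summary of a voxelwise map: z-standardize over
    ``standardization_mask``, smooth with a Gaussian kernel, then average
    over the GM mask."""
    if not gm_mask.any():
        raise ValueError("empty GM mask")
    z = zscore_map(volume, standardization_mask)
    sm = smooth_gaussian(z, smooth_fwhm, voxel_size, mask=standardization_mask)
    return float(sm[gm_mask].mean())


def extract_features(
    run: BoldRun,
    atlas: PhantomAtlas,
    low: float = 0.01,
    high: float = 0.1,
    smooth_fwhm: float = 4.5,
    dc_threshold: float = DC_THRESHOLD,
) -> dict[str, float]:
    """The full ten-feature vector for one run.

    Confound regression first; ALFF is computed before band-pass filtering,
    everything else on the band-passed data.  Returns a dict keyed by
    ``FEATURE_COLUMNS``.
    """
    regressed = regress_confounds(run)
    alff = alff_map(regressed, low=low, high=high)
    cleaned = clean_run(run, low=low, high=high)
    ts = parcel_timeseries(cleaned, atlas)
    cm = connectivity_matrix(ts, atlas.parcel_networks)
    values = network_fc(cm)
    # maps over the whole analysis (brain) mask, standardized there,
    # averaged over GM — distinct supports keep the global means informative
    reho = reho_map(cleaned, mask=run.brain_mask)
    reho = np.nan_to_num(reho, nan=0.0)
    dc = dc_map(cleaned, mask=run.brain_mask, r_threshold=dc_threshold)
    for name, vol in (("alff_global", alff), ("reho_global", reho), ("dc_global", dc)):
        values[name] = global_mean(
            vol, run.brain_mask, run.gm_mask, run.voxel_size, smooth_fwhm
        )
    return {c: values[c] for c in FEATURE_COLUMNS}
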