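"""Synthetic multi-site BOLD phantom with analytically known structure.

The generator builds cohorts whose ground truth is known exactly, so every
downstream stage (quality metrics, connectivity features, harmonization,
statistics) can be tested without any external data:

* a toy parcellation of 7 networks with ``parcels_per_network`` parcels
  each, plus WM and CSF slabs;
* per-voxel signals ``sqrt(c_k) * s_k(t) + sqrt(1 - c_k) * eta_p(t)`` where
  ``s_k`` is a band-limited (0.01-0.1 Hz) unit-variance network signal and
  ``eta_p`` a band-limited unit-variance parcel noise shared by the voxels
  of parcel p.  Two same-network voxels in different parcels (and the
  parcel-mean series themselves) then have expected Pearson correlation
  exactly ``c_k``, and the identity survives band-pass filtering because
  signal and noise live in the same band;
* per-site gain/offset/thermal-noise, a six-parameter random-walk motion
  trace, and shared WM/CSF nuisance signals recorded in the confound table;
* feature-level site effects (``y -> scale * y + shift``), applied by
  :func:`inject_site_effects` to feature tables rather than to voxels, so
  they realize exactly the location/scale model ComBat assumes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    BoldRun,
    FEATURE_COLUMNS,
    N_NETWORKS,
    PhantomAtlas,
    SiteSpec,
    SubjectSpec,
)

__all__ = [
    "make_atlas",
    "simulate_run",
    "simulate_cohort",
    "make_subjects",
    "default_sites",
    "inject_site_effects",
    "simulate_feature_table",
    "bandlimited_noise",
]

_BAND = (0.01, 0.1)  # Hz; the spontaneous-activity band the analysis assumes


def bandlimited_noise(
    rng: np.random.Generator,
    n_series: int,
    n_volumes: int,
    tr: float,
    band: tuple[float, float] = _BAND,
) -> np.ndarray:
    """Gaussian white noise hard-band-passed to ``band`` and rescaled to
    unit sample variance, one series per row."""
    low, high = band
    white = rng.standard_normal((n_series, n_volumes))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise ValueError(
            f"band {band} Hz contains no frequency bin at T={n_volumes}, TR={tr}"
        )
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_volumes, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    return out / sd


def make_atlas(
    grid_shape: tuple[int, int, int] = (24, 24, 12),
    parcels_per_network: int = 14,
    parcel_extent: int = 8,
) -> PhantomAtlas:
    """Deterministically place ``7 * parcels_per_network`` disjoint parcels
    plus WM and CSF slabs on a regular grid.

    Parcels are compact bricks of ``parcel_extent`` voxels tiled through the
    gray-matter region (all z-slices except the last two); the penultimate
    slice is WM and the last slice CSF.  Networks own consecutive blocks of
    parcels: parcel p belongs to network ``(p - 1) // parcels_per_network + 1``.
    """
    if parcels_per_network < 2:
        raise ValueError(
            "parcels_per_network must be >= 2: with a single parcel per "
            "network no within-network edge exists"
        )
    if parcel_extent < 1:
        raise ValueError("parcel_extent must be >= 1")
    nx, ny, nz = grid_shape
    if nz < 3:
        raise ValueError("grid needs at least 3 z-slices (GM + WM + CSF)")
    n_parcels = N_NETWORKS * parcels_per_network
    side = max(1, math.ceil(parcel_extent ** (1 / 3)))

    labels = np.zeros(grid_shape, dtype=np.int32)
    gm_z = nz - 2  # z in [0, gm_z) is gray matter territory
    bricks = []
    for z0 in range(0, gm_z - side + 1, side):
        for y0 in range(0, ny - side + 1, side):
            for x0 in range(0, nx - side + 1, side):
                bricks.append((x0, y0, z0))
    if len(bricks) < n_parcels:
        raise ValueError(
            f"grid {grid_shape} too small: {len(bricks)} parcel slots available "
            f"but {n_parcels} parcels requested ({n_parcels - len(bricks)} short)"
        )

    for p in range(1, n_parcels + 1):
        x0, y0, z0 = bricks[p - 1]
        placed = 0
        for dz in range(side):
            for dy in range(side):
                for dx in range(side):
                    if placed == parcel_extent:
                        break
                    labels[x0 + dx, y0 + dy, z0 + dz] = p
                    placed += 1

    gm = labels > 0
    wm = np.zeros(grid_shape, dtype=bool)
    csf = np.zeros(grid_shape, dtype=bool)
    wm[:, :, nz - 2] = True
    csf[:, :, nz - 1] = True
    brain = gm | wm | csf
    parcel_networks = {
        p: (p - 1) // parcels_per_network + 1 for p in range(1, n_parcels + 1)
    }
    atlas = PhantomAtlas(
        labels=labels,
        parcel_networks=parcel_networks,
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
    )
    atlas.validate()
    return atlas


def simulate_run(
    site: SiteSpec,
    subject: SubjectSpec,
    atlas: PhantomAtlas,
    seed: int,
) -> BoldRun:
    """Simulate one subject's 4D BOLD run under the phantom signal model."""
    rng = np.random.default_rng(seed)
    T = site.n_volumes
    c = subject.effective_coupling()

    net_signals = bandlimited_noise(rng, N_NETWORKS, T, site.tr)
    parcel_noise = bandlimited_noise(rng, atlas.n_parcels, T, site.tr)
    wm_signal = rng.standard_normal(T)
    csf_signal = rng.standard_normal(T)
    wm_voxel_noise_sd = 0.5

    shape = atlas.labels.shape
    data = np.zeros(shape + (T,), dtype=np.float64)
    for p, k in atlas.parcel_networks.items():
        ck = c[k - 1]
        series = math.sqrt(ck) * net_signals[k - 1] + math.sqrt(1.0 - ck) * parcel_noise[p - 1]
        data[atlas.labels == p] = series

    n_wm = int(atlas.wm_mask.sum())
    n_csf = int(atlas.csf_mask.sum())
    data[atlas.wm_mask] = wm_signal + wm_voxel_noise_sd * rng.standard_normal((n_wm, T))
    data[atlas.csf_mask] = csf_signal + wm_voxel_noise_sd * rng.standard_normal((n_csf, T))

    brain = atlas.brain_mask
    data[brain] = site.gain * data[brain] + site.offset
    if site.noise_sd > 0:
        data[brain] += site.noise_sd * rng.standard_normal((int(brain.sum()), T))

    # 6-parameter random walk: translations in mm, rotations in rad with
    # step sd motion_sd / 50 so a 50 mm lever arm contributes comparably.
    steps = np.empty((T, 6))
    steps[:, :3] = rng.normal(0.0, site.motion_sd, (T, 3))
    steps[:, 3:] = rng.normal(0.0, site.motion_sd / 50.0, (T, 3))
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)

    confounds = pd.DataFrame(
        {
            "wm_mean": data[atlas.wm_mask].mean(axis=0),
            "csf_mean": data[atlas.csf_mask].mean(axis=0),
        }
    )

    run = BoldRun(
        subject_id=subject.subject_id,
        site_id=site.site_id,
        group=subject.group,
        age=subject.age,
        sex=subject.sex,
        tr=site.tr,
        voxel_size=tuple(site.voxel_size),
        data=data,
        brain_mask=brain,
        gm_mask=atlas.gm_mask,
        wm_mask=atlas.wm_mask,
        csf_mask=atlas.csf_mask,
        motion=motion,
        confounds=confounds,
    )
    run.validate()
    return run


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    sites: list[SiteSpec],
    subjects: list[SubjectSpec],
    atlas: PhantomAtlas,
    seed: int,
) -> tuple[list[BoldRun], pd.DataFrame]:
    """One BOLD run per subject (derived per-subject seeds) plus the
    matching covariate table.

    Feature-level site effects are *not* applied here; they belong to
    :func:`inject_site_effects`, which acts on the extracted feature table.
    """
    site_map = {s.site_id: s for s in sites}
    runs = []
    rows = []
    for i, sub in enumerate(subjects):
        if sub.site_id not in site_map:
            raise KeyError(f"subject {sub.subject_id} references unknown site {sub.site_id!r}")
        run = simulate_run(site_map[sub.site_id], sub, atlas, _child_seed(seed, i))
        runs.append(run)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "site": sub.site_id,
                "group": sub.group,
                "age": sub.age,
                "sex": sub.sex,
            }
        )
    return runs, pd.DataFrame(rows)


def default_sites() -> list[SiteSpec]:
    """Four heterogeneous sites: two TRs (1.5/3.0 s), 140-240 volumes,
    different voxel sizes, gains/offsets/noise, and motion levels."""
    n_feat = len(FEATURE_COLUMNS)
    return [
        SiteSpec(
            "A", tr=3.0, n_volumes=200, voxel_size=(1.875, 1.875, 4.0),
            gain=12.0, offset=900.0, noise_sd=6.0, motion_sd=0.02,
            feature_shift=np.zeros(n_feat), feature_scale=np.ones(n_feat),
        ),
        SiteSpec(
            "B", tr=1.5, n_volumes=240, voxel_size=(4.0, 4.0, 4.0),
            gain=10.0, offset=1000.0, noise_sd=4.0, motion_sd=0.01,
            feature_shift=np.full(n_feat, 0.05), feature_scale=np.full(n_feat, 1.1),
        ),
        SiteSpec(
            "C", tr=3.0, n_volumes=140, voxel_size=(3.0, 3.0, 3.0),
            gain=12.0, offset=700.0, noise_sd=10.0, motion_sd=0.008,
            feature_shift=np.full(n_feat, -0.05), feature_scale=np.full(n_feat, 0.9),
        ),
        SiteSpec(
            "D", tr=3.0, n_volumes=200, voxel_size=(1.875, 1.875, 4.0),
            gain=11.0, offset=850.0, noise_sd=8.0, motion_sd=0.04,
            feature_shift=np.full(n_feat, 0.02), feature_scale=np.full(n_feat, 1.2),
        ),
    ]


def make_subjects(
    sites: list[SiteSpec],
    n_per_site: int,
    seed: int,
    patient_fraction: float = 0.5,
    coupling: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    group_delta: float = 0.05,
    affected_networks: tuple[int, ...] = (2, 5),
) -> list[SubjectSpec]:
    """Draw subject specs: age uniform 25-55 y, sex Bernoulli(0.5), the
    first ``round(patient_fraction * n)`` subjects per site are patients."""
    rng = np.random.default_rng(seed)
    subjects = []
    idx = 0
    for site in sites:
        n_pat = int(round(patient_fraction * n_per_site))
        for j in range(n_per_site):
            subjects.append(
                SubjectSpec(
                    subject_id=f"sub-{idx:04d}",
                    site_id=site.site_id,
                    group=1 if j < n_pat else 0,
                    age=float(rng.uniform(25.0, 55.0)),
                    sex=int(rng.integers(0, 2)),
                    coupling=coupling,
                    group_delta=group_delta,
                    affected_networks=affected_networks,
                )
            )
            idx += 1
    return subjects


def inject_site_effects(features: pd.DataFrame, sites: list[SiteSpec]) -> pd.DataFrame:
    """Apply each site's location/scale effect to the feature columns:
    ``y -> scale * y + shift``.

    The ground-truth shift/scale vectors are retained in
    ``result.attrs["site_effects"]`` so harmonization recovery can be
    checked against the exact truth.
    """
    out = features.copy()
    site_map = {s.site_id: s for s in sites}
    n_feat = len(FEATURE_COLUMNS)
    for s in site_map.values():
        if len(s.feature_shift) != n_feat or len(s.feature_scale) != n_feat:
            raise ValueError(
                f"site {s.site_id}: feature shift/scale must have length {n_feat}"
            )
    for site_id, idx in out.groupby("site").groups.items():
        if site_id not in site_map:
            raise KeyError(f"feature table references unknown site {site_id!r}")
        s = site_map[site_id]
        vals = out.loc[idx, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        out.loc[idx, list(FEATURE_COLUMNS)] = vals * s.feature_scale + s.feature_shift
    out.attrs["site_effects"] = {
        s.site_id: (s.feature_shift.copy(), s.feature_scale.copy()) for s in sites
    }
    return out


# Realistic baseline feature distributions for feature-level simulation:
# within-network Fisher-z means in the 0.2-0.4 range with sd 0.1, and
# z-standardized whole-GM map means near zero-plus with sd 0.08.
_FEATURE_MEANS = np.array(
    [0.35, 0.40, 0.30, 0.28, 0.22, 0.33, 0.38, 0.15, 0.12, 0.10]
)
_FEATURE_SDS = np.array([0.1] * 7 + [0.08] * 3)
_AGE_SLOPE = -0.002  # z-units per year, mild age-related FC decline
_SEX_SHIFT = 0.01


def simulate_feature_table(
    sites: list[SiteSpec],
    n_per_site: int | dict[str, int],
    seed: int,
    patient_fraction: float = 0.5,
    group_effect: dict[str, float] | None = None,
    feature_means: np.ndarray = _FEATURE_MEANS,
    feature_sds: np.ndarray = _FEATURE_SDS,
) -> pd.DataFrame:
    """Draw a subjects x features table directly at the feature level.

    This bypasses image simulation and realizes exactly the generative model
    ComBat assumes: ``y = mu + beta * x + group effect + noise`` per feature,
    then per-site location/scale effects via :func:`inject_site_effects`.
    ``group_effect`` maps feature names to the additive change in patients
    (default: -0.05 z-units on the somatomotor and limbic FC features).
    """
    if group_effect is None:
        group_effect = {"fc_somatomotor": -0.05, "fc_limbic": -0.05}
    delta = np.array([group_effect.get(c, 0.0) for c in FEATURE_COLUMNS])
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for site in sites:
        n = n_per_site if isinstance(n_per_site, int) else n_per_site[site.site_id]
        n_pat = int(round(patient_fraction * n))
        for j in range(n):
            group = 1 if j < n_pat else 0
            age = float(rng.uniform(25.0, 55.0))
            sex = int(rng.integers(0, 2))
            fd = float(abs(rng.normal(0.10 + 2.0 * site.motion_sd, 0.04)))
            y = (
                feature_means
                + _AGE_SLOPE * (age - 40.0)
                + _SEX_SHIFT * sex
                + delta * group
                + feature_sds * rng.standard_normal(len(FEATURE_COLUMNS))
            )
            row = {
                "subject_id": f"sub-{idx:04d}",
                "site": site.site_id,
                "group": group,
                "age": age,
                "sex": sex,
                "fd_mean": fd,
            }
            row.update(dict(zip(FEATURE_COLUMNS, y)))
            rows.append(row)
            idx += 1
    table = pd.DataFrame(rows)
    return inject_site_effects(table, sites)
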