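"""End-to-end orchestration: simulate -> QC -> clean -> features ->
harmonize -> statistics.

`run_pipeline` drives the whole analysis from a single config and writes
every intermediate table plus a provenance record, so that identical
config + seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import FEATURE_COLUMNS, validate_feature_table
from .features import extract_features
from .harmonize import harmonize_table
from .iqm import compute_iqm
from .io import json_report, tsv_write, write_atlas
from .phantom import default_sites, inject_site_effects, make_atlas, make_subjects, simulate_cohort
from .stats import (
    adjust_linear,
    correlation_screen,
    fligner_killeen,
    kruskal_wallis,
    wilcoxon_ranksum,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("multifc")


@dataclass
class PipelineConfig:
    """Every stated analysis constant in one place."""

    seed: int = 0
    fd_threshold: float = 0.25  # mm, mean-FD exclusion
    band: tuple[float, float] = (0.01, 0.1)  # Hz
    smooth_fwhm: float = 4.5  # mm
    dc_threshold: float = 0.25  # r
    combat: bool = True
    combat_covariates: tuple[str, ...] = ("age", "sex", "group")
    adjust_covariates: tuple[str, ...] = ("age", "sex", "fd_mean")
    # simulation settings
    n_per_site: int = 15
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    parcels_per_network: int = 14
    parcel_extent: int = 8
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.fd_threshold < 0:
            raise ValueError("fd_threshold must be >= 0")
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError("band must satisfy 0 <= low < high")
        if self.smooth_fwhm < 0 or self.dc_threshold < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "grid_shape", "combat_covariates", "adjust_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the full simulated multisite analysis into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    low, high = config.band

    t0 = _stage("simulate")
    sites = default_sites()
    for s in sites:
        if high >= 1.0 / (2.0 * s.tr):
            raise ValueError(f"band upper edge {high} Hz >= Nyquist for site {s.site_id}")
    atlas = make_atlas(config.grid_shape, config.parcels_per_network, config.parcel_extent)
    subjects = make_subjects(sites, config.n_per_site, seed=config.seed)
    runs, covariates = simulate_cohort(sites, subjects, atlas, seed=config.seed)
    if config.write_images:
        write_atlas(atlas, outdir / "atlas")
    tsv_write(outdir / "covariates.tsv", covariates)
    timings["simulate"] = time.perf_counter() - t0

    t0 = _stage("qc")
    records = []
    for run in runs:
        try:
            records.append(compute_iqm(run, config.fd_threshold))
        except ValueError as exc:
            raise RuntimeError(f"stage qc failed for subject {run.subject_id}: {exc}") from exc
    iqm_df = pd.DataFrame([r.to_dict() for r in records])
    tsv_write(outdir / "iqm.tsv", iqm_df)
    json_report(outdir / "iqm.json", {r.subject_id: r.to_dict() for r in records})
    exclusions = iqm_df[iqm_df["high_motion"]].copy()
    exclusions["reason"] = [
        f"mean FD {v:.3f} mm > {config.fd_threshold} mm" for v in exclusions["fd_mean"]
    ]
    tsv_write(outdir / "exclusions.tsv", exclusions[["subject_id", "site_id", "fd_mean", "reason"]])
    keep_ids = set(iqm_df.loc[~iqm_df["high_motion"], "subject_id"])
    if not keep_ids:
        raise RuntimeError("no subjects remain after the high-motion exclusion")
    runs = [r for r in runs if r.subject_id in keep_ids]
    timings["qc"] = time.perf_counter() - t0

    t0 = _stage("features")
    rows = []
    fd_map = dict(zip(iqm_df["subject_id"], iqm_df["fd_mean"]))
    dvars_map = dict(zip(iqm_df["subject_id"], iqm_df["dvars_mean"]))
    for run in runs:
        try:
            feats = extract_features(
                run, atlas, low=low, high=high,
                smooth_fwhm=config.smooth_fwhm, dc_threshold=config.dc_threshold,
            )
        except ValueError as exc:
            raise RuntimeError(
                f"stage features failed for subject {run.subject_id}: {exc}"
            ) from exc
        row = {
            "subject_id": run.subject_id,
            "site": run.site_id,
            "group": run.group,
            "age": run.age,
            "sex": run.sex,
            "fd_mean": fd_map[run.subject_id],
            "dvars_mean": dvars_map[run.subject_id],
        }
        row.update(feats)
        rows.append(row)
    features = pd.DataFrame(rows)
    features = inject_site_effects(features, sites)
    missing = features[list(FEATURE_COLUMNS)].isna().any(axis=1)
    if missing.any():
        dropped = features.loc[missing, "subject_id"].tolist()
        log.warning("dropping %d subjects with flagged-missing features: %s",
                    len(dropped), dropped)
        tsv_write(outdir / "missing_features.tsv", features.loc[missing, ["subject_id", "site"]])
        features = features.loc[~missing].reset_index(drop=True)
        if features.empty:
            raise RuntimeError("no subjects remain after dropping missing features")
    validate_feature_table(features)
    tsv_write(outdir / "features_raw.tsv", features)
    timings["features"] = time.perf_counter() - t0

    t0 = _stage("adjust")
    adjusted = adjust_linear(features, covariates=config.adjust_covariates)
    tsv_write(outdir / "features_adjusted.tsv", adjusted)
    timings["adjust"] = time.perf_counter() - t0

    harmonized_adj = None
    if config.combat:
        t0 = _stage("harmonize")
        harmonized, model = harmonize_table(features, covariates=config.combat_covariates)
        model.to_json(outdir / "combat_model.json")
        harmonized_adj = adjust_linear(harmonized, covariates=config.adjust_covariates)
        tsv_write(outdir / "features_harmonized.tsv", harmonized_adj)
        timings["harmonize"] = time.perf_counter() - t0

    t0 = _stage("stats")
    stats_dir = outdir / "stats"
    _site_battery(adjusted, stats_dir / "intersite_raw.tsv")
    _group_battery(adjusted, stats_dir / "group_raw.tsv")
    screen = correlation_screen(adjusted, metrics=("fd_mean", "dvars_mean"))
    tsv_write(stats_dir / "correlation_screen.tsv", screen)
    if harmonized_adj is not None:
        _site_battery(harmonized_adj, stats_dir / "intersite_harmonized.tsv")
        _group_battery(harmonized_adj, stats_dir / "group_harmonized.tsv")
    timings["stats"] = time.perf_counter() - t0

    json_report(
        outdir / "provenance.json",
        {
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "versions": _versions(),
            "timings_s": timings,
            "n_subjects": len(features),
            "n_excluded": int(len(exclusions)),
        },
    )
    log.info("pipeline complete: %s", outdir)
    return outdir


def _site_battery(features: pd.DataFrame, path) -> None:
    """Kruskal-Wallis across sites per feature, plus Fligner-Killeen on the
    control group only."""
    rows = []
    controls = features[features["group"] == 0]
    for feat in FEATURE_COLUMNS:
        groups = [g[feat].to_numpy(float) for _, g in features.groupby("site")]
        kw = kruskal_wallis(*groups)
        hc_groups = [g[feat].to_numpy(float) for _, g in controls.groupby("site")]
        fk = fligner_killeen(*hc_groups)
        rows.append(
            {
                "feature": feat,
                "kw_H": kw.statistic,
                "kw_p": kw.p_raw,
                "fk_stat": fk.statistic,
                "fk_p": fk.p_raw,
            }
        )
    tsv_write(path, pd.DataFrame(rows))


def _group_battery(features: pd.DataFrame, path) -> None:
    """Pooled patient-vs-control Wilcoxon rank-sum per feature."""
    rows = []
    pat = features[features["group"] == 1]
    hc = features[features["group"] == 0]
    for feat in FEATURE_COLUMNS:
        res = wilcoxon_ranksum(pat[feat].to_numpy(float), hc[feat].to_numpy(float))
        rows.append(
            {
                "feature": feat,
                "W": res.statistic,
                "p": res.p_raw,
                "median_diff": float(pat[feat].median() - hc[feat].median()),
            }
        )
    tsv_write(path, pd.DataFrame(rows))


def _versions() -> dict:
    import nibabel
    import scipy

    return {
        "multifc": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "python": sys.version.split()[0],
    }
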