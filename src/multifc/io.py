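"""Standard-format readers and writers (NIfTI, TSV, JSON).

All writers create parent directories.  NIfTI images use an affine of
``diag(voxel_size, 1)``; tables are tab-separated with a header row and
round-trip floating-point values exactly (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "nifti_write",
    "nifti_read",
    "tsv_write",
    "tsv_read",
    "json_report",
    "write_run",
    "write_atlas",
    "read_covariates",
]


def _ensure_parent(path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def nifti_write(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = _ensure_parent(path)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def nifti_read(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine)."""
    try:
        img = nib.load(str(path))
        return np.asarray(img.dataobj), img.affine
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc


def tsv_write(path, df: pd.DataFrame) -> Path:
    path = _ensure_parent(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def tsv_read(path, required_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read TSV file {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def json_report(path, payload: dict) -> Path:
    path = _ensure_parent(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_run(run, directory) -> None:
    """Write one BOLD run as NIfTI + motion/confound TSVs."""
    directory = Path(directory)
    nifti_write(directory / f"{run.subject_id}_bold.nii.gz", run.data, run.voxel_size)
    motion = pd.DataFrame(
        run.motion,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    tsv_write(directory / f"{run.subject_id}_motion.tsv", motion)
    tsv_write(directory / f"{run.subject_id}_confounds.tsv", run.confounds)


def write_atlas(atlas, directory, voxel_size=(1.0, 1.0, 1.0)) -> None:
    directory = Path(directory)
    nifti_write(directory / "atlas_labels.nii.gz", atlas.labels.astype(np.int16), voxel_size)
    for name, mask in (
        ("brain", atlas.brain_mask),
        ("gm", atlas.gm_mask),
        ("wm", atlas.wm_mask),
        ("csf", atlas.csf_mask),
    ):
        nifti_write(directory / f"mask_{name}.nii.gz", mask.astype(np.uint8), voxel_size)
    mapping = pd.DataFrame(
        sorted(atlas.parcel_networks.items()), columns=["parcel", "network"]
    )
    tsv_write(directory / "parcel_networks.tsv", mapping)


def read_covariates(path) -> pd.DataFrame:
    df = tsv_read(path, required_columns=("subject_id", "site", "group", "age", "sex"))
    if df.loc[:, ["subject_id", "site", "group", "age", "sex"]].isna().any().any():
        raise ValueError(f"{path}: covariate table has missing cells")
    return df
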