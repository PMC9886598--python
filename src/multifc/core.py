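"""Shared containers for multisite resting-state fMRI analysis.

The package operates on single-subject 4D BOLD runs together with the
tissue masks, a cortical parcellation grouped into seven large-scale
networks, rigid-body motion traces, and nuisance-regressor tables.  The
containers below are deliberately thin: plain numpy arrays on a single
native voxel grid, plus pandas tables for anything tabular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical seven-network ordering (Yeo-style large-scale networks).
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsalattention",
    "ventralattention",
    "limbic",
    "frontoparietal",
    "default",
)

N_NETWORKS = len(NETWORK_NAMES)

#: Within-network FC features, one per large-scale network (Fisher-z units).
FC_COLUMNS = tuple(f"fc_{name}" for name in NETWORK_NAMES)

#: Whole-GM summaries of the three voxelwise activity/connectivity maps.
GLOBAL_COLUMNS = ("alff_global", "reho_global", "dc_global")

#: The ten features every downstream stage (ComBat, statistics) consumes.
FEATURE_COLUMNS = FC_COLUMNS + GLOBAL_COLUMNS

#: Covariate columns expected in every feature table.
COVARIATE_COLUMNS = ("subject_id", "site", "group", "age", "sex", "fd_mean")


@dataclass
class PhantomAtlas:
    """Integer parcellation plus tissue masks on one voxel grid.

    ``labels`` holds 0 for background and 1..P for parcels; every parcel
    belongs to exactly one of the seven networks via ``parcel_networks``
    (values 1..7).  GM is the union of the parcels; WM and CSF are disjoint
    nuisance compartments inside the brain mask.
    """

    labels: np.ndarray
    parcel_networks: dict[int, int]
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_networks)

    def parcels_of_network(self, network: int) -> list[int]:
        return [p for p, k in self.parcel_networks.items() if k == network]

    def validate(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        lab = np.unique(self.labels)
        lab = lab[lab > 0]
        if set(lab.tolist()) != set(self.parcel_networks):
            raise ValueError("label volume and parcel->network map disagree")
        if np.any(self.gm_mask & self.wm_mask) or np.any(self.gm_mask & self.csf_mask) or np.any(self.wm_mask & self.csf_mask):
            raise ValueError("GM/WM/CSF masks must be disjoint")
        for m in (self.gm_mask, self.wm_mask, self.csf_mask):
            if np.any(m & ~self.brain_mask):
                raise ValueError("tissue masks must lie inside the brain mask")
        if np.any((self.labels > 0) & ~self.gm_mask):
            raise ValueError("every parcel must lie inside GM")
        counts = pd.Series(list(self.parcel_networks.values())).value_counts()
        if (counts < 2).any():
            raise ValueError("every network needs >= 2 parcels for within-network edges")


@dataclass
class BoldRun:
    """One subject's 4D BOLD run plus everything needed to analyse it."""

    subject_id: str
    site_id: str
    group: int  # 0 = control, 1 = patient
    age: float
    sex: int  # 0 = F, 1 = M
    tr: float  # seconds
    voxel_size: tuple[float, float, float]  # mm
    data: np.ndarray  # (X, Y, Z, T)
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    motion: np.ndarray  # (T, 6): 3 translations mm, 3 rotations rad
    confounds: pd.DataFrame  # one row per volume

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def validate(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (X, Y, Z, T)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.motion.shape != (self.n_volumes, 6):
            raise ValueError("motion trace must be (T, 6)")
        if len(self.confounds) != self.n_volumes:
            raise ValueError("confound table must have one row per volume")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")


@dataclass
class SiteSpec:
    """Acquisition and site-effect description for one scanning site."""

    site_id: str
    tr: float  # seconds
    n_volumes: int
    voxel_size: tuple[float, float, float]  # mm
    gain: float = 10.0  # multiplicative signal scale
    offset: float = 800.0  # additive baseline, signal units
    noise_sd: float = 5.0  # thermal noise sd, signal units
    motion_sd: float = 0.02  # random-walk step sd, mm
    feature_shift: np.ndarray = field(
        default_factory=lambda: np.zeros(len(FEATURE_COLUMNS))
    )
    feature_scale: np.ndarray = field(
        default_factory=lambda: np.ones(len(FEATURE_COLUMNS))
    )

    def __post_init__(self) -> None:
        self.feature_shift = np.asarray(self.feature_shift, dtype=float)
        self.feature_scale = np.asarray(self.feature_scale, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.feature_scale <= 0):
            raise ValueError("feature_scale must be > 0 elementwise")


@dataclass
class SubjectSpec:
    """Identity, covariates, and coupling parameters for one phantom subject.

    ``coupling`` holds the within-network coupling c per network (the
    expected Pearson correlation between same-network time series);
    ``group_delta`` is subtracted from c in ``affected_networks`` when the
    subject is a patient (group = 1).
    """

    subject_id: str
    site_id: str
    group: int  # 0 = control, 1 = patient
    age: float
    sex: int  # 0 = F, 1 = M
    coupling: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    group_delta: float = 0.05
    affected_networks: tuple[int, ...] = (2, 5)  # somatomotor, limbic

    def effective_coupling(self) -> np.ndarray:
        c = np.asarray(self.coupling, dtype=float).copy()
        if self.group:
            for k in self.affected_networks:
                c[k - 1] -= self.group_delta
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError(
                "effective coupling must stay in [0, 1]; got "
                f"{np.round(c, 4).tolist()} for subject {self.subject_id}"
            )
        return c

    def __post_init__(self) -> None:
        if len(self.coupling) != N_NETWORKS:
            raise ValueError(f"coupling needs {N_NETWORKS} entries")
        if self.group not in (0, 1):
            raise ValueError("group must be 0 (control) or 1 (patient)")
        self.effective_coupling()  # validates the invariant


def validate_feature_table(df: pd.DataFrame) -> None:
    """Check that a feature table carries covariates and the ten features."""
    missing = [c for c in COVARIATE_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    cov = df.loc[:, list(COVARIATE_COLUMNS)]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"feature table has missing covariate values in: {bad}")
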