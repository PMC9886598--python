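import numpy as np
import pandas as pd
import pytest

from multifc.core import BoldRun, SiteSpec, SubjectSpec
from multifc.phantom import make_atlas, simulate_run


@pytest.fixture(scope="session")
def small_atlas():
    """14 parcels (2 per network) of 8 voxels on a 16x16x12 grid."""
    return make_atlas((16, 16, 12), parcels_per_network=2, parcel_extent=8)


@pytest.fixture(scope="session")
def quiet_site():
    """A site with no thermal noise and no gain/offset distortion."""
    return SiteSpec("Q", tr=3.0, n_volumes=200, voxel_size=(3.0, 3.0, 3.0),
                    gain=1.0, offset=0.0, noise_sd=0.0, motion_sd=0.01)


@pytest.fixture(scope="session")
def demo_subject():
    return SubjectSpec("sub-demo", "Q", group=0, age=40.0, sex=0,
                       coupling=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8))


@pytest.fixture(scope="session")
def demo_run(small_atlas, quiet_site, demo_subject):
    return simulate_run(quiet_site, demo_subject, small_atlas, seed=7)


def run_from_array(data, tr=2.0, voxel_size=(2.0, 2.0, 2.0), mask=None):
    """Wrap a bare 4D array as a BoldRun for metric-level tests."""
    data = np.asarray(data, dtype=float)
    shape = data.shape[:3]
    full = np.ones(shape, dtype=bool) if mask is None else mask
    T = data.shape[-1]
    return BoldRun(
        subject_id="toy", site_id="toy", group=0, age=40.0, sex=0,
        tr=tr, voxel_size=voxel_size, data=data,
        brain_mask=full, gm_mask=full, wm_mask=np.zeros(shape, bool),
        csf_mask=np.zeros(shape, bool),
        motion=np.zeros((T, 6)),
        confounds=pd.DataFrame({"wm_mean": np.zeros(T)}),
    )
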