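"""Connectivity and activity features against brute-force oracles and the
phantom's known coupling structure."""

import itertools

import numpy as np
import pytest

from multifc.core import FC_COLUMNS, N_NETWORKS
from multifc.features import (
    ConnectivityMatrix,
    R_CLIP,
    alff_map,
    connectivity_matrix,
    dc_map,
    global_mean,
    network_fc,
    parcel_timeseries,
    reho_map,
)
from multifc.phantom import make_atlas, simulate_run
from multifc.core import SiteSpec, SubjectSpec

from conftest import run_from_array


def _pearson_oracle(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestParcelTimeseries:
    def test_mean_of_identical_voxels(self, small_atlas, demo_run):
        ts = parcel_timeseries(demo_run, small_atlas)
        vox = demo_run.data[small_atlas.labels == 1]
        assert np.allclose(ts[0], vox.mean(axis=0))

    def test_two_half_parcels_average(self, small_atlas):
        run = simulate_run(
            SiteSpec("S", tr=3.0, n_volumes=40, voxel_size=(3, 3, 3),
                     gain=1.0, offset=0.0, noise_sd=0.0),
            SubjectSpec("s", "S", 0, 40.0, 0),
            small_atlas, seed=0)
        # overwrite parcel 1 with two distinct half series a and b
        idx = np.argwhere(small_atlas.labels == 1)
        a = np.sin(np.arange(40.0))
        b = np.cos(np.arange(40.0))
        for i, (x, y, z) in enumerate(idx):
            run.data[x, y, z] = a if i < len(idx) // 2 else b
        ts = parcel_timeseries(run, small_atlas)
        assert np.allclose(ts[0], (a + b) / 2.0)

    def test_empty_parcel_reported(self, small_atlas, demo_run):
        run = demo_run
        mask = run.brain_mask & ~(small_atlas.labels == 3)
        import dataclasses

        broken = dataclasses.replace(run, brain_mask=mask)
        with pytest.raises(ValueError, match=r"\[3\]"):
            parcel_timeseries(broken, small_atlas)


class TestConnectivityMatrix:
    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((5, 17))
        cm = connectivity_matrix(ts, {i + 1: 1 for i in range(5)})
        for i, j in itertools.combinations(range(5), 2):
            r = _pearson_oracle(ts[i], ts[j])
            assert cm.z_matrix[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)
            assert cm.z_matrix[i, j] == cm.z_matrix[j, i]

    def test_duplicated_row_clipped_finite(self):
        ts = np.vstack([np.arange(10.0), np.arange(10.0), np.random.default_rng(1).standard_normal(10)])
        cm = connectivity_matrix(ts, {1: 1, 2: 1, 3: 1})
        assert cm.z_matrix[0, 1] == pytest.approx(np.arctanh(R_CLIP))

    def test_negated_row_clipped_finite_negative(self):
        base = np.arange(10.0)
        cm = connectivity_matrix(np.vstack([base, -base]), {1: 1, 2: 1})
        assert cm.z_matrix[0, 1] == pytest.approx(-np.arctanh(R_CLIP))

    def test_zero_variance_row_rejected(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            connectivity_matrix(ts, {1: 1, 2: 1})


def _toy_cm(block_values, parcels_per_network=3):
    """7 networks x 3 parcels with prescribed within-network z values."""
    P = N_NETWORKS * parcels_per_network
    z = np.zeros((P, P))
    nets = {p + 1: p // parcels_per_network + 1 for p in range(P)}
    for k in range(1, N_NETWORKS + 1):
        members = [p - 1 for p, n in nets.items() if n == k]
        vals = iter(block_values.get(k, [0.5] * 3))
        for a, b in itertools.combinations(members, 2):
            v = next(vals)
            z[a, b] = z[b, a] = v
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z_matrix=z, parcel_networks=nets)


class TestNetworkFc:
    def test_constant_block_mean(self):
        values = network_fc(_toy_cm({}))
        assert all(v == pytest.approx(0.5) for v in values.values())

    def test_negative_edges_excluded(self):
        values = network_fc(_toy_cm({2: [0.6, -0.2, 0.4]}))
        assert values["fc_somatomotor"] == pytest.approx(0.5)

    def test_all_negative_network_flagged_missing(self):
        with pytest.warns(UserWarning, match="no positive"):
            values = network_fc(_toy_cm({5: [-0.1, -0.2, -0.3]}))
        assert np.isnan(values["fc_limbic"])

    def test_invariant_to_parcel_relabelling_within_networks(self):
        rng = np.random.default_rng(2)
        common = rng.standard_normal((7, 60))
        ts = rng.standard_normal((14, 60)) + common.repeat(2, axis=0)
        nets = {p + 1: p // 2 + 1 for p in range(14)}
        ref = network_fc(connectivity_matrix(ts, nets))
        perm = np.arange(14)
        for k in range(7):  # swap the two parcels of each network
            perm[2 * k], perm[2 * k + 1] = perm[2 * k + 1], perm[2 * k]
        out = network_fc(connectivity_matrix(ts[perm], nets))
        for key in ref:
            assert out[key] == pytest.approx(ref[key])

    def test_phantom_orders_coupled_networks(self, small_atlas):
        site = SiteSpec("S", tr=3.0, n_volumes=200, voxel_size=(3, 3, 3),
                        gain=1.0, offset=0.0, noise_sd=0.0)
        sub = SubjectSpec("s", "S", 0, 40.0, 0,
                          coupling=(0.3, 0.6, 0.3, 0.6, 0.3, 0.6, 0.3))
        vals = []
        for seed in range(10):
            run = simulate_run(site, sub, small_atlas, seed=seed)
            cm = connectivity_matrix(parcel_timeseries(run, small_atlas),
                                     small_atlas.parcel_networks)
            vals.append([network_fc(cm)[c] for c in FC_COLUMNS])
        mean = np.mean(vals, axis=0)
        assert np.all(mean[[1, 3, 5]] > mean[[0, 2, 4, 6]].max())
        # recovered means approximate the Fisher-z transformed couplings
        assert np.mean(mean[[1, 3, 5]]) == pytest.approx(np.arctanh(0.6), abs=0.1)
        assert np.mean(mean[[0, 2, 4, 6]]) == pytest.approx(np.arctanh(0.3), abs=0.1)


def _alff_oracle(series, tr, low=0.01, high=0.1):
    T = len(series)
    amps = []
    for k in range(T // 2 + 1):
        f = k / (T * tr)
        if low <= f <= high and f > 0:
            X = sum(series[t] * np.exp(-2j * np.pi * k * t / T) for t in range(T))
            amps.append(2.0 * abs(X) / T)
    return float(np.mean(amps))


class TestAlff:
    def test_linear_in_amplitude(self):
        t = np.arange(100) * 3.0
        x = np.sin(2 * np.pi * 0.05 * t)
        run1 = run_from_array(x.reshape(1, 1, 1, -1), tr=3.0)
        run2 = run_from_array((2 * x).reshape(1, 1, 1, -1), tr=3.0)
        a1 = alff_map(run1)[0, 0, 0]
        a2 = alff_map(run2)[0, 0, 0]
        assert a2 == pytest.approx(2.0 * a1, rel=1e-10)

    def test_out_of_band_signal_has_no_amplitude(self):
        t = np.arange(100) * 1.5
        x = np.sin(2 * np.pi * 0.2 * t)
        a = alff_map(run_from_array(x.reshape(1, 1, 1, -1), tr=1.5))[0, 0, 0]
        assert a < 1e-10

    def test_matches_direct_dft_summation(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal(100)
        a = alff_map(run_from_array(series.reshape(1, 1, 1, -1), tr=3.0))[0, 0, 0]
        assert a == pytest.approx(_alff_oracle(series, 3.0), abs=1e-10)

    def test_empty_band_rejected(self):
        run = run_from_array(np.random.default_rng(4).standard_normal((1, 1, 1, 30)), tr=0.1)
        with pytest.raises(ValueError, match="no FFT bin"):
            alff_map(run, low=0.001, high=0.002)


def _reho_oracle(series_list):
    """Brute-force Kendall's W, no tie correction."""
    from scipy.stats import rankdata

    K = len(series_list)
    T = len(series_list[0])
    ranks = np.array([rankdata(s) for s in series_list])
    R = ranks.sum(axis=0)
    return 12.0 * ((R - R.mean()) ** 2).sum() / (K**2 * (T**3 - T))


class TestReho:
    def test_identical_series_give_full_concordance(self):
        series = np.sin(np.arange(20.0))
        data = np.tile(series, (3, 3, 3, 1))
        w = reho_map(run_from_array(data))
        assert w[1, 1, 1] == pytest.approx(1.0)

    def test_null_mean_is_one_over_k(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, 8, 8, 200))
        w = reho_map(run_from_array(data))
        interior = w[1:-1, 1:-1, 1:-1]
        assert interior.mean() == pytest.approx(1.0 / 27.0, abs=0.005)

    def test_matches_brute_force_on_toy_grid(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((3, 3, 3, 7))
        w = reho_map(run_from_array(data))
        center = _reho_oracle(data.reshape(-1, 7))
        assert w[1, 1, 1] == pytest.approx(center, abs=1e-12)
        # corner voxel uses its 8-voxel neighborhood
        corner_series = data[:2, :2, :2].reshape(-1, 7)
        assert w[0, 0, 0] == pytest.approx(_reho_oracle(corner_series), abs=1e-12)

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(7)
        w = reho_map(run_from_array(rng.standard_normal((5, 5, 4, 12))))
        assert np.nanmin(w) >= 0.0 and np.nanmax(w) <= 1.0


def _dc_oracle(series_2d, threshold):
    N = series_2d.shape[0]
    out = np.zeros(N)
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            r = _pearson_oracle(series_2d[i], series_2d[j])
            if r > threshold:
                out[i] += r
    return out


class TestDegreeCentrality:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((8, 8, 7, 20))  # 448 voxels
        dc = dc_map(run_from_array(data), r_threshold=0.25)
        oracle = _dc_oracle(data.reshape(-1, 20), 0.25)
        assert np.allclose(dc.ravel(), oracle, atol=1e-8)

    def test_identical_voxels_form_complete_graph(self):
        series = np.sin(np.arange(10.0))
        data = np.tile(series, (3, 2, 2, 1))
        dc = dc_map(run_from_array(data))
        assert np.allclose(dc, 11.0)

    def test_threshold_above_max_gives_empty_graph(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((4, 4, 2, 30))
        dc = dc_map(run_from_array(data), r_threshold=1.0)
        assert np.all(dc == 0.0)

    def test_hand_threshold_rule(self):
        # three voxels engineered so r12 ~ 0.9 but r13 and r23 stay below
        # the threshold: only supra-threshold correlations contribute
        rng = np.random.default_rng(10)
        x = rng.standard_normal(2000)
        y = 0.9 * x + np.sqrt(1 - 0.9**2) * rng.standard_normal(2000)
        z = 0.15 * x + rng.standard_normal(2000)
        data = np.stack([x, y, z]).reshape(3, 1, 1, -1)
        dc = dc_map(run_from_array(data), r_threshold=0.25)
        rs = np.corrcoef(np.stack([x, y, z]))
        expected = _dc_oracle(np.stack([x, y, z]), 0.25)
        assert np.allclose(dc.ravel(), expected, atol=1e-10)
        assert rs[0, 2] < 0.25 and rs[1, 2] < 0.25  # sub-threshold edges exist


class TestGlobalMean:
    def test_zero_when_masks_coincide_and_no_smoothing(self):
        rng = np.random.default_rng(11)
        vol = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        assert global_mean(vol, mask, mask, (2, 2, 2), smooth_fwhm=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_elevated_gm_region_is_positive(self):
        rng = np.random.default_rng(12)
        vol = rng.standard_normal((8, 8, 8))
        gm = np.zeros((8, 8, 8), bool)
        gm[2:6, 2:6, 2:6] = True
        vol[gm] += 2.0
        brain = np.ones((8, 8, 8), bool)
        assert global_mean(vol, brain, gm, (2, 2, 2)) > 0.5

    def test_hand_pipeline_evaluation(self):
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [1.0, 2.0, 3.0]
        brain = np.ones((3, 1, 1), bool)
        gm = np.zeros((3, 1, 1), bool)
        gm[2] = True
        # z-scores are (-1, 0, 1); no smoothing; GM mean = 1
        assert global_mean(vol, brain, gm, (1, 1, 1), smooth_fwhm=0.0) == pytest.approx(1.0)
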