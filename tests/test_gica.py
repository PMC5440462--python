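"""Group ICA tests: concatenation, MDL order selection, PCA whitening,
Infomax separation and dual regression."""

import numpy as np
import pytest

from fncpipe import gica, synth
from fncpipe.core import AcquisitionParams, Volume4D

from conftest import pearson


def _subjects(n=3, T=10, dims=(8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    return {
        f"S{i}": Volume4D(rng.standard_normal(dims + (T,)), 3.0, 2.0, subject_id=f"S{i}")
        for i in range(n)
    }


class TestConcat:
    def test_shape_is_total_time_by_voxels(self):
        subs = _subjects(n=3, T=10, dims=(8, 8, 8))
        c = gica.concat_temporal(subs)
        assert c.data.shape == (30, 512)
        assert c.subject_offsets["S2"] == (20, 30)

    def test_single_subject_equals_centered_data(self):
        subs = _subjects(n=1, T=12)
        c = gica.concat_temporal(subs)
        raw = subs["S0"].to_matrix()
        assert np.allclose(c.data, raw - raw.mean(axis=0), atol=1e-12)

    def test_each_block_is_voxelwise_centered(self):
        c = gica.concat_temporal(_subjects(n=4, T=9, seed=2))
        for start, stop in c.subject_offsets.values():
            assert np.max(np.abs(c.data[start:stop].mean(axis=0))) < 1e-10

    def test_grid_mismatch_rejected(self):
        subs = _subjects(n=2)
        subs["S1"] = Volume4D(np.zeros((9, 8, 8, 10)), 3.0, 2.0, subject_id="S1")
        with pytest.raises(ValueError, match="grid"):
            gica.concat_temporal(subs)


class TestMdlOrder:
    def _planted(self, seed, k=12, n=2000, p=64, snr=10.0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, k))
        S = rng.standard_normal((k, p))
        return A @ S * np.sqrt(snr / k) + rng.standard_normal((n, p))

    def test_recovers_planted_order_at_high_snr(self):
        hits = sum(gica.estimate_order_mdl(self._planted(s)).k == 12 for s in range(20))
        assert hits >= 18

    def test_pure_noise_gives_minimal_order(self):
        ks = [
            gica.estimate_order_mdl(
                np.random.default_rng(100 + s).standard_normal((2000, 64))
            ).k
            for s in range(20)
        ]
        assert max(ks) <= 2

    def test_rank_one_signal_gives_order_one(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(500), rng.standard_normal(40))
        X += 1e-3 * rng.standard_normal(X.shape)
        assert gica.estimate_order_mdl(X).k == 1

    def test_curve_minimum_is_reported_order(self):
        est = gica.estimate_order_mdl(self._planted(5))
        assert est.k == int(np.argmin(est.criterion_curve)) + 1

    def test_degenerate_rank_rejected(self):
        X = np.outer(np.ones(50), np.ones(30))
        with pytest.raises(ValueError, match="degenerate"):
            gica.estimate_order_mdl(X)


class TestPcaReduce:
    def test_full_rank_reconstruction_is_exact(self):
        X = np.random.default_rng(0).standard_normal((20, 30))
        pca = gica.pca_reduce(X, 20)
        recon = pca.back_projection @ pca.whitened
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-10

    def test_whitened_covariance_is_identity(self):
        X = np.random.default_rng(1).standard_normal((40, 200))
        pca = gica.pca_reduce(X, 10)
        cov = pca.whitened @ pca.whitened.T / pca.whitened.shape[1]
        assert np.max(np.abs(cov - np.eye(10))) < 1e-6

    def test_planted_sources_capture_most_variance(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((500, 12))
        S = rng.standard_normal((12, 400))
        X = A @ S * np.sqrt(10.0 / 12) + rng.standard_normal((500, 400))
        pca = gica.pca_reduce(X, 12)
        assert pca.explained_variance_ratio >= 0.85

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.standard_normal(30), rng.standard_normal(20))
        with pytest.raises(ValueError, match="rank"):
            gica.pca_reduce(X, 5)


class TestInfomax:
    def test_separates_super_gaussian_sources(self):
        rng = np.random.default_rng(1)
        S = rng.laplace(size=(2, 5000))
        X = np.array([[1.0, 0.6], [0.4, 1.0]]) @ S
        dec = gica.infomax_ica(gica.pca_reduce(X, 2), seed=0)
        C = np.abs(np.corrcoef(np.vstack([dec.component_maps, S]))[:2, 2:])
        assert C.max(axis=1).min() >= 0.99

    def test_gaussian_sources_terminate_cleanly(self):
        rng = np.random.default_rng(2)
        X = np.array([[1.0, 0.6], [0.4, 1.0]]) @ rng.standard_normal((2, 3000))
        dec = gica.infomax_ica(gica.pca_reduce(X, 2), seed=0, max_iter=100)
        assert np.all(np.isfinite(dec.component_maps))

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = np.array([[1.0, 0.6], [0.4, 1.0]]) @ rng.laplace(size=(2, 2000))
        pca = gica.pca_reduce(X, 2)
        d1 = gica.infomax_ica(pca, seed=7)
        d2 = gica.infomax_ica(pca, seed=7)
        assert np.array_equal(d1.component_maps, d2.component_maps)

    def test_different_seeds_agree_per_component(self):
        rng = np.random.default_rng(4)
        S = rng.laplace(size=(3, 4000))
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        pca = gica.pca_reduce(A @ S, 3)
        d1 = gica.infomax_ica(pca, seed=0)
        d2 = gica.infomax_ica(pca, seed=99)
        C = np.abs(np.corrcoef(np.vstack([d1.component_maps, d2.component_maps]))[:3, 3:])
        assert C.max(axis=1).min() >= 0.95

    def test_maps_are_skew_positive_and_variance_ordered(self):
        rng = np.random.default_rng(5)
        S = np.abs(rng.laplace(size=(3, 3000)))      # positively skewed sources
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        dec = gica.infomax_ica(gica.pca_reduce(A @ S, 3), seed=0)
        from scipy.stats import skew
        assert np.all(skew(dec.component_maps, axis=1) >= 0)
        assert np.all(np.diff(dec.explained_variance) <= 1e-12)

    def test_back_projection_consistency(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 300))
        pca = gica.pca_reduce(X, 5)
        dec = gica.infomax_ica(pca, seed=0, max_iter=50)
        lhs = dec.component_timecourses @ dec.component_maps
        rhs = pca.back_projection @ pca.whitened
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestDualRegression:
    def _generative(self, noise_sd=0.0, seed=0, k=3, T=60, dims=(16, 16, 12)):
        acq = AcquisitionParams(n_volumes=T, grid_dims=dims)
        specs = synth.default_network_specs(acq)[:k]
        maps = synth.make_network_maps(specs, acq)
        tcs = synth.make_timecourses([], k, acq, seed=seed)
        vol, _ = synth.assemble_subject(maps, tcs, acq, noise_sd=noise_sd, seed=seed)
        flat = maps.reshape(k, -1)
        return flat, tcs, vol

    def test_noiseless_inverse_recovers_maps_and_timecourses(self):
        flat, tcs, vol = self._generative(noise_sd=0.0)
        out = gica.dual_regression(flat, vol)
        for k in range(3):
            assert abs(pearson(out.timecourses[:, k], tcs[k])) >= 0.999
            assert abs(pearson(out.maps[k], flat[k])) >= 0.999

    def test_default_noise_recovery_after_smoothing(self):
        # at the generator's default noise and run length the analysis
        # sees smoothed data; map precision scales with T
        from fncpipe import prep

        flat, tcs, vol = self._generative(noise_sd=1.0, seed=3, T=250)
        out = gica.dual_regression(flat, prep.smooth_gaussian(vol, 8.0))
        for k in range(3):
            assert abs(pearson(out.maps[k], flat[k])) >= 0.9

    def test_single_constant_map_gives_global_mean_series(self):
        rng = np.random.default_rng(0)
        vol = Volume4D(rng.standard_normal((8, 8, 8, 30)), 3.0, 2.0)
        out = gica.dual_regression(np.ones((1, 512)), vol)
        global_mean = vol.data.reshape(-1, 30).mean(axis=0)
        assert abs(pearson(out.timecourses[:, 0], global_mean)) >= 0.999999

    def test_collinear_group_maps_rejected(self):
        rng = np.random.default_rng(1)
        vol = Volume4D(rng.standard_normal((8, 8, 8, 30)), 3.0, 2.0)
        base = rng.standard_normal(512)
        G = np.vstack([base, base * 2.0 + 1e-12])
        with pytest.raises(ValueError, match="collinear"):
            gica.dual_regression(G, vol)

    def test_group_mean_self_consistency(self):
        # dual regression of data built exactly from the group maps and
        # time courses returns those time courses
        flat, tcs, vol = self._generative(noise_sd=0.0, seed=5)
        out = gica.dual_regression(flat, vol)
        assert np.allclose(
            np.corrcoef(out.timecourses.T, tcs)[:3, 3:].diagonal(),
            [1.0, 1.0, 1.0], atol=1e-6,
        ) or all(abs(pearson(out.timecourses[:, i], tcs[i])) > 0.999 for i in range(3))
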