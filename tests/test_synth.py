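"""Generator tests: spatial maps, lagged coupling, subject assembly,
cohort determinism."""

import numpy as np
import pytest

from fncpipe import synth
from fncpipe.core import AcquisitionParams
from fncpipe.fnc import LagSpec, NetworkTimeCourse, max_lagged_corr

from conftest import pearson


ACQ = AcquisitionParams()  # TR 2 s, 255 volumes, 24x24x18 @ 3 mm


class TestNetworkMaps:
    def test_single_blob_peaks_at_center_with_value_one(self):
        spec = synth.NetworkSpec("X", ((12, 12, 9),), blob_fwhm_mm=12.0)
        other = synth.NetworkSpec("Y", ((6, 6, 4),), blob_fwhm_mm=12.0)
        maps = synth.make_network_maps([spec, other], ACQ)
        assert np.unravel_index(np.argmax(maps[0]), maps[0].shape) == (12, 12, 9)
        assert maps[0].max() == pytest.approx(1.0)

    def test_default_layout_has_low_pairwise_overlap(self):
        maps = synth.make_network_maps(synth.default_network_specs(ACQ), ACQ)
        flat = maps.reshape(12, -1)
        corr = np.corrcoef(flat)
        off = np.abs(corr[np.triu_indices(12, 1)])
        assert off.shape == (66,)
        assert off.max() <= 0.3

    def test_identical_blob_layouts_rejected(self):
        s = synth.NetworkSpec("A", ((5, 5, 5),))
        t = synth.NetworkSpec("B", ((5, 5, 5),))
        with pytest.raises(ValueError, match="identical blob layout"):
            synth.make_network_maps([s, t], ACQ)

    def test_center_outside_grid_rejected(self):
        s = synth.NetworkSpec("A", ((99, 5, 5),))
        t = synth.NetworkSpec("B", ((5, 5, 5),))
        with pytest.raises(ValueError, match="outside grid"):
            synth.make_network_maps([s, t], ACQ)


class TestTimecourses:
    def test_uncoupled_networks_stay_near_zero_correlation(self):
        # pooled over seeds, pairs and lags, ~98% of null lagged-correlation
        # draws at T=250 should sit inside +-0.15
        acq = AcquisitionParams(n_volumes=250)
        count = total = 0
        for seed in range(50):
            tcs = synth.make_timecourses([], 3, acq, seed=seed)
            for i in range(3):
                for j in range(i + 1, 3):
                    for lag in range(-2, 3):
                        a, b = tcs[i], tcs[j]
                        if lag >= 0:
                            r = pearson(a[:len(a) - lag] if lag else a, b[lag:])
                        else:
                            r = pearson(a[-lag:], b[:lag])
                        total += 1
                        count += abs(r) < 0.15
        assert count / total >= 0.95

    def test_planted_zero_lag_coupling_realized(self):
        acq = AcquisitionParams(n_volumes=250)
        for seed in range(5):
            tcs = synth.make_timecourses(
                [synth.CouplingSpec((0, 1), 0.6)], 3, acq, seed=seed
            )
            assert pearson(tcs[0], tcs[1]) == pytest.approx(0.6, abs=0.12)

    def test_planted_coupling_mean_within_002_of_target(self):
        # fidelity over repeated draws at T=250
        acq = AcquisitionParams(n_volumes=250)
        rs = [
            pearson(*synth.make_timecourses(
                [synth.CouplingSpec((0, 1), 0.6)], 2, acq, seed=s
            ))
            for s in range(200)
        ]
        assert np.mean(rs) == pytest.approx(0.6, abs=0.02)

    def test_lagged_coupling_recovered_by_fnc_estimator(self):
        acq = AcquisitionParams(n_volumes=250)
        spec = LagSpec()
        hits = 0
        for seed in range(100):
            tcs = synth.make_timecourses(
                [synth.CouplingSpec((0, 1), 0.9, lag_s=4.0)], 2, acq, seed=seed
            )
            edge = max_lagged_corr(
                NetworkTimeCourse(tcs[0], acq.tr_s),
                NetworkTimeCourse(tcs[1], acq.tr_s), spec,
            )
            hits += edge.lag_s == 4.0
        assert hits >= 95

    def test_infeasible_correlation_structure_rejected(self):
        couplings = [
            synth.CouplingSpec((0, 1), 0.9),
            synth.CouplingSpec((1, 2), 0.9),
            synth.CouplingSpec((0, 2), -0.9),
        ]
        with pytest.raises(ValueError, match="eigenvalue"):
            synth.make_timecourses(couplings, 3, ACQ, seed=0)

    def test_lag_off_the_tr_grid_rejected(self):
        with pytest.raises(ValueError, match="multiple of TR"):
            synth.make_timecourses(
                [synth.CouplingSpec((0, 1), 0.5, lag_s=3.0)], 2, ACQ, seed=0
            )

    def test_inconsistent_lag_cycle_rejected(self):
        couplings = [
            synth.CouplingSpec((0, 1), 0.3, lag_s=2.0),
            synth.CouplingSpec((1, 2), 0.3, lag_s=2.0),
            synth.CouplingSpec((0, 2), 0.3, lag_s=2.0),  # should be 4 s
        ]
        with pytest.raises(ValueError, match="inconsistent lag"):
            synth.make_timecourses(couplings, 3, ACQ, seed=0)

    def test_rows_are_standardized(self):
        tcs = synth.make_timecourses([synth.CouplingSpec((0, 1), 0.5)], 4, ACQ, seed=3)
        assert np.allclose(tcs.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(tcs.std(axis=1), 1, atol=1e-12)


class TestAssembleSubject:
    def _small(self):
        acq = AcquisitionParams(n_volumes=60, grid_dims=(16, 16, 12))
        specs = synth.default_network_specs(acq)[:3]
        maps = synth.make_network_maps(specs, acq)
        tcs = synth.make_timecourses([], 3, acq, seed=0)
        return acq, maps, tcs

    def test_noiseless_voxel_series_is_exact_mixture(self):
        acq, maps, tcs = self._small()
        vol, _ = synth.assemble_subject(maps[:1], tcs[:1], acq, noise_sd=0.0)
        peak = np.unravel_index(np.argmax(maps[0]), maps[0].shape)
        series = vol.data[peak]
        # regression on the planted time course explains everything
        assert pearson(series, tcs[0]) == pytest.approx(1.0, abs=1e-6)

    def test_mask_average_recovers_timecourse_at_default_noise(self):
        acq, maps, tcs = self._small()
        vol, _ = synth.assemble_subject(maps, tcs, acq, noise_sd=1.0, seed=4)
        mask = maps[0] > synth.SUPRA_THRESHOLD
        series = vol.data[mask].mean(axis=0)
        assert abs(pearson(series, tcs[0])) >= 0.8

    def test_noiseless_data_has_low_rank(self):
        acq, maps, tcs = self._small()
        vol, _ = synth.assemble_subject(maps, tcs, acq, noise_sd=0.0, drift_slope=0.01)
        X = vol.data.reshape(-1, acq.n_volumes).astype(np.float64)
        s = np.linalg.svd(X, compute_uv=False)
        assert np.sum(s > s[0] * 1e-8) <= maps.shape[0] + 2

    def test_negative_noise_rejected(self):
        acq, maps, tcs = self._small()
        with pytest.raises(ValueError, match="noise_sd"):
            synth.assemble_subject(maps, tcs, acq, noise_sd=-1.0)

    def test_nuisance_masks_disjoint_from_networks(self):
        acq, maps, tcs = self._small()
        wm, csf = synth.default_nuisance_masks(acq.grid_dims)
        supra = np.any(maps > synth.SUPRA_THRESHOLD, axis=0)
        assert not (wm & supra).any()
        assert not (csf & supra).any()
        # overlap must be rejected when forced
        bad_wm = wm.copy()
        bad_wm[np.unravel_index(np.argmax(maps[0]), maps[0].shape)] = True
        with pytest.raises(ValueError, match="overlaps suprathreshold"):
            synth.assemble_subject(maps, tcs, acq, wm_mask=bad_wm, csf_mask=csf)


class TestCohort:
    def test_default_spec_matches_study_design(self):
        spec = synth.default_cohort_spec()
        assert spec.group_sizes == {"HC": 21, "MS": 20, "AS": 21}
        assert sum(spec.group_sizes.values()) == 62
        assert spec.acq.tr_s == 2.0
        assert spec.acq.n_volumes == 255
        assert spec.acq.voxel_mm == 3.0

    def test_same_seed_reproduces_cohort_bit_for_bit(self, tmp_path):
        spec = synth.default_cohort_spec(
            grid_dims=(16, 16, 12), n_volumes=40, group_sizes={"HC": 2, "MS": 2, "AS": 2}
        )
        a = synth.simulate_cohort(spec, seed=9, out_dir=tmp_path / "a")
        b = synth.simulate_cohort(spec, seed=9, out_dir=tmp_path / "b")
        for sid in a.volumes:
            assert np.array_equal(a.volumes[sid].data, b.volumes[sid].data)
        fa = (tmp_path / "a" / "HC01_bold.nii").read_bytes()
        fb = (tmp_path / "b" / "HC01_bold.nii").read_bytes()
        assert fa == fb

    def test_distinct_subject_seeds_and_manifest_roundtrip(self, tmp_path):
        import pandas as pd

        spec = synth.default_cohort_spec(
            grid_dims=(16, 16, 12), n_volumes=40, group_sizes={"HC": 2, "MS": 2, "AS": 2}
        )
        res = synth.simulate_cohort(spec, seed=1, out_dir=tmp_path)
        assert res.manifest["seed"].nunique() == len(res.manifest)
        back = pd.read_csv(tmp_path / "manifest.tsv", sep="\t")
        assert back.equals(res.manifest)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            synth.default_cohort_spec(group_sizes={"HC": 1, "MS": 5, "AS": 5})

    def test_group_effects_shift_planted_correlation_in_z(self):
        spec = synth.default_cohort_spec(grid_dims=(16, 16, 12), n_volumes=40,
                                         group_sizes={"HC": 2, "MS": 2, "AS": 2})
        res = synth.simulate_cohort(spec, seed=0)
        row = res.truth.coupling_table.query("label_i == 'VN' and label_j == 'SN'")
        if row.empty:
            row = res.truth.coupling_table.query("label_i == 'SN' and label_j == 'VN'")
        row = row.iloc[0]
        assert np.arctanh(row["rho_MS"]) == pytest.approx(np.arctanh(row["rho"]) - 0.43, abs=1e-9)
        assert np.arctanh(row["rho_AS"]) == pytest.approx(np.arctanh(row["rho"]) - 0.31, abs=1e-9)

    def test_motion_exceeders_generated_on_request(self):
        trace = synth.simulate_motion(100, seed=0, exceed=True)
        assert np.abs(trace[:, :3]).max() > 2.0
        calm = synth.simulate_motion(100, seed=0, exceed=False)
        assert np.abs(calm).max() <= 2.0
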