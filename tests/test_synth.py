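"""Generator contracts: determinism, planted structure, ground-truth records."""

import numpy as np
import pytest

from fibriddi import depth, energetics as en, synth, thermo as th, transport as tr


class TestDeterminism:
    def test_tunnel_profile(self):
        a = synth.gen_tunnel_profile(7)
        b = synth.gen_tunnel_profile(7)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.l, b.l)

    def test_trajectory_pair(self):
        (a1, b1, t1), (a2, b2, t2) = (synth.gen_trajectory_pair(3) for _ in range(2))
        assert np.array_equal(a1.dg, a2.dg) and np.array_equal(b1.dg, b2.dg)
        assert t1 == t2

    def test_depth_chains(self):
        (b1, a1, _), (b2, a2, _) = (synth.gen_depth_chains(5) for _ in range(2))
        for c1, c2 in zip(b1 + a1, b2 + a2):
            assert np.array_equal(c1.coords, c2.coords)
            assert c1.res_types == c2.res_types

    def test_pose_ensemble(self):
        assert synth.gen_pose_ensemble(9).poses == synth.gen_pose_ensemble(9).poses

    def test_ultrasound_series(self):
        (s1, t1), (s2, t2) = (synth.gen_ultrasound_series(4) for _ in range(2))
        assert np.array_equal(s1.velocity, s2.velocity)
        assert t1 == t2

    def test_different_seeds_differ(self):
        a = synth.gen_tunnel_profile(1)
        b = synth.gen_tunnel_profile(2)
        assert not np.array_equal(a.r, b.r)


class TestTunnelProfile:
    def test_bottleneck_radius_within_one_percent(self):
        p = synth.gen_tunnel_profile(0)
        assert min(p.r) == pytest.approx(2.4, rel=0.01)

    def test_bottleneck_position(self):
        p = synth.gen_tunnel_profile(0, bottleneck_position=0.3)
        assert p.l[int(np.argmin(p.r))] == pytest.approx(0.3 * 15.0, abs=0.5)

    def test_flat_when_bottleneck_equals_mean(self):
        p = synth.gen_tunnel_profile(0, mean_radius=3.0, bottleneck_radius=3.0)
        assert np.allclose(p.r, 3.0)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_tunnel_profile(0, mean_radius=2.0, bottleneck_radius=3.0)


class TestTrajectoryPair:
    def test_well_depths_within_five_percent(self):
        a, b, truth = synth.gen_trajectory_pair(1)
        assert tr.trajectory_extrema(a)[0] == pytest.approx(-7.7, rel=0.05)
        assert tr.trajectory_extrema(b)[0] == pytest.approx(-6.5, rel=0.05)

    def test_correlated_inside_window(self):
        a, b, truth = synth.gen_trajectory_pair(2)
        w0, w1 = truth.window
        mask = (a.pos >= w0) & (a.pos <= w1)
        r = np.corrcoef(a.dg[mask], b.dg[mask])[0, 1]
        assert r > 0.8

    def test_second_ligand_positive_outside_window(self):
        a, b, truth = synth.gen_trajectory_pair(3)
        w0, w1 = truth.window
        outside = (b.pos < w0 - 0.2) | (b.pos > w1 + 0.2)
        assert np.all(b.dg[outside] > 0)
        assert np.all(a.dg < 0)

    def test_zero_divergence_identical(self):
        a, b, _ = synth.gen_trajectory_pair(
            4, well_depths=(-7.0, -7.0), divergence_amplitude=0.0
        )
        np.testing.assert_allclose(a.dg, b.dg, atol=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_trajectory_pair(0, support=10.0, window=(8.0, 12.0))


class TestDepthChains:
    def test_round_trip_mean_drop_in_range(self):
        before, after, truth = synth.gen_depth_chains(11)
        pb, _ = depth.residue_depth(before)
        pa, _ = depth.residue_depth(after, "ligand-bound")
        _, summary = depth.depth_perturbation(pb, pa)
        assert 1.0 <= summary["mean"] <= 2.0
        ref = np.mean(list(truth.per_chain_drop.values()))
        assert summary["mean"] == pytest.approx(ref, abs=1e-9)

    def test_zero_drop_gives_identical_depths(self):
        before, after, _ = synth.gen_depth_chains(12, depth_drop=(0.0, 0.0))
        pb, _ = depth.residue_depth(before)
        pa, _ = depth.residue_depth(after, "ligand-bound")
        _, summary = depth.depth_perturbation(pb, pa)
        assert summary["max_abs"] < 1e-9

    def test_baseline_mean_depth_calibrated(self):
        before, _, truth = synth.gen_depth_chains(13)
        pb, _ = depth.residue_depth(before)
        per_chain = {}
        for (cid, _), v in pb.values.items():
            per_chain.setdefault(cid, []).append(v)
        for vals in per_chain.values():
            assert np.mean(vals) == pytest.approx(truth.mean_depth_before, abs=1e-9)

    def test_excessive_drop_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_depth_chains(0, depth_drop=(5.0, 6.0), mean_depth=4.0)


class TestPoseEnsembles:
    def test_hot_site_single_dominant_bin(self):
        h = en.k_occurrence_histogram(synth.gen_pose_ensemble(21, "hot"), 0.5)
        assert int((h.k_docked + h.k_undocked).max()) >= 80

    def test_cold_site_dispersed(self):
        h = en.k_occurrence_histogram(synth.gen_pose_ensemble(22, "cold"), 0.5)
        assert int((h.k_docked + h.k_undocked).max()) <= 30

    def test_zero_poses_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_pose_ensemble(0, "hot", 0)


class TestUltrasoundSeries:
    def test_ideal_limit_matches_clint(self):
        _, cmc_m = synth.forward_mixed_cmc(0.0, 10.0, 2.0, 0.5)
        assert cmc_m == pytest.approx(th.ideal_mixing_cmc(10.0, 2.0, 0.5), rel=1e-10)

    def test_break_at_planted_cac_noise_free(self):
        series, truth = synth.gen_ultrasound_series(0, noise_rel=0.0)
        assert th.detect_cac(series) == pytest.approx(truth.cmc_m, abs=0.05)

    def test_ground_truth_is_self_consistent(self):
        _, truth = synth.gen_ultrasound_series(1, beta_true=-1.0)
        beta_back = th.beta_interaction(truth.cmc1, truth.cmc_m, truth.alpha1, truth.x1)
        assert beta_back == pytest.approx(-1.0, abs=1e-9)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_ultrasound_series(0, noise_rel=-0.1)


class TestBackboneStandIn:
    def test_has_all_six_chains(self, eregion):
        assert set(eregion.chain_ids) == set("NOPQRS")

    def test_pdb_round_trip(self, eregion, tmp_path):
        from fibriddi import structure as st

        p = tmp_path / "synthetic_eregion.pdb"
        synth.write_pdb(eregion, p)
        s2 = st.read_structure(p)
        assert s2.n_residues() == eregion.n_residues()
        a1 = eregion.atom(("N", 48, ""), "CA")
        a2 = s2.atom(("N", 48, ""), "CA")
        assert np.allclose(a1.coord, a2.coord, atol=1e-3)
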