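"""Pairwise scoring terms, energy decomposition, and k-occurrence counts."""

import numpy as np
import pytest

from fibriddi import energetics as en


def _atom(i, x, **kw):
    return en.AtomRecord(i, "C", (float(x), 0.0, 0.0), 1.0, **kw)


def _rand_atoms(rng, n, shift=0.0):
    return [
        en.AtomRecord(
            i,
            "C",
            tuple(rng.uniform(0, 5, 3) + shift),
            float(rng.uniform(1.2, 2.0)),
            hydrophobic=bool(rng.random() < 0.5),
            donor=bool(rng.random() < 0.4),
            acceptor=bool(rng.random() < 0.4),
        )
        for i in range(n)
    ]


class TestPairTerm:
    @pytest.mark.parametrize(
        "d,kind,value",
        [
            (0.0, "gauss1", 1.0),
            (3.0, "gauss2", 1.0),
            (1.0, "hydrophobic", 0.5),
            (0.5, "hydrophobic", 1.0),
            (1.5, "hydrophobic", 0.0),
            (-0.7, "hbond", 1.0),
            (0.0, "hbond", 0.0),
            (-0.35, "hbond", 0.5),
            (-0.5, "repulsion", 0.25),
            (0.5, "repulsion", 0.0),
        ],
    )
    def test_reference_points(self, d, kind, value):
        assert en.pair_term(d, kind) == pytest.approx(value)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            en.pair_term(0.0, "electrostatic")

    def test_continuity_and_ranges(self):
        grid = np.linspace(-3, 6, 2001)
        for kind in en.TERMS:
            vals = np.array([en.pair_term(d, kind) for d in grid])
            assert np.max(np.abs(np.diff(vals))) < 0.05  # no jumps on a fine grid
            if kind.startswith("gauss"):
                assert np.all((vals > 0) & (vals <= 1))
            elif kind == "repulsion":
                assert np.all(vals >= 0)
            else:
                assert np.all((vals >= 0) & (vals <= 1))


class TestLigandBindingEnergy:
    def test_single_pair_gauss2_only(self):
        # surface distance = 5 - 1 - 1 = 3, the gauss2 peak
        lig = [_atom(1, 0.0)]
        rec = [_atom(2, 5.0)]
        weights = {k: 0.0 for k in en.TERMS}
        weights["gauss2"] = -1.0
        eb = en.ligand_binding_energy(lig, rec, weights=weights)
        assert eb.total == pytest.approx(-1.0)

    def test_no_rotors_means_no_rot_term(self):
        rng = np.random.default_rng(0)
        lig, rec = _rand_atoms(rng, 4), _rand_atoms(rng, 4, 1.0)
        eb = en.ligand_binding_energy(lig, rec, n_rot=0)
        assert eb.rot == 0.0

    def test_rot_term_is_scaling_difference(self):
        rng = np.random.default_rng(1)
        lig, rec = _rand_atoms(rng, 4), _rand_atoms(rng, 4, 1.0)
        eb0 = en.ligand_binding_energy(lig, rec, n_rot=0)
        eb5 = en.ligand_binding_energy(lig, rec, n_rot=5)
        scale = 1.0 / (1.0 + en.W_ROT_DEFAULT * 5)
        assert eb5.total == pytest.approx(eb0.total * scale, abs=1e-12)
        assert eb5.rot == pytest.approx(eb0.total * (scale - 1.0), abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        lig, rec = _rand_atoms(rng, 5), _rand_atoms(rng, 5, 0.5)
        eb = en.ligand_binding_energy(lig, rec, cutoff=100.0)
        ref = {k: 0.0 for k in en.TERMS}
        for a in lig:
            for b in rec:
                d = (
                    float(np.linalg.norm(np.subtract(a.coord, b.coord)))
                    - a.vdw_radius
                    - b.vdw_radius
                )
                ref["gauss1"] += en.pair_term(d, "gauss1")
                ref["gauss2"] += en.pair_term(d, "gauss2")
                ref["repulsion"] += en.pair_term(d, "repulsion")
                if (a.donor and b.acceptor) or (a.acceptor and b.donor):
                    ref["hbond"] += en.pair_term(d, "hbond")
                if a.hydrophobic and b.hydrophobic:
                    ref["hydrophobic"] += en.pair_term(d, "hydrophobic")
        for k in en.TERMS:
            assert getattr(eb, k) == pytest.approx(
                en.DEFAULT_WEIGHTS[k] * ref[k], abs=1e-9
            )

    def test_breakdown_sums_reconcile(self):
        rng = np.random.default_rng(3)
        lig, rec = _rand_atoms(rng, 6), _rand_atoms(rng, 6, 1.0)
        eb = en.ligand_binding_energy(lig, rec, n_rot=3)
        parts = eb.gauss1 + eb.gauss2 + eb.repulsion + eb.hbond + eb.hydrophobic + eb.rot
        assert parts == pytest.approx(eb.total, abs=1e-12)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            en.ligand_binding_energy([], [_atom(1, 0.0)])


class TestTotalAffinity:
    def test_favorable_sum(self):
        a = en.EnergyBreakdown("A", -4.2, 0, 0, 0, 0, 0)
        b = en.EnergyBreakdown("P", -3.5, 0, 0, 0, 0, 0)
        total, cls = en.total_affinity(a, b)
        assert total == pytest.approx(-7.7) and cls == "favorable"

    @pytest.mark.parametrize("ga,gb,cls", [(1.0, -0.5, "unfavorable"), (0.0, 0.0, "unfavorable")])
    def test_unfavorable_and_boundary(self, ga, gb, cls):
        a = en.EnergyBreakdown("A", ga, 0, 0, 0, 0, 0)
        b = en.EnergyBreakdown("P", gb, 0, 0, 0, 0, 0)
        assert en.total_affinity(a, b)[1] == cls

    def test_label_swap_invariance(self):
        a = en.EnergyBreakdown("A", -1.1, -0.2, 0.3, 0, 0, 0)
        b = en.EnergyBreakdown("P", -2.0, 0, 0, -0.4, 0, 0)
        assert en.total_affinity(a, b)[0] == pytest.approx(en.total_affinity(b, a)[0])


class TestPerAtomContributions:
    def test_single_ligand_atom_takes_all(self):
        lig = [_atom(1, 0.0, hydrophobic=True)]
        rec = [_atom(2, 4.0, hydrophobic=True), _atom(3, 5.0)]
        table = en.per_atom_contributions(lig, rec)
        eb = en.ligand_binding_energy(lig, rec)
        assert table.total.sum() == pytest.approx(eb.total, abs=1e-12)
        assert len(table) == 1

    def test_symmetric_ligand_splits_evenly(self):
        lig = [_atom(1, -2.0), _atom(2, 2.0)]
        rec = [_atom(3, 0.0)]
        table = en.per_atom_contributions(lig, rec)
        assert table.total.iloc[0] == pytest.approx(table.total.iloc[1], abs=1e-12)

    def test_column_sums_reconcile_with_breakdown(self):
        rng = np.random.default_rng(5)
        lig, rec = _rand_atoms(rng, 7), _rand_atoms(rng, 6, 0.8)
        for n_rot in (0, 4):
            table = en.per_atom_contributions(lig, rec, n_rot=n_rot)
            eb = en.ligand_binding_energy(lig, rec, n_rot=n_rot)
            assert table.total.sum() == pytest.approx(eb.total, abs=1e-9)


class TestKOccurrences:
    def test_empty_ensemble(self):
        h = en.k_occurrence_histogram(en.PoseEnsemble([]), 0.5)
        assert len(h) == 0

    def test_single_mode_single_bin(self):
        poses = [(f"p{i}", -7.7, True) for i in range(100)]
        h = en.k_occurrence_histogram(en.PoseEnsemble(poses), 0.5)
        assert len(h) == 1 and h.k_docked.iloc[0] == 100

    def test_counts_partition_poses(self):
        rng = np.random.default_rng(6)
        poses = [
            (f"p{i}", float(a), bool(rng.random() < 0.5))
            for i, a in enumerate(rng.uniform(-9, -3, 250))
        ]
        h = en.k_occurrence_histogram(en.PoseEnsemble(poses), 0.7)
        assert int((h.k_docked + h.k_undocked).sum()) == 250
        # brute-force binning oracle
        for _, row in h.iterrows():
            n_ref = sum(1 for p in poses if row.bin_left <= p[1] < row.bin_right)
            assert int(row.k_docked + row.k_undocked) == n_ref

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            en.k_occurrence_histogram(en.PoseEnsemble([]), 0.0)
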