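"""Structure parsing, backbone dihedrals, and Ramachandran classification."""

import numpy as np
import pytest

from fibriddi import structure as st
from fibriddi.synth import build_backbone


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent four-point formula via plane normals and atan2."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    a = np.degrees(np.arctan2(y, x))
    return a + 360.0 if a <= -180.0 else a


class TestReadStructure:
    def test_parses_residues_and_chains(self, mini_pdb):
        s = st.read_structure(mini_pdb)
        assert set(s.chain_ids) == {"P", "Q"}
        # 3 amino acids in P (one with icode), 1 in Q, plus a water
        assert s.n_residues() == 5
        assert s.residue_name(("P", 2, "A")) == "SER"

    def test_altloc_keeps_highest_occupancy(self, mini_pdb):
        s = st.read_structure(mini_pdb)
        ca = s.atom(("P", 2, ""), "CA")
        assert ca.occupancy == pytest.approx(0.60)
        assert ca.coord[0] == pytest.approx(8.612)

    def test_hetatm_flagged(self, mini_pdb):
        s = st.read_structure(mini_pdb)
        assert s.atom(("Q", 101, ""), "O").het

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            st.read_structure(tmp_path / "nope.pdb")

    def test_no_atoms_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="no ATOM"):
            st.read_structure(p)


class TestDihedral:
    def test_matches_independent_oracle_on_random_points(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            assert st.dihedral(*pts) == pytest.approx(
                _dihedral_oracle(*pts), abs=1e-6
            )

    def test_trans_extended_tripeptide_near_180(self):
        coords = build_backbone([180.0, 180.0, 180.0], [180.0, 180.0, 180.0])
        phi2 = st.dihedral(coords[2], coords[3], coords[4], coords[5])
        psi2 = st.dihedral(coords[3], coords[4], coords[5], coords[6])
        assert abs(abs(phi2) - 180.0) < 1.0
        assert abs(abs(psi2) - 180.0) < 1.0

    def test_mirroring_negates_angle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        a = st.dihedral(*pts)
        if abs(abs(a) - 180.0) > 1e-6:  # +-180 is its own mirror image
            assert st.dihedral(*mirrored) == pytest.approx(-a, abs=1e-9)

    def test_builder_round_trip(self):
        """compute_phi_psi recovers the dihedrals the chain was built with."""
        phis = [0.0, -63.0, -120.0, -75.0]
        psis = [-43.0, 130.0, -40.0, 0.0]
        coords = build_backbone(phis, psis)
        atoms = []
        for i in range(4):
            for j, name in enumerate(("N", "CA", "C")):
                xyz = coords[3 * i + j]
                atoms.append(
                    st.Atom("A", i + 1, "", "ALA", name, name[0], tuple(xyz))
                )
        geoms = st.compute_phi_psi(st.Structure(atoms))
        assert geoms[0].phi is None and geoms[-1].psi is None
        for i in (1, 2, 3):
            assert geoms[i].phi == pytest.approx(phis[i], abs=1e-6)
        for i in (0, 1, 2):
            assert geoms[i].psi == pytest.approx(psis[i], abs=1e-6)


class TestComputePhiPsi:
    def test_chain_first_phi_undefined(self, mini_pdb):
        geoms = st.compute_phi_psi(st.read_structure(mini_pdb))
        by_res = {(g.chain_id, g.res_seq, g.icode): g for g in geoms}
        assert by_res[("P", 1, "")].phi is None
        assert by_res[("P", 2, "A")].psi is None  # chain-last
        assert by_res[("P", 2, "")].phi is not None

    def test_water_not_reported(self, mini_pdb):
        geoms = st.compute_phi_psi(st.read_structure(mini_pdb))
        assert all(g.res_name != "HOH" for g in geoms)


class TestRamachandran:
    @pytest.mark.parametrize(
        "phi,psi,label",
        [
            (-60.0, -45.0, "favored"),
            (-120.0, 130.0, "favored"),
            (60.0, 45.0, "favored"),
            (0.0, 0.0, "disallowed"),
            (120.0, -120.0, "disallowed"),
        ],
    )
    def test_classification(self, phi, psi, label):
        assert st.classify_ramachandran(phi, psi).label == label

    def test_alpha_region_name(self):
        assert st.classify_ramachandran(-60.0, -45.0).region == "alpha"

    def test_undefined_angles_not_classifiable(self):
        assert st.classify_ramachandran(None, -45.0).label == "not-classifiable"

    def test_favored_subset_of_allowed(self):
        """Every grid point classified favored lies inside an allowed polygon."""
        from fibriddi.structure import _CONTOURS

        for phi in np.arange(-180, 181, 5.0):
            for psi in np.arange(-180, 181, 5.0):
                cls = st.classify_ramachandran(phi, psi)
                if cls.label == "favored":
                    assert any(
                        path.contains_point((phi, psi), radius=1e-9)
                        for _, path in _CONTOURS["allowed"]
                    )


class TestSiteFlexibility:
    def test_all_favored_is_100(self, eregion):
        residues = [("N", n) for n in range(48, 52)]
        assert st.site_flexibility_report(eregion, residues) == pytest.approx(100.0)

    def test_quarter_disallowed_is_75(self):
        # 4-residue chain: three helical, one forced into a clash region
        phis = [0.0, -63.0, -63.0, 0.0, -63.0, 0.0]
        psis = [-43.0, -43.0, -43.0, 0.0, -43.0, 0.0]
        coords = build_backbone(phis, psis)
        atoms = []
        for i in range(6):
            for j, name in enumerate(("N", "CA", "C")):
                atoms.append(
                    st.Atom("A", i + 1, "", "ALA", name, name[0],
                            tuple(coords[3 * i + j]))
                )
        pct = st.site_flexibility_report(
            st.Structure(atoms), [("A", 2), ("A", 3), ("A", 4), ("A", 5)]
        )
        assert pct == pytest.approx(75.0)

    def test_permutation_invariant(self, eregion):
        residues = [("N", 48), ("P", 19), ("Q", 50), ("S", 21)]
        a = st.site_flexibility_report(eregion, residues)
        b = st.site_flexibility_report(eregion, residues[::-1])
        assert a == b

    def test_empty_list_raises(self, eregion):
        with pytest.raises(ValueError, match="empty"):
            st.site_flexibility_report(eregion, [])

    def test_no_classifiable_raises(self, eregion):
        # residues absent from the structure
        with pytest.raises(ValueError, match="classifiable"):
            st.site_flexibility_report(eregion, [("Z", 1)])


def test_rama_report_tsv(eregion, tmp_path):
    out = tmp_path / "rama.tsv"
    st.write_rama_report(eregion, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("chain\tresnum")
    assert len(lines) == eregion.n_residues() + 1
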