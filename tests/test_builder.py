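"""Backbone construction: torsion fidelity, geometry, caps, truncation, anions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cannmotif.builder import (
    IDEAL_GEOMETRY,
    build_anion,
    build_backbone,
    get_peptide,
    make_model,
    model_dihedrals,
    native_dihedrals,
    peptide_catalog,
    truncate_to_short,
)
from cannmotif.conformation import backbone_dihedrals
from cannmotif.core import (
    BackboneDihedrals,
    PeptideModel,
    ResidueSpec,
    angle_close,
    bond_angle,
    dihedral_angle,
)

torsions = st.floats(min_value=-179.99, max_value=180.0)


def _measure(structure):
    return backbone_dihedrals(structure)


class TestBuildBackbone:
    def test_table_torsions_recovered_for_all_designs(self):
        """Built models reproduce every catalogued motif torsion within 0.5 deg."""
        for pid in ("CPS224Ac", "CPS226", "CPS228"):
            structure = make_model(pid, "native")
            measured = _measure(structure)
            for i, (phi, psi) in enumerate(native_dihedrals(pid), start=1):
                assert angle_close(measured.phi[i - 1], phi, 0.5), (pid, i)
                assert angle_close(measured.psi[i - 1], psi, 0.5), (pid, i)

    def test_lys3_phi_matches_crystal_value(self):
        measured = _measure(make_model("CPS224Ac", "native"))
        assert measured.phi[2] == pytest.approx(-63.7, abs=0.5)

    def test_cps226_ala3_psi(self):
        measured = _measure(make_model("CPS226", "native"))
        assert measured.psi[2] == pytest.approx(-35.0, abs=0.5)

    @given(
        phis=st.lists(torsions, min_size=6, max_size=6),
        psis=st.lists(torsions, min_size=6, max_size=6),
    )
    @settings(max_examples=25, deadline=None)
    def test_random_torsion_round_trip(self, phis, psis):
        pep = PeptideModel(
            "rand",
            [ResidueSpec(c) for c in ("LEU", "GLY", "LYS", "AIB", "SER", "ALA")],
        )
        dih = BackboneDihedrals(phi=list(phis), psi=list(psis))
        measured = _measure(build_backbone(pep, dih))
        for a, b in zip(measured.phi, phis):
            assert angle_close(a, b, 0.5)
        for a, b in zip(measured.psi, psis):
            assert angle_close(a, b, 0.5)

    def test_trans_chain_calpha_spacing(self):
        """Fully extended trans geometry gives the classic 3.80 A CA-CA rise."""
        pep = PeptideModel("di", [ResidueSpec("ALA"), ResidueSpec("ALA")])
        dih = BackboneDihedrals(phi=[180.0] * 2, psi=[180.0] * 2)
        s = build_backbone(pep, dih)
        d = np.linalg.norm(s.atom(1, "CA").xyz - s.atom(2, "CA").xyz)
        assert d == pytest.approx(3.80, abs=0.05)

    def test_bond_lengths_are_ideal(self, native_structure):
        g = IDEAL_GEOMETRY
        s = native_structure
        for i in s.peptide_residue_indices():
            assert np.linalg.norm(
                s.atom(i, "CA").xyz - s.atom(i, "N").xyz
            ) == pytest.approx(g["N-CA"], abs=0.02)
            assert np.linalg.norm(
                s.atom(i, "C").xyz - s.atom(i, "CA").xyz
            ) == pytest.approx(g["CA-C"], abs=0.02)
            if s.has_atom(i, "H"):
                assert np.linalg.norm(
                    s.atom(i, "H").xyz - s.atom(i, "N").xyz
                ) == pytest.approx(g["N-H"], abs=0.02)

    def test_helix_is_right_handed(self):
        """Negative phi/psi helical torsions give a right-handed CA spiral."""
        s = make_model("CPS224Ac", "native")
        ca = [s.atom(i, "CA").xyz for i in range(6, 14)]
        # consecutive CA-triad torsion is positive (~+50 deg) in a right-handed helix
        tors = [dihedral_angle(*ca[k : k + 4]) for k in range(len(ca) - 4)]
        assert all(t > 0 for t in tors)

    def test_residue_content(self, native_structure):
        s = native_structure
        gly = 2  # Gly2: two alpha hydrogens, no CB
        assert s.has_atom(gly, "HA2") and s.has_atom(gly, "HA3")
        assert not s.has_atom(gly, "CB")
        aib = 6  # Aib6: two methyl carbons, no alpha hydrogen
        assert s.has_atom(aib, "CB1") and s.has_atom(aib, "CB2")
        assert not s.has_atom(aib, "HA")
        assert s.has_atom(aib, "H")  # amide H is present on Aib
        # caps
        assert s.residue_code(0) == "ACE"
        assert s.residue_code(19) == "NH2"

    def test_undefined_torsion_is_error(self):
        pep = PeptideModel("p", [ResidueSpec("ALA"), ResidueSpec("ALA")])
        dih = BackboneDihedrals(phi=[None, -60.0], psi=[-45.0, -45.0])
        with pytest.raises(ValueError, match="phi"):
            build_backbone(pep, dih)

    def test_unknown_peptide_id_is_error(self):
        with pytest.raises(KeyError, match="unknown peptide id"):
            make_model("CPS999", "native")

    def test_unknown_variant_is_error(self):
        with pytest.raises(ValueError, match="variant"):
            model_dihedrals("CPS224Ac", "zigzag")


class TestMakeModelVariants:
    def test_extended_sets_first_four_to_180(self, extended_structure):
        measured = _measure(extended_structure)
        for i in (0, 1, 2, 3):
            if i > 0:  # phi1 defined via the acetyl cap too, check all
                pass
            assert angle_close(measured.phi[i], 180.0, 0.5)
            assert angle_close(measured.psi[i], 180.0, 0.5)

    def test_anchor_helix_torsions(self, native_structure, extended_structure):
        for s in (native_structure, extended_structure):
            measured = _measure(s)
            for i in range(5, 18):  # residues 5..18 (psi18 via amide cap)
                assert angle_close(measured.phi[i - 1], -57.0, 0.5)
                assert angle_close(measured.psi[i - 1], -47.0, 0.5)

    def test_native_and_extended_differ_only_in_motif_segment(
        self, native_structure, extended_structure
    ):
        m_nat = _measure(native_structure)
        m_ext = _measure(extended_structure)
        for i in range(4, 18):
            assert angle_close(m_nat.phi[i], m_ext.phi[i], 0.5)
            assert angle_close(m_nat.psi[i], m_ext.psi[i], 0.5)
        assert not angle_close(m_nat.phi[1], m_ext.phi[1], 0.5)

    def test_experimental_like_takes_user_torsions(self):
        user = [(-80.0, 100.0), (120.0, 110.0), (-65.0, -40.0), (-60.0, -45.0)]
        s = make_model("CPS224Ac", "experimental_like", experimental=user)
        measured = _measure(s)
        for i, (phi, psi) in enumerate(user):
            assert angle_close(measured.phi[i], phi, 0.5)
            assert angle_close(measured.psi[i], psi, 0.5)


class TestTruncation:
    def test_short_design_sequence(self):
        pep = get_peptide("SCPS224Ac")
        assert pep.sequence == ["LEU", "GLY", "LYS", "GLN", "ALA"]
        assert pep.c_cap == "amide"

    def test_kept_atoms_identical_to_parent(self):
        parent = make_model("CPS224Ac", "native")
        short, short_pep = truncate_to_short(parent, get_peptide("CPS224Ac"))
        assert len(short_pep) == 5
        for a in short.atoms:
            if a.residue_code == "NH2":
                continue
            assert np.allclose(a.xyz, parent.atom(a.residue_index, a.name).xyz)
        # amide cap N coincides with residue 6 N of the parent: psi5 preserved
        assert np.allclose(short.atom(6, "N").xyz, parent.atom(6, "N").xyz)

    def test_truncating_too_short_chain_is_error(self):
        pep = PeptideModel("p4", [ResidueSpec("ALA")] * 4)
        dih = BackboneDihedrals(phi=[-57.0] * 4, psi=[-47.0] * 4)
        s = build_backbone(pep, dih)
        with pytest.raises(ValueError, match="at least 5"):
            truncate_to_short(s, pep)

    def test_all_catalog_ids_build(self):
        for pid in peptide_catalog():
            s = make_model(pid, "native")
            n_res = len(s.peptide_residue_indices())
            assert n_res == (5 if pid.startswith("S") else 18)


class TestBuildAnion:
    def test_sulfate_ideal_tetrahedron(self):
        an = build_anion("sulfate")
        for o in an.oxygens:
            assert np.linalg.norm(o.xyz - an.central.xyz) == pytest.approx(1.49, abs=1e-3)
        for i in range(4):
            for j in range(i + 1, 4):
                assert bond_angle(
                    an.oxygens[i].xyz, an.central.xyz, an.oxygens[j].xyz
                ) == pytest.approx(109.47, abs=0.1)
        assert an.hydroxyl_h is None

    def test_phosphate_has_exactly_one_hydroxyl(self):
        an = build_anion("phosphate")
        assert an.hydroxyl_h is not None
        d = np.linalg.norm(an.hydroxyl_h.xyz - an.oxygens[3].xyz)
        assert d == pytest.approx(0.96, abs=1e-3)
        for o in an.oxygens:
            assert np.linalg.norm(o.xyz - an.central.xyz) == pytest.approx(1.54, abs=1e-3)

    def test_oxygen_centroid_at_central_atom(self):
        an = build_anion("sulfate")
        centroid = np.mean([o.xyz for o in an.oxygens], axis=0)
        assert np.linalg.norm(centroid - an.central.xyz) < 1e-6

    def test_unknown_kind_is_error(self):
        with pytest.raises(ValueError, match="unknown anion"):
            build_anion("nitrate")
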