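import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactgrid import fixtures as fx
from contactgrid.classify import (
    backbone_dihedrals,
    contact_type,
    default_class_table,
    detect_disulfide,
    detect_peptide_bond,
    primary_label,
    separation_class,
    torsion_angle,
)
from contactgrid.pdb_io import parse_structure
from tests.conftest import make_sphere


def atom(res, name, pos, element=None, seq=1, chain="A", serial=1, standard=True):
    el = element or name[0]
    return make_sphere(el, pos, 1.7, serial=serial, seq=seq, chain=chain,
                       name=name, residue_name=res, standard=standard)


class TestDisulfide:
    @pytest.mark.parametrize("d,expected", [
        (2.05, True), (1.95, True), (2.1, True),   # inside incl. boundaries
        (1.90, False), (2.15, False),
    ])
    def test_distance_window(self, d, expected):
        a = atom("CYS", "SG", (0, 0, 0), "S", seq=1, serial=1)
        b = atom("CYS", "SG", (d, 0, 0), "S", seq=10, serial=2)
        assert detect_disulfide(a, b) is expected

    def test_non_cysteine_sulfur_rejected(self):
        a = atom("MET", "SD", (0, 0, 0), "S", seq=1, serial=1)
        b = atom("CYS", "SG", (2.05, 0, 0), "S", seq=2, serial=2)
        assert not detect_disulfide(a, b)


class TestPeptideBond:
    def test_canonical_bond(self):
        c = atom("ALA", "C", (0, 0, 0), "C", seq=1, serial=1)
        n = atom("GLY", "N", (1.33, 0, 0), "N", seq=2, serial=2)
        assert detect_peptide_bond(c, n)

    def test_chain_break_distance(self):
        c = atom("ALA", "C", (0, 0, 0), "C", seq=1, serial=1)
        n = atom("GLY", "N", (2.5, 0, 0), "N", seq=2, serial=2)
        assert not detect_peptide_bond(c, n)

    def test_non_adjacent_residues(self):
        c = atom("ALA", "C", (0, 0, 0), "C", seq=1, serial=1)
        n = atom("GLY", "N", (1.33, 0, 0), "N", seq=3, serial=2)
        assert not detect_peptide_bond(c, n)

    def test_different_chains(self):
        c = atom("ALA", "C", (0, 0, 0), "C", seq=1, chain="A", serial=1)
        n = atom("GLY", "N", (1.33, 0, 0), "N", seq=2, chain="B", serial=2)
        assert not detect_peptide_bond(c, n)


class TestContactType:
    def test_hb_inside_window(self):
        o = atom("ALA", "O", (0, 0, 0), "O", seq=1, serial=1)     # acceptor
        n = atom("GLY", "N", (3.0, 0, 0), "N", seq=5, serial=2)   # donor
        assert "HB" in contact_type(o, n, 3.0)

    @pytest.mark.parametrize("d,expect_hb", [
        (1.5, True), (3.5, True), (1.4, False), (3.6, False)])
    def test_hb_window_boundaries(self, d, expect_hb):
        o = atom("ALA", "O", (0, 0, 0), "O", seq=1, serial=1)
        n = atom("GLY", "N", (d, 0, 0), "N", seq=5, serial=2)
        assert ("HB" in contact_type(o, n, d)) is expect_hb

    def test_aromatic_carbons_are_arom_and_phob(self):
        a = atom("PHE", "CZ", (0, 0, 0), "C", seq=1, serial=1)
        b = atom("TYR", "CE1", (3.5, 0, 0), "C", seq=9, serial=2)
        labels = contact_type(a, b, 3.5)
        assert {"AROM", "PHOB"} <= labels

    def test_his_imidazole_aromatic_set(self):
        table = default_class_table()
        for name in ("CG", "CD2", "CE1"):
            assert table.is_aromatic(atom("HIS", name, (0, 0, 0), "C"))
        for name in ("ND1", "NE2", "CB"):
            assert not table.is_aromatic(atom("HIS", name, (0, 0, 0),
                                              "N" if name.startswith("N") else "C"))

    def test_destabilizing_contact(self):
        c = atom("LEU", "CD1", (0, 0, 0), "C", seq=1, serial=1)
        o = atom("SER", "OG", (3.0, 0, 0), "O", seq=5, serial=2)
        assert "DC" in contact_type(c, o, 3.0)

    def test_phob_pair(self):
        a = atom("LEU", "CD1", (0, 0, 0), "C", seq=1, serial=1)
        b = atom("VAL", "CG1", (3.8, 0, 0), "C", seq=5, serial=2)
        assert contact_type(a, b, 3.8) == frozenset({"PHOB"})

    def test_other_fallback(self):
        # two backbone nitrogens: donor-donor, no rule fires at 4 A
        a = atom("ALA", "N", (0, 0, 0), "N", seq=1, serial=1)
        b = atom("GLY", "N", (4.0, 0, 0), "N", seq=5, serial=2)
        assert contact_type(a, b, 4.0) == frozenset({"OTHER"})

    def test_symmetric_in_arguments(self):
        a = atom("ALA", "O", (0, 0, 0), "O", seq=1, serial=1)
        b = atom("GLY", "N", (3.0, 0, 0), "N", seq=5, serial=2)
        assert contact_type(a, b, 3.0) == contact_type(b, a, 3.0)

    def test_priority_collapse(self):
        assert primary_label({"AROM", "PHOB"}) == "AROM"
        assert primary_label({"PHOB", "DC"}) == "PHOB"
        assert primary_label(set(), covalent=True) == "Cova"
        assert primary_label(set()) == "OTHER"


class TestSeparationClass:
    @pytest.mark.parametrize("delta,label", [
        (1, "S"), (2, "S"), (3, "M"), (4, "M"), (5, "L1"), (7, "L1"),
        (10, "L1"), (11, "L2"), (20, "L2"), (21, "L3"), (30, "L3"),
        (31, "L4"), (40, "L4"), (41, "L5"), (50, "L5"), (51, "L6"),
        (200, "L6")])
    def test_partition_boundaries(self, delta, label):
        assert separation_class(("A", 10, ""), ("A", 10 + delta, "")) == label
        assert separation_class(("A", 10 + delta, ""), ("A", 10, "")) == label

    def test_inter_chain(self):
        assert separation_class(("A", 5, ""), ("B", 5, "")) == "I"

    def test_same_residue_rejected(self):
        with pytest.raises(ValueError):
            separation_class(("A", 5, ""), ("A", 5, ""))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(sa=st.integers(-50, 300), sb=st.integers(-50, 300),
           same_chain=st.booleans())
    def test_exactly_one_label(self, sa, sb, same_chain):
        if same_chain and sa == sb:
            return
        label = separation_class(("A", sa, ""), ("A" if same_chain else "B", sb, ""))
        assert label in ("S", "M", "L1", "L2", "L3", "L4", "L5", "L6", "I")
        if not same_chain:
            assert label == "I"


def torsion_oracle(p0, p1, p2, p3):
    """Independent formula: project the outer bonds onto the plane normal to
    the central bond and take the signed angle between the projections."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p0 - p1
    b2 = p2 - p1
    b3 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    u = b1 - np.dot(b1, b2n) * b2n
    w = b3 - np.dot(b3, b2n) * b2n
    return math.degrees(math.atan2(np.dot(np.cross(u, w), b2n), np.dot(u, w)))


class TestDihedrals:
    @pytest.mark.parametrize("pts", [
        [(1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)],       # 0 deg
        [(1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)],      # 180 deg
        [(1, 0, 0), (0, 0, 0), (0, 1, 0), (0.3, 1, 0.8)],
        [(1.2, -0.5, 0.3), (0, 0, 0), (0.1, 1.4, 0), (1.0, 1.8, -0.9)],
    ])
    def test_matches_independent_oracle(self, pts):
        got = torsion_angle(*pts)
        want = torsion_oracle(*pts)
        # compare as angles (180 == -180)
        diff = (got - want + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6

    def test_collinear_is_nan(self):
        assert math.isnan(torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)))

    def test_tripeptide_terminal_rules(self, tmp_path):
        p = tmp_path / "pep.pdb"
        p.write_text(fx.make_tripeptide_pdb())
        model = parse_structure(p).models[0]
        angles = backbone_dihedrals(model)
        phi1, psi1 = angles[("A", 1, "")]
        phi2, psi2 = angles[("A", 2, "")]
        phi3, psi3 = angles[("A", 3, "")]
        assert math.isnan(phi1) and not math.isnan(psi1)   # N-terminus
        assert not math.isnan(phi2) and not math.isnan(psi2)
        assert not math.isnan(phi3) and math.isnan(psi3)   # C-terminus

    def test_tripeptide_angles_match_oracle(self, tmp_path):
        p = tmp_path / "pep.pdb"
        p.write_text(fx.make_tripeptide_pdb())
        model = parse_structure(p).models[0]
        bb = {(a.residue_seq, a.name): a.position for a in model}
        angles = backbone_dihedrals(model)
        want_phi2 = torsion_oracle(bb[(1, "C")], bb[(2, "N")],
                                   bb[(2, "CA")], bb[(2, "C")])
        got = angles[("A", 2, "")][0]
        diff = (got - want_phi2 + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-6

    def test_non_standard_residue_undefined(self):
        atoms = [
            atom("HEM", "N", (0, 0, 0), "N", seq=1, serial=1, standard=False),
            atom("HEM", "CA", (1.5, 0, 0), "C", seq=1, serial=2, standard=False),
            atom("HEM", "C", (2.0, 1.4, 0), "C", seq=1, serial=3, standard=False),
        ]
        angles = backbone_dihedrals(atoms)
        phi, psi = angles[("A", 1, "")]
        assert math.isnan(phi) and math.isnan(psi)
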