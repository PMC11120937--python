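import gzip
import itertools
import random

import pandas as pd
import pytest

from contactgrid import fixtures as fx
from contactgrid.aggregate import (
    AnalysisOptions,
    analyze_model,
    apply_cutoff,
    classify_records,
    process_structure,
    records_frame,
    residue_pair_totals,
    residue_summaries,
    write_all_csv,
    write_res_csv,
    write_sum_csv,
)
from contactgrid.contact_core import ContactRecord
from contactgrid.pdb_io import parse_structure
from tests.conftest import make_sphere


def record(seq_a, seq_b, S=1.0, V=1.0, V0=None, serial_a=None, serial_b=None,
           d=3.0):
    a = make_sphere("O", (0, 0, 0), 1.52, serial=serial_a or seq_a * 10,
                    seq=seq_a)
    b = make_sphere("N", (d, 0, 0), 1.55, serial=serial_b or seq_b * 10 + 1,
                    seq=seq_b)
    return ContactRecord(atom_a=a, atom_b=b, center_distance=d, S=S, V=V,
                         V0=V0, separation_class="S")


class TestResiduePairTotals:
    def test_sums_atom_contacts(self):
        recs = [record(1, 2, S=1.0, V=1.25), record(1, 2, S=2.0, V=2.50)]
        (summary,) = residue_pair_totals(recs)
        assert summary.Vr == pytest.approx(3.75)
        assert summary.Sr == pytest.approx(3.0)
        assert summary.n_atom_pairs == 2

    def test_no_contacts_no_rows(self):
        assert residue_pair_totals([]) == []

    def test_permutation_invariance_bit_exact(self):
        base = [record(1, 2, S=0.1 * k, V=0.07 * k, serial_a=k * 2,
                       serial_b=k * 2 + 101) for k in range(1, 8)]
        ref = residue_pair_totals(list(base))
        for seed in (0, 1, 2):
            shuffled = list(base)
            random.Random(seed).shuffle(shuffled)
            got = residue_pair_totals(shuffled)
            assert got[0].Sr == ref[0].Sr    # bit-exact, not approx
            assert got[0].Vr == ref[0].Vr


class TestApplyCutoff:
    def test_boundary_inclusive(self):
        recs = [record(1, 2, V=v) for v in (0.1, 0.25, 0.9)]
        assert len(apply_cutoff(recs, min_volume=0.25)) == 2

    def test_zero_thresholds_identity(self):
        recs = [record(1, 2, V=v) for v in (0.0, 0.1)]
        assert apply_cutoff(recs) == recs

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_cutoff([], min_area=-1.0)

    def test_matches_brute_force_filter(self):
        rng = random.Random(7)
        recs = [record(1, 2, S=rng.uniform(0, 2), V=rng.uniform(0, 1))
                for _ in range(40)]
        got = apply_cutoff(recs, 0.5, 0.25)
        brute = [r for r in recs if r.S >= 0.5 and r.V >= 0.25]
        assert got == brute


ALL_FLAGS = list(itertools.product([False, True], repeat=3))  # (-a, -w, -s)


class TestColumnContracts:
    @pytest.mark.parametrize("use_sasa,use_aowv,surface_only", ALL_FLAGS)
    def test_all_csv_headers(self, tmp_path, use_sasa, use_aowv, surface_only):
        opts = AnalysisOptions(sasa=use_sasa, aowv=use_aowv,
                               surface_only=surface_only)
        recs = classify_records([record(1, 2, V0=2.0 if use_aowv else None)])
        if surface_only:
            for r in recs:
                r.V = None
        path = write_all_csv(recs, tmp_path / "x_ALL.csv", opts)
        cols = list(pd.read_csv(path).columns)
        assert cols[:6] == ["Residue1", "Atom1", "Type1",
                            "Residue2", "Atom2", "Type2"]
        assert ("Volume" in cols) is (not surface_only)
        assert ("AOWV" in cols) is use_aowv
        assert cols[-2:] == ["Contact", "Class"]

    @pytest.mark.parametrize("use_sasa,use_aowv,surface_only", ALL_FLAGS)
    def test_sum_csv_headers(self, tmp_path, use_sasa, use_aowv, surface_only):
        opts = AnalysisOptions(sasa=use_sasa, aowv=use_aowv,
                               surface_only=surface_only)
        recs = classify_records([record(1, 2, V0=2.0 if use_aowv else None)])
        atoms = [recs[0].atom_a, recs[0].atom_b]
        table = residue_summaries(atoms, recs, {}, opts)
        path = write_sum_csv(table, tmp_path / "x_SUM.csv", opts)
        cols = list(pd.read_csv(path).columns)
        assert cols[:3] == ["Residue", "Phi", "Psi"]
        assert ("SASA" in cols) is use_sasa
        assert ("Cova_AOWV" in cols) is use_aowv
        assert ("NC_AOWV" in cols) is use_aowv
        assert ("Cova_Volu" in cols) is (not surface_only)
        assert ("NC_Volu" in cols) is (not surface_only)
        assert "UNDEF_Area" in cols

    @pytest.mark.parametrize("use_aowv,surface_only",
                             [(False, False), (True, False), (False, True),
                              (True, True)])
    def test_res_csv_headers(self, tmp_path, use_aowv, surface_only):
        opts = AnalysisOptions(aowv=use_aowv, surface_only=surface_only)
        recs = classify_records([record(1, 2, V0=2.0 if use_aowv else None)])
        if surface_only:
            for r in recs:
                r.V = None
        path = write_res_csv(residue_pair_totals(recs), tmp_path / "x_RES.csv",
                             opts)
        cols = list(pd.read_csv(path).columns)
        assert cols[:3] == ["Residue1", "Residue2", "Class"]
        assert ("Volume" in cols) is (not surface_only)
        assert ("AOWV" in cols) is use_aowv

    def test_empty_contacts_header_only(self, tmp_path):
        path = write_res_csv([], tmp_path / "empty_RES.csv")
        df = pd.read_csv(path)
        assert len(df) == 0
        assert list(df.columns) == ["Residue1", "Residue2", "Class", "Area",
                                    "Volume"]


class TestSerialization:
    def test_round_trip_at_serialized_precision(self, tmp_path):
        recs = classify_records([record(1, 2, S=1.23456, V=0.98765)])
        path = write_all_csv(recs, tmp_path / "x_ALL.csv")
        df = pd.read_csv(path)
        assert df.loc[0, "Area"] == pytest.approx(1.2346, abs=1e-9)
        assert df.loc[0, "Volume"] == pytest.approx(0.9877, abs=1e-9)

    def test_gzip_output_reads_back_identical(self, tmp_path):
        opts = AnalysisOptions(compress=True)
        recs = classify_records([record(1, 2)])
        path = write_all_csv(recs, tmp_path / "x_ALL.csv", opts)
        assert path.suffix == ".gz"
        plain = write_all_csv(recs, tmp_path / "y_ALL.csv")
        pd.testing.assert_frame_equal(pd.read_csv(path), pd.read_csv(plain))

    def test_non_standard_residue_underscored(self, tmp_path):
        a = make_sphere("C", (0, 0, 0), 1.7, serial=1, seq=200,
                        residue_name="HEM", standard=False)
        b = make_sphere("N", (3.0, 0, 0), 1.55, serial=2, seq=1)
        recs = classify_records([ContactRecord(atom_a=a, atom_b=b,
                                               center_distance=3.0, S=1.0,
                                               V=1.0)])
        df = records_frame(recs)
        labels = set(df["Residue1"]) | set(df["Residue2"])
        assert any("HEM_" in lab for lab in labels)

    def test_ambiguous_hetero_link_is_undef(self):
        a = make_sphere("C", (0, 0, 0), 1.7, serial=1, seq=200,
                        residue_name="HEM", standard=False)
        b = make_sphere("N", (1.8, 0, 0), 1.55, serial=2, seq=1)
        (rec,) = classify_records([ContactRecord(atom_a=a, atom_b=b,
                                                 center_distance=1.8, S=1.0,
                                                 V=1.0)])
        assert rec.attribution == "UNDEF"


class TestPipeline:
    def test_residue_totals_consistent_with_all_rows(self, tmp_path):
        p = tmp_path / "pep.pdb"
        p.write_text(fx.make_tripeptide_pdb())
        atoms = parse_structure(p).models[0]
        records, pairs, table = analyze_model(atoms, AnalysisOptions())
        assert records and pairs
        # Sr equals the hand-sum of the _ALL rows per residue pair
        for pair in pairs:
            hand = sum(r.S for r in records
                       if {r.atom_a.residue_id, r.atom_b.residue_id}
                       == {pair.residue_a, pair.residue_b})
            assert pair.Sr == hand
        # covalent peptide links present and labelled
        assert any(r.covalent for r in records)

    def test_process_structure_multi_model_layout(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(fx.make_pdb_text(
            [fx.ToyAtom("O", "O", "ALA", 1, position=(0, 0, 0)),
             fx.ToyAtom("N", "N", "ALA", 2, position=(3, 0, 0))],
            n_models=2, displacements=[(0, 0, 0), (0.3, 0, 0)]))
        folder = process_structure(pdb, tmp_path / "out", AnalysisOptions())
        for k in (1, 2):
            sub = folder / f"model_{k}"
            for suffix in ("ALL", "SUM", "RES"):
                assert (sub / f"toy_{suffix}.csv").exists()

    def test_single_model_layout_and_per_residue(self, tmp_path):
        pdb = tmp_path / "pep.pdb"
        pdb.write_text(fx.make_tripeptide_pdb())
        opts = AnalysisOptions(per_residue=True)
        folder = process_structure(pdb, tmp_path / "out", opts)
        assert (folder / "pep_ALL.csv").exists()
        residues = list((folder / "residues").glob("*.csv"))
        assert len(residues) == 3
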