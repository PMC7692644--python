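import csv

import pytest
from rdkit import Chem
from hypothesis import given, settings, strategies as st

from npscreen import chemio
from npscreen.chemio import (
    FormatError,
    Molecule,
    RelationalRecord,
    SmilesParseError,
    canonicalize,
    is_valid,
    read_relational_table,
    structure_key,
    write_relational_table,
)
from npscreen.fixtures import SCAFFOLDS


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("OCC", "CCO"),
            ("CCO", "CCO"),
            ("C1=CC=CC=C1", "c1ccccc1"),
        ],
    )
    def test_known_forms(self, raw, expected):
        assert canonicalize(raw) == expected

    def test_unparsable_raises(self):
        with pytest.raises(SmilesParseError):
            canonicalize("C(")

    @pytest.mark.parametrize("smiles", SCAFFOLDS)
    def test_idempotent_on_scaffold_library(self, smiles):
        once = canonicalize(smiles)
        assert canonicalize(once) == once


class TestValidity:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("CCO", True), ("C(", False), ("", False), ("not smiles", False)],
    )
    def test_is_valid(self, smiles, expected):
        assert is_valid(smiles) is expected


class TestStructureKey:
    def test_frozen_ethanol_key(self):
        assert structure_key("CCO") == "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"

    def test_respelling_invariance(self):
        assert structure_key("OCC") == structure_key("CCO")

    def test_invalid_raises(self):
        with pytest.raises(SmilesParseError):
            structure_key("C(")

    def test_key_is_27_characters(self):
        assert len(structure_key("c1ccccc1")) == 27

    @pytest.mark.parametrize("smiles", SCAFFOLDS[:12])
    def test_invariant_under_random_atom_order(self, smiles, rng):
        mol = Chem.MolFromSmiles(smiles)
        reference = structure_key(smiles)
        for _ in range(3):
            respelled = Chem.MolToSmiles(
                mol, doRandom=True, canonical=False
            )
            assert structure_key(respelled) == reference


def _write_rows(path, rows):
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "source_name", "smiles", "reference"])
        w.writerows(rows)


class TestRelationalTable:
    def test_groups_and_drops_invalid(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        _write_rows(p, [
            ["S1", "Alpha", "CCO", "ref1"],
            ["S1", "Alpha", "c1ccccc1", "ref2"],
            ["S1", "Alpha", "C(", "ref3"],
        ])
        records = read_relational_table(p)
        assert len(records) == 1
        assert len(records[0].compounds) == 2
        assert "dropping invalid SMILES" in caplog.text

    def test_dedup_by_structure_key(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_rows(p, [
            ["S1", "Alpha", "CCO", "a"],
            ["S1", "Alpha", "OCC", "b"],
        ])
        (record,) = read_relational_table(p)
        assert len(record.compounds) == 1
        assert record.references[0] == "a; b"  # merged on dedup

    def test_two_sources_two_records(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_rows(p, [
            ["S1", "Alpha", "CCO", ""],
            ["S2", "Beta", "CCN", ""],
        ])
        assert len(read_relational_table(p)) == 2

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("source_id,smiles\nS1,CCO\n")
        with pytest.raises(FormatError, match="source_name"):
            read_relational_table(p)

    def test_empty_file_is_empty_collection(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("")
        assert read_relational_table(p) == []

    def test_round_trip_lossless(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        _write_rows(p1, [
            ["S1", "Alpha", "CCO", "r1"],
            ["S1", "Alpha", "c1ccccc1", "r2"],
            ["S2", "Beta", "CC(=O)O", "r3"],
        ])
        records = read_relational_table(p1)
        write_relational_table(records, p2)
        again = read_relational_table(p2)
        as_tuples = lambda recs: [
            (r.source_id, r.source_name,
             tuple(m.structure_key for m in r.compounds), tuple(r.references))
            for r in recs
        ]
        assert as_tuples(records) == as_tuples(again)


class TestCandidateReport:
    def _case(self, sid="S1", np_s="O=C(O)c1ccccc1", art="COC(=O)c1ccccc1"):
        from npscreen.screening import CandidateCase
        from npscreen.templates import ReactionClass

        return CandidateCase(
            source_id=sid,
            source_name="Alpha",
            natural_product=Molecule.from_smiles(np_s),
            artifact=Molecule.from_smiles(art),
            reaction_class=ReactionClass.METHANOL,
            predictor_provenance="rules",
            reference="ref",
        )

    def test_empty_report_is_header_only(self, tmp_path):
        p = tmp_path / "cases.csv"
        chemio.write_candidate_report([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("source_id,")

    def test_rows_sorted_and_round_trip(self, tmp_path):
        p = tmp_path / "cases.csv"
        c1 = self._case(sid="S2")
        c2 = self._case(sid="S1")
        chemio.write_candidate_report([c1, c2], p)
        rows = chemio.read_candidate_report(p)
        assert [r["source_id"] for r in rows] == ["S1", "S2"]
        assert rows[0]["artifact_smiles"] == "COC(=O)c1ccccc1"
        assert rows[0]["reaction_class"] == "methanol"


@settings(max_examples=30, deadline=None)
@given(st.sampled_from(SCAFFOLDS))
def test_canonical_form_is_fixed_point_of_respelling(smiles):
    """Any respelling of a structure canonicalizes back to one string."""
    mol = Chem.MolFromSmiles(smiles)
    respelled = Chem.MolToSmiles(mol, doRandom=True, canonical=False)
    assert canonicalize(respelled) == canonicalize(smiles)


def test_record_add_keeps_first_occurrence():
    rec = RelationalRecord("S1", "Alpha")
    rec.add(Molecule.from_smiles("CCO"), "first")
    rec.add(Molecule.from_smiles("OCC"), "second")
    assert len(rec.compounds) == 1
    assert rec.compounds[0].canonical_smiles == "CCO"
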