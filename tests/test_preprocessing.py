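"""Cleaning pipeline, corpus construction and vectorization contracts."""

import numpy as np
import pytest
from rdkit import Chem

from molforge.preprocessing import (ChemCorpus, MoleculeRecord, Rejection,
                                    SPECIALS, build_corpus, clean_smiles,
                                    decode_tokens, preprocess_smiles,
                                    read_molecule_file, vectorize_batch)


def canonical(s):
    return Chem.MolToSmiles(Chem.MolFromSmiles(s), isomericSmiles=False)


class TestCleanSmiles:
    def test_clean_single_fragment_unchanged(self):
        rec = clean_smiles("c1ccccc1")
        assert isinstance(rec, MoleculeRecord)
        assert rec.canonical_smiles == canonical("c1ccccc1")

    def test_salt_is_stripped_and_neutralized(self):
        # largest fragment (acetate) chosen, then uncharged to acetic acid
        rec = clean_smiles("CC(=O)[O-].[Na+]")
        assert isinstance(rec, MoleculeRecord)
        assert rec.canonical_smiles == canonical("CC(=O)O")

    def test_unparseable_input_is_rejected_with_reason(self):
        rej = clean_smiles("C1CC")
        assert isinstance(rej, Rejection)
        assert rej.reason == "parse_failure"

    def test_grammar_unrepresentable_is_rejected(self):
        rej = clean_smiles("C[Si](C)C")
        assert isinstance(rej, Rejection)
        assert rej.reason == "selfies_encoding_failure"

    def test_isomeric_information_is_dropped(self):
        rec = clean_smiles("C[C@H](N)C(=O)O")
        assert "@" not in rec.canonical_smiles

    def test_cleaning_is_idempotent(self):
        rec = clean_smiles("CC(=O)[O-].[Na+]")
        again = clean_smiles(rec.canonical_smiles)
        assert again.canonical_smiles == rec.canonical_smiles

    def test_record_tokens_decode_back_to_canonical(self):
        rec = clean_smiles("COC1=CC=C(Br)C=C1C(=O)NC2=CC=C(F)C=C2")
        from molforge import grammar
        assert grammar.decode_tokens(rec.selfies_tokens) == rec.canonical_smiles


class TestCorpus:
    def test_union_of_tokens_plus_three_specials(self):
        records = [
            MoleculeRecord("x", "x", ("[C]", "[=C]")),
            MoleculeRecord("y", "y", ("[Ring1]", "[=Branch1]" if False else "[Branch1]", "[C]")),
        ]
        corpus = build_corpus(records)
        assert corpus.size_c == 4 + 3
        assert corpus.tokens[:3] == SPECIALS

    def test_specials_occupy_fixed_indices(self):
        corpus = build_corpus([MoleculeRecord("x", "x", ("[C]",))])
        assert (corpus.start_idx, corpus.pad_idx, corpus.end_idx) == (0, 1, 2)

    def test_duplicates_do_not_change_the_corpus(self):
        rec = MoleculeRecord("x", "x", ("[C]", "[O]"))
        assert build_corpus([rec]) == build_corpus([rec, rec, rec])

    def test_deterministic_lexicographic_ordering(self):
        r1 = MoleculeRecord("a", "a", ("[O]", "[C]"))
        r2 = MoleculeRecord("b", "b", ("[C]", "[O]"))
        assert build_corpus([r1, r2]).tokens == build_corpus([r2, r1]).tokens

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_corpus([])

    def test_json_round_trip(self, tmp_path):
        corpus = build_corpus([MoleculeRecord("x", "x", ("[C]", "[N]"))])
        corpus.to_json(tmp_path / "c.json")
        assert ChemCorpus.from_json(tmp_path / "c.json") == corpus


class TestVectorize:
    @pytest.fixture()
    def corpus(self):
        return build_corpus([MoleculeRecord("x", "x", ("[C]", "[N]", "[O]"))])

    def test_width_is_longest_plus_two(self, corpus):
        recs = [MoleculeRecord("a", "a", ("[C]",) * 3),
                MoleculeRecord("b", "b", ("[N]",) * 5)]
        batch = vectorize_batch(recs, corpus)
        assert batch.matrix.shape == (2, 7)
        assert batch.l == 5

    def test_row_structure_start_payload_end_pad(self, corpus):
        recs = [MoleculeRecord("a", "a", ("[C]", "[N]")),
                MoleculeRecord("b", "b", ("[O]",) * 4)]
        batch = vectorize_batch(recs, corpus)
        row = batch.matrix[0]
        assert row[0] == corpus.start_idx
        assert list(row).count(corpus.end_idx) == 1
        end_pos = list(row).index(corpus.end_idx)
        assert all(v == corpus.pad_idx for v in row[end_pos + 1:])

    def test_single_molecule_has_no_padding(self, corpus):
        batch = vectorize_batch([MoleculeRecord("a", "a", ("[C]", "[N]"))], corpus)
        assert batch.matrix.shape == (1, 4)
        assert corpus.pad_idx not in batch.matrix

    def test_identical_molecules_give_identical_rows(self, corpus):
        rec = MoleculeRecord("a", "a", ("[C]", "[O]", "[N]"))
        batch = vectorize_batch([rec, rec, rec], corpus)
        assert (batch.matrix == batch.matrix[0]).all()

    def test_out_of_vocabulary_token_names_the_token(self, corpus):
        rec = MoleculeRecord("a", "a", ("[S]",))
        with pytest.raises(KeyError, match=r"\[S\]"):
            vectorize_batch([rec], corpus)

    def test_decode_inverts_vectorization(self, corpus):
        rec = clean_smiles("CC=O")
        full = build_corpus([rec])
        batch = vectorize_batch([rec], full)
        assert decode_tokens(batch.matrix[0], full) == rec.canonical_smiles

    def test_decode_rejects_out_of_range_indices(self, corpus):
        with pytest.raises(IndexError):
            decode_tokens([corpus.size_c + 1], corpus)


class TestFileIO:
    def test_smi_file_with_ids(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\tmol1\nc1ccccc1 mol2\n\n")
        assert read_molecule_file(p) == ["CCO", "c1ccccc1"]

    def test_csv_with_smiles_header(self, tmp_path):
        p = tmp_path / "in.csv"
        p.write_text("id,smiles\n1,CCO\n2,CCN\n")
        assert read_molecule_file(p) == ["CCO", "CCN"]

    def test_csv_without_smiles_column_is_an_error(self, tmp_path):
        p = tmp_path / "in.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_molecule_file(p)

    def test_rejections_are_counted_not_fatal(self):
        records, report = preprocess_smiles(["CCO", "C1CC", "not-a-molecule"])
        assert report.n_kept == 1
        assert report.rejections["parse_failure"] == 2
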