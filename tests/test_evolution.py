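"""Molecule evolution: similarity primitives, mutation and the greedy walk."""

import numpy as np
import pytest
from rdkit import Chem

from molforge import grammar
from molforge.evolution import (EvolutionConfig, evolve, joint_similarity,
                                mutate_selfies, path_report,
                                select_evolution_target, tanimoto)
from molforge.fixtures import bundled_drugs
from molforge.metrics import SampleSet


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EvolutionConfig(stop_similarity=0.0)
        with pytest.raises(ValueError):
            EvolutionConfig(max_token_edits=0)
        with pytest.raises(ValueError):
            EvolutionConfig(joint_mode="max")


class TestSimilarity:
    def test_self_similarity_is_one(self):
        assert tanimoto("CCO", "CCO") == 1.0

    def test_symmetric(self):
        assert tanimoto("CCO", "c1ccccc1") == tanimoto("c1ccccc1", "CCO")

    def test_in_unit_interval(self):
        assert 0.0 <= tanimoto("CCO", "c1ccccc1") <= 1.0

    def test_joint_similarity_at_endpoints(self):
        # m == start == end: both similarities 1, gap 0
        assert joint_similarity("CCO", "CCO", "CCO") == 1.0

    def test_joint_penalizes_one_sided(self):
        # identical to start, dissimilar to end: (1+t)/2 - (1-t) < min(1,t)+eps
        val = joint_similarity("CCO", "CCO", "c1ccc(I)cc1")
        assert val < 0.5

    def test_min_mode(self):
        a, b, m = "CCO", "c1ccccc1", "CCO"
        assert joint_similarity(m, a, b, mode="min") == min(
            tanimoto(m, a), tanimoto(m, b))


class TestTargetSelection:
    def test_picks_highest_qed_in_window(self):
        ma97 = bundled_drugs()["Ma97"]
        sample = SampleSet([ma97, "CCO", "C"])  # decoys: much lower QED
        cfg = EvolutionConfig(logp_window=(0.0, 5.0))
        assert select_evolution_target(sample, cfg) == Chem.MolToSmiles(
            Chem.MolFromSmiles(ma97), isomericSmiles=False)

    def test_single_passing_molecule(self):
        # benzene: Lipinski-passing, logP about 1.7 inside the window
        # (ethanol would fail: its Crippen logP is slightly negative)
        sample = SampleSet(["c1ccccc1"])
        assert select_evolution_target(sample, EvolutionConfig()) == "c1ccccc1"

    def test_logp_window_filters(self):
        sample = SampleSet(["CCO"])  # logP about -0.0014
        cfg = EvolutionConfig(logp_window=(2.0, 5.0))
        with pytest.raises(ValueError, match="widen"):
            select_evolution_target(sample, cfg)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            select_evolution_target(SampleSet(["zz"]), EvolutionConfig())


class TestMutation:
    ALPHABET = list(grammar.ATOM_TOKENS)

    def test_zero_edits_is_identity(self):
        toks = ["[C]", "[O]"]
        rng = np.random.default_rng(0)
        assert mutate_selfies(toks, self.ALPHABET, 0, rng) == toks

    def test_edit_distance_bounded(self):
        rng = np.random.default_rng(1)
        toks = ["[C]"] * 6
        for _ in range(50):
            out = mutate_selfies(toks, self.ALPHABET, 2, rng)
            assert abs(len(out) - len(toks)) <= 2

    def test_output_always_decodes(self):
        rng = np.random.default_rng(2)
        toks = ["[C]", "[O]", "[N]"]
        for _ in range(100):
            out = mutate_selfies(toks, self.ALPHABET, 2, rng)
            smi = grammar.decode_tokens(out)
            assert smi == "" or Chem.MolFromSmiles(smi) is not None

    def test_never_empties_the_string(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert mutate_selfies(["[C]"], self.ALPHABET, 1, rng)

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            mutate_selfies(["[C]"], [], 1, np.random.default_rng(0))


class TestEvolve:
    def test_start_equals_end_is_length_one_converged(self):
        path = evolve("CCO", "CCO")
        assert len(path) == 1
        assert path.converged
        assert path.steps[0].sim_to_end == 1.0

    def test_one_token_apart_converges(self):
        start = grammar.decode_tokens(["[C]", "[C]", "[O]"])
        end = grammar.decode_tokens(["[C]", "[C]", "[N]", "[O]"])
        cfg = EvolutionConfig(max_steps=10, candidates_per_step=300,
                              stop_similarity=1.0, seed=0)
        path = evolve(start, end, cfg)
        assert path.converged
        assert path.steps[-1].molecule == end

    def test_similarity_to_end_is_monotone(self):
        cfg = EvolutionConfig(max_steps=15, candidates_per_step=60, seed=4)
        path = evolve("CCO", bundled_drugs()["aspirin"], cfg)
        sims = [s.sim_to_end for s in path.steps]
        assert all(a <= b for a, b in zip(sims, sims[1:]))

    def test_deterministic_under_seed(self):
        cfg = EvolutionConfig(max_steps=5, candidates_per_step=40, seed=9)
        p1 = evolve("CCO", "c1ccccc1", cfg)
        p2 = evolve("CCO", "c1ccccc1", cfg)
        assert [s.molecule for s in p1.steps] == [s.molecule for s in p2.steps]

    def test_every_path_member_is_valid(self):
        cfg = EvolutionConfig(max_steps=8, candidates_per_step=60, seed=2)
        path = evolve("CCO", bundled_drugs()["benzene"], cfg)
        for step in path.steps:
            assert Chem.MolFromSmiles(step.molecule) is not None
            assert 0.0 <= step.sim_to_start <= 1.0
            assert 0.0 <= step.sim_to_end <= 1.0

    def test_unencodable_start_rejected(self):
        with pytest.raises(grammar.EncodingError):
            evolve("C[Si](C)C", "CCO")


class TestPathReport:
    def test_length_one_path_gives_one_unflagged_row(self):
        path = evolve("CCO", "CCO")
        df = path_report(path)
        assert len(df) == 1
        assert not df.loc[0, "better_than_start"]  # equal-to-start is false

    def test_csv_written(self, tmp_path):
        path = evolve("CCO", "CCO")
        out = tmp_path / "path.csv"
        path_report(path, out=str(out))
        assert out.read_text().startswith("step,smiles,")

    def test_empty_path_rejected(self):
        from molforge.evolution import EvolutionPath
        with pytest.raises(ValueError):
            path_report(EvolutionPath())
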