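"""Policy-gradient fine-tuning: surrogate loss, rollouts, schedule, monitor."""

import numpy as np
import pytest
from rdkit import Chem

from molforge.rl import (CollapseMonitor, DivergenceError, EpisodeBatch,
                         RLConfig, monitor_report, policy_loss, rl_run,
                         rollout)
from molforge.scoring import atom_count_scorer, constant_scorer


class TestConfig:
    def test_direction_validated(self):
        with pytest.raises(ValueError):
            RLConfig(direction="up")

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            RLConfig(epochs=0)


class TestRollout:
    def test_shapes_and_valid_molecules(self, pretrained):
        model, corpus = pretrained
        batch = rollout(model, corpus, 25, rng=3)
        assert len(batch.sequences) == len(batch.molecules) == 25
        assert batch.logps.shape == batch.rewards.shape == (25,)
        assert (batch.rewards == 0).all()  # unscored until score_batch
        for smi in batch.molecules:
            assert smi and Chem.MolFromSmiles(smi) is not None

    def test_seeded_rollout_is_deterministic(self, pretrained):
        model, corpus = pretrained
        a = rollout(model, corpus, 10, rng=7)
        b = rollout(model, corpus, 10, rng=7)
        assert a.molecules == b.molecules
        np.testing.assert_array_equal(a.logps, b.logps)

    def test_n_validated(self, pretrained):
        model, corpus = pretrained
        with pytest.raises(ValueError):
            rollout(model, corpus, 0)


class TestPolicyLoss:
    def _batch(self):
        return EpisodeBatch(sequences=[[3], [4]], molecules=["C", "N"],
                            logps=np.array([-1.0, -2.0]),
                            rewards=np.array([2.0, 4.0]))

    def test_positive_is_negative_mean_reward_weighted_logp(self):
        # -(1/2) * (2*-1 + 4*-2) = 5
        assert policy_loss(self._batch(), "positive") == 5.0

    def test_negative_is_exact_negation(self):
        b = self._batch()
        assert policy_loss(b, "negative") == -policy_loss(b, "positive")

    def test_zero_rewards_give_zero_loss(self):
        b = self._batch()
        b.rewards = np.zeros(2)
        assert policy_loss(b, "positive") == 0.0

    def test_empty_batch_rejected(self):
        b = EpisodeBatch([], [], np.zeros(0), np.zeros(0))
        with pytest.raises(ValueError):
            policy_loss(b, "positive")


def _marker_fraction(model, corpus, n=300, seed=99):
    from molforge.generator import sample_batch
    pairs = sample_batch(model, corpus, n, rng=seed)
    hits = 0
    for smi, _ in pairs:
        mol = Chem.MolFromSmiles(smi)
        if any(a.GetSymbol() == "N" for a in mol.GetAtoms()):
            hits += 1
    return hits / n


class TestRlRun:
    def test_short_run_updates_parameters_and_fills_monitor(self, pretrained_copy):
        model, corpus = pretrained_copy
        before = {k: v.copy() for k, v in model.params.items()}
        cfg = RLConfig(direction="positive", molecules_per_step=5,
                       steps_per_epoch=2, epochs=2, learning_rate=1e-3, seed=0)
        scorer = atom_count_scorer("N", per_atom=10.0, offset=-5.0)
        model, monitor = rl_run(model, corpus, scorer, cfg)
        assert any(not np.array_equal(before[k], model.params[k])
                   for k in before)
        assert len(monitor.duplicate_fraction) == 2
        assert len(monitor.mean_reward) == 2
        assert all(0.0 <= d <= 1.0 for d in monitor.duplicate_fraction)
        assert all(t > 0 for t in monitor.distinct_tokens)

    def test_positive_direction_raises_marker_frequency(self, pretrained_copy):
        model, corpus = pretrained_copy
        before = _marker_fraction(model, corpus)
        scorer = atom_count_scorer("N", per_atom=300.0, offset=-150.0)
        cfg = RLConfig(direction="positive", molecules_per_step=10,
                       steps_per_epoch=10, epochs=3, learning_rate=2e-3,
                       truncate=False, seed=1)
        model, _ = rl_run(model, corpus, scorer, cfg)
        assert _marker_fraction(model, corpus) > before

    def test_negative_direction_lowers_marker_frequency(self, pretrained_copy):
        model, corpus = pretrained_copy
        before = _marker_fraction(model, corpus)
        scorer = atom_count_scorer("N", per_atom=300.0, offset=-150.0)
        cfg = RLConfig(direction="negative", molecules_per_step=10,
                       steps_per_epoch=10, epochs=3, learning_rate=2e-3,
                       truncate=False, seed=1)
        model, _ = rl_run(model, corpus, scorer, cfg)
        assert _marker_fraction(model, corpus) < before

    def test_all_excluded_rewards_leave_model_unchanged(self, pretrained_copy):
        model, corpus = pretrained_copy
        before = {k: v.copy() for k, v in model.params.items()}
        cfg = RLConfig(direction="positive", molecules_per_step=5,
                       steps_per_epoch=2, epochs=1, learning_rate=1e-2, seed=0)
        # raw 200 > truncation threshold: every molecule excluded
        model, monitor = rl_run(model, corpus, constant_scorer(200.0), cfg)
        assert all(np.array_equal(before[k], model.params[k]) for k in before)
        assert monitor.mean_reward == [0.0]

    def test_divergence_guard_trips_when_bound_exceeded(self, pretrained_copy):
        model, corpus = pretrained_copy
        # any sampled batch has mean |log p| well above 1 nat, so the guard
        # must fire on the first step
        cfg = RLConfig(direction="positive", molecules_per_step=5,
                       steps_per_epoch=20, epochs=5, learning_rate=1e-3,
                       max_logp_bound=1.0, truncate=False, seed=0)
        with pytest.raises(DivergenceError):
            rl_run(model, corpus, constant_scorer(100.0), cfg)


class TestMonitorReport:
    def test_table_and_csv(self, tmp_path):
        m = CollapseMonitor(duplicate_fraction=[0.1, 0.2],
                            mean_reward=[3.0, 3.5], distinct_tokens=[9, 8])
        out = tmp_path / "monitor.csv"
        df = monitor_report(m, out)
        assert list(df.columns) == ["epoch", "duplicate_fraction",
                                    "mean_reward", "distinct_tokens"]
        assert len(df) == 2
        assert out.read_text().startswith("epoch,")

    def test_empty_monitor_rejected(self):
        with pytest.raises(ValueError):
            monitor_report(CollapseMonitor())
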