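"""Policy-gradient fine-tuning of the backbone generator.

The generator is treated as a stochastic policy over token actions; a batch
of molecules is sampled de novo, each is scored, and the REINFORCE
surrogate is optimized: for positive optimization (easier-to-synthesize)

    loss = -(1/N) * sum_n R(tau_n) * sum_t log p(a_t | s_t),

and for negative optimization the sign is flipped, driving the policy away
from high-reward regions.  R(tau) is the (optionally truncated)
reinforcement score of the decoded molecule; molecules excluded by the
truncation threshold contribute neither reward nor log-probability terms.
There is no learned critic or baseline — reward truncation is the only
shaping.

A collapse monitor records, per epoch, the duplicate-molecule fraction,
the mean reward and the number of distinct tokens used, the quantities
that expose reward-hacking degeneration ("model collapse") where the
policy repeats a few high-reward token combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import GRUStack, Adam, weighted_nll_and_grads
from .preprocessing import ChemCorpus, decode_tokens, first_step_forbidden
from .scoring import Scorer, score_batch

__all__ = ["RLConfig", "EpisodeBatch", "CollapseMonitor", "rollout",
           "policy_loss", "rl_run", "monitor_report"]


@dataclass
class RLConfig:
    direction: str = "positive"       # positive: easier to synthesize
    molecules_per_step: int = 10
    steps_per_epoch: int = 20
    epochs: int = 10
    learning_rate: float = 1e-4
    truncate: bool = True
    temperature: float = 1.0
    max_logp_bound: float = 1e4       # divergence guard on mean |log p|
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")
        if min(self.molecules_per_step, self.steps_per_epoch, self.epochs) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class EpisodeBatch:
    """Sampled trajectories with their log-probabilities and rewards."""
    sequences: list[list[int]]        # token indices, without start/end
    molecules: list[str]              # decoded canonical SMILES
    logps: np.ndarray                 # per-trajectory sum of action log-probs
    rewards: np.ndarray               # per-trajectory truncated reward


@dataclass
class CollapseMonitor:
    duplicate_fraction: list[float] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    distinct_tokens: list[int] = field(default_factory=list)


class DivergenceError(RuntimeError):
    pass


def rollout(model: GRUStack, corpus: ChemCorpus, n: int,
            temperature: float = 1.0,
            rng: np.random.Generator | int | None = None) -> EpisodeBatch:
    """Sample ``n`` de novo trajectories, recording action log-probabilities."""
    from .generator import sample_tokens
    if n < 1:
        raise ValueError("n must be >= 1")
    seqs, logps = sample_tokens(model, corpus, n, temperature=temperature,
                                rng=rng, return_logps=True)
    molecules = [decode_tokens(s, corpus) for s in seqs]
    return EpisodeBatch(sequences=seqs, molecules=molecules, logps=logps,
                        rewards=np.zeros(n))


def policy_loss(batch: EpisodeBatch, direction: str) -> float:
    """REINFORCE surrogate on recorded log-probabilities.

    Positive direction returns -(1/N) sum R*logp (minimizing it ascends
    the expected reward); negative returns its exact negation.
    """
    if not batch.sequences:
        raise ValueError("empty episode batch")
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    n = len(batch.sequences)
    value = -float(batch.rewards @ batch.logps) / n
    return value if direction == "positive" else -value


def _episode_grads(model: GRUStack, batch: EpisodeBatch, corpus: ChemCorpus,
                   direction: str):
    """Gradients of the surrogate loss by re-running teacher forcing on the
    sampled sequences with per-sequence weight R/N."""
    n = len(batch.sequences)
    max_len = max(len(s) for s in batch.sequences)
    inputs = np.full((n, max_len + 1), corpus.pad_idx, dtype=np.int64)
    targets = np.full((n, max_len + 1), corpus.pad_idx, dtype=np.int64)
    mask = np.zeros((n, max_len + 1))
    for i, seq in enumerate(batch.sequences):
        row = [corpus.start_idx] + list(seq)
        tgt = list(seq) + [corpus.end_idx]
        inputs[i, :len(row)] = row
        targets[i, :len(tgt)] = tgt
        mask[i, :len(tgt)] = 1.0
    weights = batch.rewards / n
    # NLL = -sum log p, so minimizing +sum w*NLL maximizes reward-weighted
    # log-likelihood (positive direction); the negative direction flips it
    sign = 1.0 if direction == "positive" else -1.0
    # the sampler renormalizes over allowed tokens (start/pad always
    # forbidden, only atom tokens at the first step); the likelihood must
    # match that policy exactly
    logit_mask = np.zeros((max_len + 1, model.vocab_size), dtype=bool)
    logit_mask[:, corpus.start_idx] = True
    logit_mask[:, corpus.pad_idx] = True
    logit_mask[0, :] = first_step_forbidden(corpus)
    loss, seq_nll, grads = weighted_nll_and_grads(
        model, inputs, targets, mask, weights, sign=sign,
        logit_mask=logit_mask)
    return loss, seq_nll, grads


def rl_run(model: GRUStack, corpus: ChemCorpus, scorer: Scorer,
           config: RLConfig) -> tuple[GRUStack, CollapseMonitor]:
    """Run the full schedule: epochs x steps of (rollout, score, update)."""
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)
    monitor = CollapseMonitor()
    for _epoch in range(config.epochs):
        epoch_mols: list[str] = []
        epoch_rewards: list[float] = []
        epoch_tokens: set[int] = set()
        for _step in range(config.steps_per_epoch):
            batch = rollout(model, corpus, config.molecules_per_step,
                            temperature=config.temperature, rng=rng)
            scores = score_batch(scorer, batch.molecules,
                                 mode=config.direction, truncate=config.truncate)
            batch.rewards = np.array([s.reward for s in scores])
            loss, seq_nll, grads = _episode_grads(model, batch, corpus,
                                                  config.direction)
            if np.mean(np.abs(seq_nll)) > config.max_logp_bound:
                raise DivergenceError(
                    "mean |log p| exceeded the divergence bound; "
                    "lower the learning rate or shorten the schedule")
            if batch.rewards.any():  # all-zero rewards: defined, no update
                optimizer.step(model.params, grads)
            epoch_mols.extend(batch.molecules)
            epoch_rewards.extend(batch.rewards.tolist())
            for s in batch.sequences:
                epoch_tokens.update(s)
        n = len(epoch_mols)
        monitor.duplicate_fraction.append(1.0 - len(set(epoch_mols)) / n)
        monitor.mean_reward.append(float(np.mean(epoch_rewards)))
        monitor.distinct_tokens.append(len(epoch_tokens))
    return model, monitor


def monitor_report(monitor: CollapseMonitor, path: str | Path | None = None
                   ) -> pd.DataFrame:
    """Per-epoch table of the collapse diagnostics (optionally saved as CSV)."""
    if not monitor.duplicate_fraction:
        raise ValueError("monitor holds no epochs")
    df = pd.DataFrame({
        "epoch": np.arange(len(monitor.duplicate_fraction)),
        "duplicate_fraction": monitor.duplicate_fraction,
        "mean_reward": monitor.mean_reward,
        "distinct_tokens": monitor.distinct_tokens,
    })
    if path is not None:
        df.to_csv(path, index=False)
    return df
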