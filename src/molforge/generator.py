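"""The backbone chemical language model: a three-layer stacked GRU.

Trained with the next-token objective (teacher forcing, pad positions
masked out of the loss) on token-vectorized molecules, and sampled
autoregressively from the start placeholder until the end placeholder.
Because decoding goes through the robust grammar, every sampled sequence
yields a valid molecule regardless of training state.

The default full-scale architecture (vocabulary 148, embedding 270, hidden
540, three layers) instantiates to 4,941,148 trainable parameters, about
4.9 million; dimensions are overridable through :class:`GeneratorConfig`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .nn import GRUStack, Adam, weighted_nll_and_grads, log_softmax
from .preprocessing import (ChemCorpus, EncodedBatch, MoleculeRecord,
                            decode_tokens, first_step_forbidden,
                            vectorize_batch)

__all__ = [
    "GeneratorConfig", "TrainState", "build_model", "train_epoch", "fit",
    "sample_batch", "sample_tokens", "save_checkpoint", "load_checkpoint",
]


@dataclass
class GeneratorConfig:
    vocab_size: int = 148
    embedding_dim: int = 270
    hidden_dim: int = 540
    num_layers: int = 3
    max_sample_length: int = 128
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 (0 = greedy)")
        if self.max_sample_length < 2:
            raise ValueError("max_sample_length must be >= 2")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


@dataclass
class TrainState:
    epoch: int
    mean_loss: float
    parameter_count: int


def build_model(config: GeneratorConfig) -> GRUStack:
    """Instantiate the stacked-GRU model with seeded initialization."""
    model = GRUStack(config.vocab_size, config.embedding_dim,
                     config.hidden_dim, config.num_layers, seed=config.seed)
    model.config = config  # carried for checkpointing / sampling defaults
    return model


def _batch_loss_grads(model: GRUStack, batch: EncodedBatch, pad_idx: int,
                      compute_grads: bool = True):
    mat = batch.matrix
    inputs, targets = mat[:, :-1], mat[:, 1:]
    mask = (targets != pad_idx).astype(float)
    n_tokens = mask.sum()
    weights = np.full(mat.shape[0], 1.0 / n_tokens)
    loss, _, grads = weighted_nll_and_grads(
        model, inputs, targets, mask, weights, sign=1.0,
        compute_grads=compute_grads)
    return loss, n_tokens, grads


def train_epoch(model: GRUStack, batches: list[EncodedBatch], corpus: ChemCorpus,
                optimizer: Adam, epoch: int = 0) -> TrainState:
    """One pass of teacher-forced cross-entropy over the given batches."""
    if not batches:
        raise ValueError("no batches to train on")
    total_loss = 0.0
    total_tokens = 0.0
    for batch in batches:
        loss, n_tok, grads = _batch_loss_grads(model, batch, corpus.pad_idx)
        optimizer.step(model.params, grads)
        total_loss += loss * n_tok
        total_tokens += n_tok
    return TrainState(epoch=epoch, mean_loss=total_loss / total_tokens,
                      parameter_count=model.param_count())


def evaluate_loss(model: GRUStack, batch: EncodedBatch, corpus: ChemCorpus) -> float:
    """Mean per-token NLL of a batch without updating parameters."""
    loss, _, _ = _batch_loss_grads(model, batch, corpus.pad_idx, compute_grads=False)
    return loss


def make_batches(records: list[MoleculeRecord], corpus: ChemCorpus,
                 batch_size: int, rng: np.random.Generator | None = None) -> list[EncodedBatch]:
    """Shuffle records and vectorize per-batch (padding is per batch, so
    batch widths are ragged across the dataset)."""
    order = np.arange(len(records))
    if rng is not None:
        rng.shuffle(order)
    return [
        vectorize_batch([records[j] for j in order[i:i + batch_size]], corpus)
        for i in range(0, len(order), batch_size)
    ]


def fit(model: GRUStack, records: list[MoleculeRecord], corpus: ChemCorpus,
        epochs: int = 10, batch_size: int = 128, lr: float = 1e-3,
        seed: int = 0, log_path: str | Path | None = None,
        verbose: bool = False) -> list[TrainState]:
    """Convenience training loop; returns the per-epoch history."""
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params, lr=lr)
    history = []
    log_rows = ["epoch,mean_loss,seconds"]
    for epoch in range(epochs):
        t0 = time.perf_counter()
        batches = make_batches(records, corpus, batch_size, rng)
        state = train_epoch(model, batches, corpus, optimizer, epoch=epoch)
        history.append(state)
        log_rows.append(f"{epoch},{state.mean_loss:.6f},{time.perf_counter() - t0:.2f}")
        if verbose:
            print(log_rows[-1])
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_rows) + "\n")
    return history


# -------------------------------------------------------------------------
# sampling
# -------------------------------------------------------------------------

def sample_tokens(model: GRUStack, corpus: ChemCorpus, n: int,
                  temperature: float = 1.0, max_length: int | None = None,
                  rng: np.random.Generator | int | None = None,
                  return_logps: bool = False):
    """Sample ``n`` token index sequences autoregressively.

    Placeholder symbols are masked: start/pad are never emitted, and the
    first step is restricted to atom tokens (every training sequence begins
    with one), so every sequence decodes to a nonempty valid molecule.
    ``temperature == 0`` is the greedy (argmax) limit.  Returns a list of
    index lists (without start/end), optionally with the per-sequence sum
    of chosen-action log-probabilities.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = getattr(model, "config", None)
    if max_length is None:
        max_length = cfg.max_sample_length if cfg is not None else 128

    first_forbidden = first_step_forbidden(corpus)
    seqs: list[list[int]] = [[] for _ in range(n)]
    logps = np.zeros(n)
    chunk = 2048
    out_idx = 0
    for start in range(0, n, chunk):
        b = min(chunk, n - start)
        hs = model.init_hidden(b)
        tokens = np.full(b, corpus.start_idx, dtype=np.int64)
        alive = np.ones(b, dtype=bool)
        for step in range(max_length):
            logits, hs = model.step(tokens, hs)
            logits = logits.copy()
            logits[:, corpus.start_idx] = -np.inf
            logits[:, corpus.pad_idx] = -np.inf
            if step == 0:
                logits[:, first_forbidden] = -np.inf
            if temperature == 0:
                choice = np.argmax(logits, axis=1)
                logp = log_softmax(logits)
            else:
                logp = log_softmax(logits / temperature)
                u = rng.random((b, 1))
                cum = np.cumsum(np.exp(logp), axis=1)
                cum[:, -1] = 1.0  # guard against rounding
                choice = (u <= cum).argmax(axis=1)
            for i in np.nonzero(alive)[0]:
                c = int(choice[i])
                logps[start + i] += float(logp[i, c])
                if c == corpus.end_idx:
                    alive[i] = False
                else:
                    seqs[start + i].append(c)
            tokens = choice
            # frozen rows keep stepping but their outputs are ignored
            if not alive.any():
                break
        out_idx += b
    if return_logps:
        return seqs, logps
    return seqs


def sample_batch(model: GRUStack, corpus: ChemCorpus, n: int,
                 temperature: float = 1.0, max_length: int | None = None,
                 rng: np.random.Generator | int | None = None
                 ) -> list[tuple[str, list[str]]]:
    """Sample ``n`` molecules; returns (canonical SMILES, token list) pairs."""
    seqs = sample_tokens(model, corpus, n, temperature=temperature,
                         max_length=max_length, rng=rng)
    out = []
    for seq in seqs:
        toks = [corpus.tokens[i] for i in seq]
        out.append((decode_tokens(seq, corpus) if seq else decode_tokens([], corpus), toks))
    return out


# -------------------------------------------------------------------------
# checkpoints
# -------------------------------------------------------------------------

def _corpus_hash(corpus: ChemCorpus) -> str:
    return hashlib.sha256("|".join(corpus.tokens).encode()).hexdigest()[:16]


def save_checkpoint(model: GRUStack, corpus: ChemCorpus, path: str | Path) -> None:
    """Self-describing checkpoint: config + weights + corpus."""
    cfg = getattr(model, "config", None)
    if cfg is None:
        cfg = GeneratorConfig(vocab_size=model.vocab_size,
                              embedding_dim=model.embedding_dim,
                              hidden_dim=model.hidden_dim,
                              num_layers=model.num_layers)
    meta = {"config": asdict(cfg), "corpus_tokens": list(corpus.tokens),
            "corpus_hash": _corpus_hash(corpus)}
    np.savez(Path(path), meta=np.array(json.dumps(meta)), **model.params)


def load_checkpoint(path: str | Path, corpus: ChemCorpus | None = None
                    ) -> tuple[GRUStack, ChemCorpus]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
    except Exception as exc:
        raise ValueError(f"corrupt checkpoint {path}") from exc
    cfg = GeneratorConfig(**meta["config"])
    ckpt_corpus = ChemCorpus(tokens=tuple(meta["corpus_tokens"]))
    if corpus is not None and tuple(corpus.tokens) != ckpt_corpus.tokens:
        raise ValueError("checkpoint corpus does not match the supplied corpus")
    if cfg.vocab_size != ckpt_corpus.size_c:
        raise ValueError("checkpoint vocab_size does not match its corpus")
    model = build_model(cfg)
    for k in model.params:
        model.params[k] = np.asarray(data[k])
    return model, ckpt_corpus
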