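"""Train a backbone generator on a fixture corpus and sample molecules.

The pipeline: generate a seeded molecule set, clean it, build the token
corpus, train the stacked-GRU language model with teacher forcing, then
sample autoregressively.  Because decoding goes through the robust grammar,
every sample is a valid molecule even from a briefly trained model.

Runs in about a minute on one CPU; outputs land in scratch/.
"""

from pathlib import Path

from molforge.fixtures import FixtureSpec, random_molecule_set
from molforge.generator import (GeneratorConfig, build_model, fit,
                                sample_batch, save_checkpoint)
from molforge.preprocessing import build_corpus, preprocess_smiles

OUT = Path("scratch/example01")
OUT.mkdir(parents=True, exist_ok=True)

# 1. a seeded fixture corpus -- no download, deterministic
mols = random_molecule_set(FixtureSpec(n_molecules=2000, seed=42))
records, report = preprocess_smiles(mols)
print(f"kept {report.n_kept}/{report.n_input} molecules after cleaning")

# 2. token corpus: three placeholders + every token observed in the data
corpus = build_corpus(records)
print(f"corpus size {corpus.size_c}: {corpus.tokens[:8]} ...")

# 3. a reduced backbone (the full-scale default is ~4.9M parameters;
#    this one is small enough to train in seconds)
max_len = max(len(r.selfies_tokens) for r in records)
cfg = GeneratorConfig(vocab_size=corpus.size_c, embedding_dim=64,
                      hidden_dim=128, max_sample_length=2 * (max_len + 2),
                      seed=0)
model = build_model(cfg)
print(f"model: {model.param_count():,} trainable parameters")

history = fit(model, records, corpus, epochs=5, batch_size=128, lr=1e-3,
              seed=0, log_path=OUT / "training_log.csv", verbose=True)

# 4. sample -- every output is valid by construction
pairs = sample_batch(model, corpus, 20, rng=0)
print("\nsampled molecules:")
for smi, tokens in pairs[:10]:
    print(f"  {smi:30s}  <- {' '.join(tokens)}")

save_checkpoint(model, corpus, OUT / "checkpoint.npz")
print(f"\ncheckpoint written to {OUT / 'checkpoint.npz'}")
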