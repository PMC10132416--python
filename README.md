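# molforge

A self-contained pipeline for de novo molecule generation with a
SELFIES-style chemical language model, policy-gradient optimization of
synthetic accessibility, and similarity-controlled molecule evolution.
Everything runs offline on one CPU: training corpora are generated by
seeded fixtures, the neural network is implemented directly in numpy, and
chemistry goes through RDKit.

## What it does

1. **Robust molecular grammar** — a SELFIES-style token alphabet with a
   valence-clipping decoder, so *every* token string decodes to a valid
   molecule. Sampling, reinforcement learning and mutation therefore never
   produce invalid chemistry; validity is structural, not statistical.
2. **Backbone generator** — a three-layer stacked-GRU language model over
   molecule tokens (the default full-scale configuration has ≈4.9 M
   trainable parameters), trained with teacher forcing and sampled
   autoregressively.
3. **Synthesis-aware fine-tuning** — REINFORCE in both directions
   (toward or away from easy-to-synthesize chemistry) with the exponential
   reward projection `RS(x) = exp(x/150) + e` and reward truncation, which
   doubles as the collapse-mitigation mechanism. A collapse monitor tracks
   duplicate fraction, mean reward and token diversity per epoch.
4. **Evaluation** — validity / uniqueness / novelty, QED and Crippen logP,
   a Lipinski rule-of-five filter, easy-to-synthesize fraction under a
   pluggable scorer, and PCA projection of circular fingerprints.
5. **Molecule evolution** — greedy, similarity-controlled walks from a
   start molecule (e.g., ribavirin) toward a high-drug-likeness endpoint,
   at most two token edits per step, with per-step QED/logP reporting.

See [docs/methods.md](docs/methods.md) for the modeling details and
numerical choices.

## Worked example

Train a reduced backbone on a seeded fixture corpus and sample from it:

```python
from molforge import (FixtureSpec, GeneratorConfig, SampleSet, build_corpus,
                      build_model, evaluate_samples, fit,
                      preprocess_smiles, random_molecule_set, sample_batch)

mols = random_molecule_set(FixtureSpec(n_molecules=2000, seed=42))
records, report = preprocess_smiles(mols)        # clean + tokenize
corpus = build_corpus(records)                    # placeholders + observed tokens

cfg = GeneratorConfig(vocab_size=corpus.size_c, embedding_dim=64,
                      hidden_dim=128, seed=0)
model = build_model(cfg)
fit(model, records, corpus, epochs=5, batch_size=128, lr=1e-3, seed=0)

pairs = sample_batch(model, corpus, 1000, rng=0)
sample = SampleSet([smi for smi, _ in pairs])
print(evaluate_samples(sample, [r.canonical_smiles for r in records]))
```

Output of the closely related `examples/01_train_and_sample.py`
(reduced model, ~40 s on one CPU):

```
kept 2000/2000 molecules after cleaning
corpus size 18: ('<start>', '<pad>', '<end>', '[#C]', '[#N]', '[#Ring1]', '[=C]', '[=N]') ...
model: 276,114 trainable parameters
...
sampled molecules:
  N#CCCNC=O                       <- [N] [#C] [C] [C] [N] [C] [=O]
  C=CC=NCF                        <- [C] [=C] [Branch1] [=N] [C] [=N] [C] [F]
  NNC=O                           <- [N] [N] [C] [=O]
```

Every sampled molecule is valid — the grammar guarantees it — so the
interesting metrics are uniqueness, novelty and drug-likeness.

## Examples

Narrative scripts under `examples/` (outputs land in `scratch/`):

| script | demonstrates |
|--------|--------------|
| `01_train_and_sample.py` | corpus building, training, sampling, checkpoints |
| `02_optimize_synthesis.py` | reference scorer + positive-direction REINFORCE with truncation |
| `03_evaluate_samples.py` | full metric report and PCA chemical-space projection |
| `04_molecule_evolution.py` | ribavirin → Ma97 evolution with per-step properties |

The same capabilities are exposed by the thin CLI:

```bash
molforge fixtures --n 5000 --seed 42 --out scratch/corpus.smi
molforge train --data scratch/corpus.smi --epochs 10 --out scratch/run1
molforge sample --checkpoint scratch/run1/checkpoint.npz --n 1000 --out scratch/samples.smi
molforge optimize --checkpoint scratch/run1/checkpoint.npz --direction positive --out scratch/rl1
molforge evaluate --samples scratch/samples.smi --reference scratch/corpus.smi --out scratch/report.json
molforge evolve --start ribavirin --end Ma97 --out scratch/path.csv
```

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
pytest -q                                   # full suite, ~2 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance suite (one test per
criterion: score projection and truncation formulas, drug-likeness of the
bundled Ma97 molecule, 100% sample validity at 10,000 samples, the 4.9 M
parameter budget, exact metric formulas, directional optimization,
collapse mitigation, and evolution sanity). `scripts/acceptance.py`
recomputes the reported target values from scratch — a 5,000-molecule
fixture corpus, a 10-epoch training run and 10,000 samples — and writes
them as JSON.

All randomness is seeded; fixtures, training, sampling and evolution are
deterministic given the seed.

## Layout

```
src/molforge/
  grammar.py         robust token grammar (encode/decode)
  preprocessing.py   cleaning, corpus, vectorization
  nn.py              numpy GRU stack, BPTT, Adam
  generator.py       training loop, sampling, checkpoints
  scoring.py         RS projection, truncation, scorers
  rl.py              REINFORCE fine-tuning + collapse monitor
  metrics.py         validity/uniqueness/novelty, QED/logP, PCA
  evolution.py       similarity-controlled token-edit walks
  fixtures.py        seeded molecule/corpus generators
  cli.py             thin click wrapper
```
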