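"""Evaluate a sample set: validity, uniqueness, novelty, drug-likeness, PCA.

Metrics follow the standard chemical-language-model definitions:
validity = valid/sampled, uniqueness = distinct/valid, novelty = fraction
of distinct valid molecules absent from the training set.  Drug-likeness is
QED and Crippen logP with a Lipinski rule-of-five filter; chemical-space
coverage is visualized by a 2-component PCA of binary circular
fingerprints (written as CSV coordinates here; plot with matplotlib if the
optional plot extra is installed).
"""

from pathlib import Path

from molforge.fixtures import FixtureSpec, labelled_es_hs_sets, random_molecule_set
from molforge.generator import GeneratorConfig, build_model, fit, sample_batch
from molforge.metrics import SampleSet, evaluate_samples, pca_projection
from molforge.preprocessing import build_corpus, preprocess_smiles
from molforge.scoring import train_reference_scorer

OUT = Path("scratch/example03")
OUT.mkdir(parents=True, exist_ok=True)

# train a small model, then sample from it
mols = random_molecule_set(FixtureSpec(n_molecules=1000, min_len=4,
                                       max_len=14, seed=7))
records, _ = preprocess_smiles(mols)
corpus = build_corpus(records)
max_len = max(len(r.selfies_tokens) for r in records)
model = build_model(GeneratorConfig(vocab_size=corpus.size_c, embedding_dim=32,
                                    hidden_dim=64,
                                    max_sample_length=2 * (max_len + 2), seed=0))
fit(model, records, corpus, epochs=3, batch_size=128, lr=2e-3, seed=0)

pairs = sample_batch(model, corpus, 1000, rng=0)
sample = SampleSet([smi for smi, _ in pairs])

# the reference scorer provides the easy-to-synthesize fraction
es, hs = labelled_es_hs_sets(seed=0, n_per_class=100)
scorer = train_reference_scorer(es, hs)

report = evaluate_samples(sample, [r.canonical_smiles for r in records],
                          scorer=scorer, reference_name="fixture-training-set")
print("sample metrics:")
for key, value in report.as_dict().items():
    print(f"  {key:24s} {value}")

# chemical-space projection of samples + training molecules
coords, evr = pca_projection(sample.valid_subset[:300]
                             + [r.canonical_smiles for r in records[:300]])
coords["source"] = ["sample"] * 300 + ["training"] * 300
coords.to_csv(OUT / "pca.csv", index=False)
print(f"\nPCA explained variance: {evr.round(3).tolist()}")
print(f"coordinates written to {OUT / 'pca.csv'}")
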