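import copy

import pytest

from molforge.fixtures import FixtureSpec, random_molecule_set
from molforge.generator import GeneratorConfig, build_model, fit
from molforge.preprocessing import build_corpus, preprocess_smiles


@pytest.fixture(scope="session")
def small_dataset():
    """1000-molecule seeded fixture corpus with its token corpus."""
    mols = random_molecule_set(FixtureSpec(n_molecules=1000, min_len=4,
                                           max_len=14, seed=7))
    records, report = preprocess_smiles(mols)
    assert report.n_kept == report.n_input  # fixture molecules always clean
    corpus = build_corpus(records)
    return records, corpus


@pytest.fixture(scope="session")
def pretrained(small_dataset):
    """A small backbone trained briefly on the fixture corpus.

    Session-scoped and shared; tests that update parameters must deepcopy.
    """
    records, corpus = small_dataset
    max_len = max(len(r.selfies_tokens) for r in records)
    cfg = GeneratorConfig(vocab_size=corpus.size_c, embedding_dim=32,
                          hidden_dim=64, max_sample_length=2 * (max_len + 2),
                          seed=0)
    model = build_model(cfg)
    fit(model, records, corpus, epochs=3, batch_size=128, lr=2e-3, seed=0)
    return model, corpus


@pytest.fixture()
def pretrained_copy(pretrained):
    model, corpus = pretrained
    return copy.deepcopy(model), corpus
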