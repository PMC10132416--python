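"""Seeded generators for every input the pipeline needs.

Everything the tests and examples consume — training corpora, labeled
easy/hard-to-synthesize sets, named reference drugs — is generated
programmatically here, so the whole repository builds and tests with no
external download.  Molecule sets are drawn as uniform random token strings
over a configurable alphabet and decoded through the robust grammar, which
guarantees validity; the default alphabet is a small organic subset (C, N,
O, F plus bond, branch and ring tokens) that keeps the decoded chemistry
loosely drug-like and the token corpus compact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
from rdkit import Chem

from . import grammar
from .preprocessing import clean_smiles, MoleculeRecord

__all__ = ["FixtureSpec", "DEFAULT_ALPHABET", "random_molecule_set",
           "random_records", "labelled_es_hs_sets", "bundled_drugs"]

# ~20 common organic tokens: enough chemistry for realistic training
# corpora while keeping vocabulary and sequence statistics small
DEFAULT_ALPHABET = (
    "[C]", "[=C]", "[#C]", "[N]", "[=N]", "[O]", "[=O]", "[F]",
    "[Branch1]", "[Ring1]", "[=Ring1]",
)


@dataclass
class FixtureSpec:
    n_molecules: int = 5000
    token_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    min_len: int = 4
    max_len: int = 20
    seed: int = 42

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.token_alphabet:
            raise ValueError("alphabet must be nonempty")
        for tok in self.token_alphabet:
            if tok not in grammar.ALPHABET:
                raise ValueError(f"{tok!r} is not a grammar token")


def random_molecule_set(spec: FixtureSpec) -> list[str]:
    """Draw unique valid molecules: uniform token strings, decoded and
    canonicalized, deduplicated in draw order.  Deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    alphabet = list(spec.token_alphabet)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = max(50 * spec.n_molecules, 1000)
    while len(out) < spec.n_molecules:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {spec.n_molecules} unique molecules; "
                f"got {len(out)} after {attempts} attempts — enlarge the "
                "alphabet or length range")
        attempts += 1
        n = int(rng.integers(spec.min_len, spec.max_len + 1))
        toks = [alphabet[i] for i in rng.integers(0, len(alphabet), n)]
        smi = grammar.decode_tokens(toks)
        if smi and smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


def random_records(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Fixture molecules passed through the cleaning pipeline."""
    records = []
    for smi in random_molecule_set(spec):
        rec = clean_smiles(smi)
        if isinstance(rec, MoleculeRecord):  # fixture molecules always clean
            records.append(rec)
    return records


def labelled_es_hs_sets(seed: int = 0, n_per_class: int = 100
                        ) -> tuple[list[str], list[str]]:
    """Two structurally separable molecule families for scorer training.

    The easy-to-synthesize stand-in class is drawn from a plain C/N/O
    alphabet; the hard-to-synthesize stand-in class from the same alphabet
    plus sulfur tokens, filtered so every member contains at least one
    sulfur atom.  Sulfur environments are therefore the documented marker
    fragments that separate the classes exactly.
    """
    es_spec = FixtureSpec(n_molecules=n_per_class,
                          token_alphabet=("[C]", "[=C]", "[N]", "[O]", "[=O]",
                                          "[Branch1]", "[Ring1]"),
                          min_len=4, max_len=14, seed=seed)
    es = random_molecule_set(es_spec)

    rng = np.random.default_rng(seed + 1)
    hs_alphabet = ("[C]", "[=C]", "[N]", "[O]", "[=O]", "[S]", "[=S]",
                   "[Branch1]", "[Ring1]")
    hs: list[str] = []
    seen: set[str] = set()
    while len(hs) < n_per_class:
        n = int(rng.integers(4, 15))
        toks = [hs_alphabet[i] for i in rng.integers(0, len(hs_alphabet), n)]
        smi = grammar.decode_tokens(toks)
        if not smi or smi in seen:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is not None and any(a.GetSymbol() == "S" for a in mol.GetAtoms()):
            seen.add(smi)
            hs.append(smi)
    return es, hs


_DRUGS = MappingProxyType({
    # generated drug-like candidate used as the evolution endpoint demo
    "Ma97": "COC1=CC=C(Br)C=C1C(=O)NC2=CC=C(F)C=C2",
    # standard reference structure (antiviral nucleoside analog)
    "ribavirin": "NC(=O)c1cn(C2OC(CO)C(O)C2O)cn1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "benzene": "c1ccccc1",
})


def bundled_drugs() -> MappingProxyType:
    """Immutable name -> SMILES table of the bundled demo molecules."""
    return _DRUGS
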