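"""SMILES cleaning, token corpus construction and batch vectorization.

The cleaning pipeline follows the standard chemical-language-model recipe:
validity check, largest-fragment selection, charge neutralization, an
optional tautomer canonicalization pass, and canonical non-isomeric SMILES
output.  Cleaned molecules are tokenized with the robust grammar
(:mod:`molforge.grammar`); molecules the grammar cannot represent are
rejected and counted rather than raised, since corpus construction is
expected to drop a small fraction of inputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from . import grammar

__all__ = [
    "MoleculeRecord", "Rejection", "ChemCorpus", "EncodedBatch",
    "PreprocessReport", "clean_smiles", "encode_record", "build_corpus",
    "vectorize_batch", "decode_tokens", "read_molecule_file",
    "preprocess_file",
]

START_TOKEN = "<start>"
PAD_TOKEN = "<pad>"
END_TOKEN = "<end>"
SPECIALS = (START_TOKEN, PAD_TOKEN, END_TOKEN)

# rejection reasons
PARSE_FAILURE = "parse_failure"
EMPTY_AFTER_CLEANING = "empty_after_cleaning"
SELFIES_ENCODING_FAILURE = "selfies_encoding_failure"


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule in its synchronized representations."""
    raw_smiles: str
    canonical_smiles: str
    selfies_tokens: tuple[str, ...]


@dataclass(frozen=True)
class Rejection:
    raw_smiles: str
    reason: str


@dataclass(frozen=True)
class ChemCorpus:
    """Token <-> index bijection with the three placeholders first.

    Placeholders occupy fixed indices (start=0, pad=1, end=2); chemical
    tokens follow in lexicographic order, so corpora are deterministic
    across runs.  ``size_c`` counts the placeholders.
    """
    tokens: tuple[str, ...]

    def __post_init__(self):
        if self.tokens[:3] != SPECIALS:
            raise ValueError("corpus must start with the three placeholders")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("corpus tokens must be unique")

    @property
    def size_c(self) -> int:
        return len(self.tokens)

    @property
    def start_idx(self) -> int:
        return 0

    @property
    def pad_idx(self) -> int:
        return 1

    @property
    def end_idx(self) -> int:
        return 2

    @property
    def chemical_tokens(self) -> tuple[str, ...]:
        return self.tokens[3:]

    def index(self, token: str) -> int:
        m = _corpus_map(self)
        if token not in m:
            raise KeyError(f"token {token!r} not in corpus")
        return m[token]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"tokens": list(self.tokens), "specials": list(SPECIALS)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChemCorpus":
        data = json.loads(Path(path).read_text())
        return cls(tokens=tuple(data["tokens"]))


# fast lookup without breaking frozen dataclass semantics
def _corpus_map(corpus: ChemCorpus) -> dict[str, int]:
    m = getattr(corpus, "_cached_map", None)
    if m is None:
        m = {t: i for i, t in enumerate(corpus.tokens)}
        object.__setattr__(corpus, "_cached_map", m)
    return m


@dataclass
class EncodedBatch:
    """Padded index matrix of shape (batch, l + 2) plus true lengths."""
    matrix: np.ndarray
    lengths: np.ndarray
    l: int


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_kept: int = 0
    rejections: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "rejections": dict(self.rejections)}


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER: rdMolStandardize.TautomerEnumerator | None = None


def clean_smiles(raw: str, tautomer_canonicalize: bool = False) -> MoleculeRecord | Rejection:
    """Clean one raw SMILES into a :class:`MoleculeRecord`.

    Steps, in order: parse-validity check; largest-fragment selection;
    charge neutralization; optional tautomer canonicalization (off by
    default); canonical non-isomeric SMILES; grammar tokenization.
    Unusable inputs return a :class:`Rejection` with an enumerated reason.
    """
    if not raw or not raw.strip():
        return Rejection(raw, PARSE_FAILURE)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return Rejection(raw, PARSE_FAILURE)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    if tautomer_canonicalize:
        global _TAUTOMERIZER
        if _TAUTOMERIZER is None:
            _TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()
        mol = _TAUTOMERIZER.Canonicalize(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(raw, EMPTY_AFTER_CLEANING)
    canonical = Chem.MolToSmiles(mol, isomericSmiles=False)
    if not canonical:
        return Rejection(raw, EMPTY_AFTER_CLEANING)
    try:
        tokens = tuple(grammar.encode_smiles(canonical))
    except grammar.EncodingError:
        return Rejection(raw, SELFIES_ENCODING_FAILURE)
    return MoleculeRecord(raw_smiles=raw, canonical_smiles=canonical,
                          selfies_tokens=tokens)


def encode_record(mol: MoleculeRecord | str) -> list[str]:
    """Token sequence of a record (or a canonical SMILES string)."""
    smiles = mol if isinstance(mol, str) else mol.canonical_smiles
    return grammar.encode_smiles(smiles)  # raises EncodingError if impossible


def build_corpus(records: list[MoleculeRecord]) -> ChemCorpus:
    """Union of observed tokens plus placeholders, deterministically ordered."""
    if not records:
        raise ValueError("cannot build a corpus from no records")
    observed: set[str] = set()
    for rec in records:
        observed.update(rec.selfies_tokens)
    return ChemCorpus(tokens=SPECIALS + tuple(sorted(observed)))


def vectorize_batch(records: list[MoleculeRecord], corpus: ChemCorpus) -> EncodedBatch:
    """Pad to this batch's longest molecule l; start + tokens + end + pads."""
    if not records:
        raise ValueError("empty batch")
    cmap = _corpus_map(corpus)
    rows = []
    for rec in records:
        try:
            rows.append([cmap[t] for t in rec.selfies_tokens])
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in corpus") from None
    l = max(len(r) for r in rows)
    matrix = np.full((len(rows), l + 2), corpus.pad_idx, dtype=np.int64)
    lengths = np.empty(len(rows), dtype=np.int64)
    for i, r in enumerate(rows):
        matrix[i, 0] = corpus.start_idx
        matrix[i, 1:1 + len(r)] = r
        matrix[i, 1 + len(r)] = corpus.end_idx
        lengths[i] = len(r)
    return EncodedBatch(matrix=matrix, lengths=lengths, l=l)


def first_step_forbidden(corpus: ChemCorpus) -> np.ndarray:
    """Boolean mask of tokens not allowed as the first sampled symbol.

    Every encoded molecule begins with an atom token (the traversal root),
    so the sampling policy restricts the first step to atom tokens; this is
    what guarantees a nonempty decoded molecule for every sample.
    """
    forbidden = np.ones(corpus.size_c, dtype=bool)
    for i, tok in enumerate(corpus.tokens):
        if tok in grammar.ATOM_TOKENS:
            forbidden[i] = False
    if forbidden.all():
        raise ValueError("corpus contains no atom tokens")
    return forbidden


def decode_tokens(indices, corpus: ChemCorpus) -> str:
    """Indices -> canonical SMILES: strip placeholders, decode the payload.

    The payload runs up to the first end placeholder; start/pad symbols are
    ignored wherever they appear.  An empty payload yields the empty-molecule
    sentinel ``""``.
    """
    payload = []
    for idx in np.asarray(indices, dtype=np.int64).ravel():
        if idx < 0 or idx >= corpus.size_c:
            raise IndexError(f"index {idx} outside corpus range")
        if idx == corpus.end_idx:
            break
        if idx in (corpus.start_idx, corpus.pad_idx):
            continue
        payload.append(corpus.tokens[idx])
    return grammar.decode_tokens(payload)


# -------------------------------------------------------------------------
# file interfaces
# -------------------------------------------------------------------------

def read_molecule_file(path: str | Path) -> list[str]:
    """Read raw SMILES from a .smi (optional tab-separated id) or a
    single-column CSV with a ``smiles`` header."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return []
    if path.suffix.lower() == ".csv":
        header = [c.strip().lower() for c in lines[0].split(",")]
        if "smiles" not in header:
            raise ValueError("CSV must have a 'smiles' column")
        col = header.index("smiles")
        return [ln.split(",")[col].strip() for ln in lines[1:]]
    return [ln.split("\t")[0].split()[0] for ln in lines]


def preprocess_file(path: str | Path, tautomer_canonicalize: bool = False
                    ) -> tuple[list[MoleculeRecord], PreprocessReport]:
    raws = read_molecule_file(path)
    return preprocess_smiles(raws, tautomer_canonicalize)


def preprocess_smiles(raws: list[str], tautomer_canonicalize: bool = False
                      ) -> tuple[list[MoleculeRecord], PreprocessReport]:
    report = PreprocessReport(n_input=len(raws))
    records = []
    for raw in raws:
        out = clean_smiles(raw, tautomer_canonicalize=tautomer_canonicalize)
        if isinstance(out, Rejection):
            report.rejections[out.reason] += 1
        else:
            records.append(out)
    report.n_kept = len(records)
    return records, report


def write_corpus_file(records: list[MoleculeRecord], path: str | Path) -> None:
    Path(path).write_text("".join(r.canonical_smiles + "\n" for r in records))
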