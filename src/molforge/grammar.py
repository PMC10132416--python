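"""Robust molecular string grammar over an organic-subset token alphabet.

The generator pipeline needs a string representation with the defining
property of SELFIES-style grammars: *every* token string decodes to a
chemically valid molecule.  This module provides a self-contained such
grammar.  Decoding is a derivation process that clips each requested bond
order to the free valences of the atoms involved and ignores branch/ring
directives that cannot be satisfied, so validity holds by construction for
arbitrary token sequences.  Encoding is a depth-first traversal of the
kekulized molecular graph emitting atom, branch and ring-closure tokens;
every encode is verified by an exact decode round trip.

The alphabet covers neutral organic chemistry (C, N, O, S, P, halogens;
single/double/triple bonds; branches and ring closures with one- or
two-digit length/lookback indices).  Molecules outside the subset --
charged species, exotic elements, oversized branches -- raise
:class:`EncodingError` and are excluded upstream, mirroring how chemical
language models drop the small fraction of molecules their grammar cannot
represent.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ALPHABET",
    "ATOM_TOKENS",
    "EncodingError",
    "DecodingError",
    "encode_smiles",
    "decode_tokens",
]


class EncodingError(ValueError):
    """The molecule cannot be represented in this grammar."""


class DecodingError(ValueError):
    """A token outside the grammar alphabet was supplied."""


# Maximum total bond order budget per element.  RDKit fills implicit
# hydrogens up to the nearest allowed valence, so any decode that respects
# these budgets sanitizes.
_MAX_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 6, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_BOND_ORDER_OF = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Master token order is part of the grammar definition: the first sixteen
# tokens double as the base-16 digits used by branch-length and
# ring-lookback indices (digit value = position mod 16).
ALPHABET = (
    "[C]", "[=C]", "[#C]", "[N]", "[=N]", "[#N]", "[O]", "[=O]",
    "[S]", "[=S]", "[P]", "[=P]", "[F]", "[Cl]", "[Br]", "[I]",
    "[Ring1]", "[=Ring1]", "[#Ring1]", "[Ring2]", "[=Ring2]",
    "[Branch1]", "[Branch2]",
)

_INDEX_OF = {tok: i for i, tok in enumerate(ALPHABET)}
_DIGIT_VALUE = {tok: i % 16 for i, tok in enumerate(ALPHABET)}
_DIGIT_TOKEN = ALPHABET[:16]  # canonical digit for each value 0..15

# kind tables -------------------------------------------------------------
_ATOM_INFO: dict[str, tuple[str, int]] = {}
for _sym in _MAX_VALENCE:
    _ATOM_INFO[f"[{_sym}]"] = (_sym, 1)
    if _MAX_VALENCE[_sym] >= 2:
        _ATOM_INFO[f"[={_sym}]"] = (_sym, 2)
    if _MAX_VALENCE[_sym] >= 3:
        _ATOM_INFO[f"[#{_sym}]"] = (_sym, 3)
# restrict to tokens actually in the alphabet
_ATOM_INFO = {t: v for t, v in _ATOM_INFO.items() if t in _INDEX_OF}

ATOM_TOKENS = tuple(t for t in ALPHABET if t in _ATOM_INFO)

_RING_INFO = {
    "[Ring1]": (1, 1), "[=Ring1]": (1, 2), "[#Ring1]": (1, 3),
    "[Ring2]": (2, 1), "[=Ring2]": (2, 2),
}
_BRANCH_INFO = {"[Branch1]": 1, "[Branch2]": 2}


# -------------------------------------------------------------------------
# decoding
# -------------------------------------------------------------------------

class _DecodeState:
    __slots__ = ("mol", "free")

    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.free: list[int] = []

    def add_atom(self, symbol: str) -> int:
        idx = self.mol.AddAtom(Chem.Atom(symbol))
        self.free.append(_MAX_VALENCE[symbol])
        return idx

    def add_bond(self, a: int, b: int, order: int) -> None:
        self.mol.AddBond(a, b, _BOND_ORDER_OF[order])
        self.free[a] -= order
        self.free[b] -= order


def _read_index(tokens: list[str], i: int, n_digits: int, end: int) -> tuple[int, int]:
    """Read up to ``n_digits`` digit tokens starting at ``i`` (base 16)."""
    q = 0
    read = 0
    while read < n_digits and i < end:
        q = q * 16 + _DIGIT_VALUE[tokens[i]]
        i += 1
        read += 1
    return q, i


def _derive(st: _DecodeState, tokens: list[str], i: int, end: int,
            current: int | None) -> None:
    while i < end:
        tok = tokens[i]
        if tok in _ATOM_INFO:
            sym, order = _ATOM_INFO[tok]
            if current is None:
                current = st.add_atom(sym)
                i += 1
                continue
            if st.free[current] <= 0:
                return  # chain saturated: derivation at this level ends
            eff = min(order, st.free[current], _MAX_VALENCE[sym])
            new = st.add_atom(sym)
            st.add_bond(current, new, eff)
            current = new
            i += 1
        elif tok in _RING_INFO:
            n_digits, order = _RING_INFO[tok]
            q, i = _read_index(tokens, i + 1, n_digits, end)
            if current is None:
                continue
            target = max(current - (q + 1), 0)
            if (
                target != current
                and st.mol.GetBondBetweenAtoms(target, current) is None
                and st.free[current] > 0
                and st.free[target] > 0
            ):
                eff = min(order, st.free[current], st.free[target])
                st.add_bond(target, current, eff)
        elif tok in _BRANCH_INFO:
            n_digits = _BRANCH_INFO[tok]
            q, i = _read_index(tokens, i + 1, n_digits, end)
            length = q + 1
            sub_end = min(i + length, end)
            if current is not None and st.free[current] > 0:
                _derive(st, tokens, i, sub_end, current)
            i = sub_end
        else:
            raise DecodingError(f"unknown token {tok!r}")


def decode_tokens(tokens: list[str] | tuple[str, ...]) -> str:
    """Decode a token sequence to a canonical (non-isomeric) SMILES.

    Any sequence over :data:`ALPHABET` decodes; an empty sequence yields
    the empty-molecule sentinel ``""``.
    """
    tokens = list(tokens)
    st = _DecodeState()
    _derive(st, tokens, 0, len(tokens), None)
    if st.mol.GetNumAtoms() == 0:
        return ""
    mol = st.mol.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


# -------------------------------------------------------------------------
# encoding
# -------------------------------------------------------------------------

def _atom_token(symbol: str, order: int) -> str:
    tok = f"[{_BOND_PREFIX[order]}{symbol}]"
    if tok not in _ATOM_INFO:
        raise EncodingError(f"no token for {symbol} with bond order {order}")
    return tok


def _index_tokens(q: int, n_digits: int) -> list[str]:
    digits = []
    for _ in range(n_digits):
        digits.append(_DIGIT_TOKEN[q % 16])
        q //= 16
    return list(reversed(digits))


def _ring_tokens(q: int, bond_order: int) -> list[str]:
    if q < 16:
        tok = {1: "[Ring1]", 2: "[=Ring1]", 3: "[#Ring1]"}[bond_order]
        return [tok] + _index_tokens(q, 1)
    if q < 256 and bond_order in (1, 2):
        return (["[Ring2]"] if bond_order == 1 else ["[=Ring2]"]) + _index_tokens(q, 2)
    raise EncodingError("ring closure outside grammar range")


def _emit(mol: Chem.Mol, v: int, parent: int, order: int,
          emitted: dict[int, int], counter: list[int]) -> list[str]:
    out = [_atom_token(mol.GetAtomWithIdx(v).GetSymbol(), order)]
    emitted[v] = counter[0]
    counter[0] += 1

    nbrs = sorted(a.GetIdx() for a in mol.GetAtomWithIdx(v).GetNeighbors())
    # ring closures are emitted at the later-visited endpoint
    for nb in nbrs:
        if nb != parent and nb in emitted:
            bo = int(mol.GetBondBetweenAtoms(v, nb).GetBondTypeAsDouble())
            out.extend(_ring_tokens(emitted[v] - emitted[nb] - 1, bo))

    # a neighbor may get visited through a ring inside an earlier sibling's
    # subtree, so re-check emission status at recursion time
    subtrees: list[list[str]] = []
    for nb in nbrs:
        if nb == parent or nb in emitted:
            continue
        bo = int(mol.GetBondBetweenAtoms(v, nb).GetBondTypeAsDouble())
        subtrees.append(_emit(mol, nb, v, bo, emitted, counter))

    for k, sub in enumerate(subtrees):
        if k < len(subtrees) - 1:
            length = len(sub)
            if length <= 16:
                out.append("[Branch1]")
                out.extend(_index_tokens(length - 1, 1))
            elif length <= 256:
                out.append("[Branch2]")
                out.extend(_index_tokens(length - 1, 2))
            else:
                raise EncodingError("branch exceeds grammar range")
        out.extend(sub)
    return out


def _check_encodable(mol: Chem.Mol) -> None:
    if len(Chem.GetMolFrags(mol)) != 1:
        raise EncodingError("multi-fragment molecule")
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _MAX_VALENCE:
            raise EncodingError(f"unsupported element {sym}")
        if atom.GetFormalCharge() != 0:
            raise EncodingError("charged atom")
        if atom.GetNumRadicalElectrons() != 0:
            raise EncodingError("radical atom")
        total = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if total > _MAX_VALENCE[sym]:
            raise EncodingError(f"{sym} exceeds supported valence")


def encode_smiles(smiles: str) -> list[str]:
    """Encode a SMILES string into grammar tokens.

    The input is parsed, kekulized and traversed depth-first from atom 0;
    the emitted token list is round-trip checked against the canonical
    non-isomeric form of the input.  Raises :class:`EncodingError` for
    molecules the grammar cannot represent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparseable SMILES {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise EncodingError("empty molecule")
    canonical = Chem.MolToSmiles(mol, isomericSmiles=False)
    # work on the canonical atom ordering so token output is deterministic
    mol = Chem.MolFromSmiles(canonical)
    Chem.RemoveStereochemistry(mol)
    kek = Chem.RWMol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    _check_encodable(kek)

    for bond in kek.GetBonds():
        if bond.GetBondTypeAsDouble() not in (1.0, 2.0, 3.0):
            raise EncodingError("unsupported bond order")

    tokens = _emit(kek.GetMol(), 0, -1, 1, {}, [0])
    if decode_tokens(tokens) != canonical:
        raise EncodingError(f"round-trip failure for {smiles!r}")
    return tokens
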