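"""Halfway-targeted molecule evolution by small grammar-token edits.

A start molecule (typically a known drug candidate) is walked toward a
model-selected, high-drug-likeness endpoint through a sequence of
intermediates.  Each step mutates the current token string with at most two
edits (replace / insert / delete); the robust grammar guarantees every
mutant decodes to a valid molecule, so the walk never leaves chemical
space.  Steps are accepted greedily by Tanimoto similarity to the
endpoint, making the similarity-to-end series non-decreasing; the joint
similarity of each intermediate to *both* endpoints is recorded as the
structural-constraint diagnostic, together with QED and logP, so
intermediates that improve on the start's physicochemical profile can be
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

from . import grammar
from .metrics import SampleSet, druglikeness, lipinski_pass

__all__ = [
    "EvolutionConfig", "PathStep", "EvolutionPath",
    "select_evolution_target", "mutate_selfies", "tanimoto",
    "joint_similarity", "evolve", "path_report",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class EvolutionConfig:
    max_steps: int = 100
    candidates_per_step: int = 200
    max_token_edits: int = 2
    stop_similarity: float = 0.9
    logp_window: tuple[float, float] = (0.0, 5.0)
    joint_mode: str = "average_minus_gap"   # or "min"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.stop_similarity <= 1.0):
            raise ValueError("stop_similarity must be in (0, 1]")
        if self.max_token_edits < 1:
            raise ValueError("max_token_edits must be >= 1")
        if self.joint_mode not in ("average_minus_gap", "min"):
            raise ValueError("joint_mode must be 'average_minus_gap' or 'min'")


@dataclass
class PathStep:
    molecule: str
    selfies_tokens: tuple[str, ...]
    sim_to_start: float
    sim_to_end: float
    joint_sim: float
    qed: float
    logp: float


@dataclass
class EvolutionPath:
    steps: list[PathStep] = field(default_factory=list)
    converged: bool = False

    def __len__(self) -> int:
        return len(self.steps)


def _fp(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return _MORGAN.GetFingerprint(mol)


def tanimoto(a: str, b: str) -> float:
    """Tanimoto coefficient on binary circular fingerprints."""
    return float(DataStructs.TanimotoSimilarity(_fp(a), _fp(b)))


def joint_similarity(m: str, start: str, end: str,
                     mode: str = "average_minus_gap") -> float:
    """Combined similarity of an intermediate to both evolution endpoints.

    Default: (T_start + T_end)/2 - |T_start - T_end|, which rewards being
    genuinely between the endpoints and penalizes one-sided similarity.
    ``mode='min'`` uses min(T_start, T_end) instead.
    """
    ts, te = tanimoto(m, start), tanimoto(m, end)
    if mode == "min":
        return min(ts, te)
    return (ts + te) / 2.0 - abs(ts - te)


def select_evolution_target(sample: SampleSet, config: EvolutionConfig) -> str:
    """Highest-QED Lipinski-passing molecule with logP inside the window.

    Ties break toward the lexicographically smaller canonical SMILES.
    """
    if not sample.valid_subset:
        raise ValueError("sample set holds no valid molecules")
    lo, hi = config.logp_window
    best: tuple[float, str] | None = None
    for smi in sorted(set(sample.valid_subset)):
        if not lipinski_pass(smi):
            continue
        qed, logp = druglikeness(smi)
        if not (lo <= logp <= hi):
            continue
        if best is None or qed > best[0]:
            best = (qed, smi)
    if best is None:
        raise ValueError(
            "no molecule passes the drug-likeness filter; widen logp_window")
    return best[1]


def mutate_selfies(tokens: list[str] | tuple[str, ...], alphabet: list[str],
                   n_edits: int, rng: np.random.Generator,
                   max_attempts: int = 20) -> list[str]:
    """Apply ``n_edits`` random token edits (replace / insert / delete).

    Edit positions, kinds and replacement tokens are uniform; a deletion
    that would empty the string is retried (bounded attempts).  The result
    always decodes, by the grammar's robustness guarantee.
    """
    out = list(tokens)
    if n_edits == 0:
        return out
    if not alphabet:
        raise ValueError("empty mutation alphabet")
    for _ in range(n_edits):
        for _attempt in range(max_attempts):
            op = rng.integers(0, 3)
            if op == 0 and out:          # replace
                pos = int(rng.integers(0, len(out)))
                out[pos] = alphabet[int(rng.integers(0, len(alphabet)))]
                break
            if op == 1:                  # insert
                pos = int(rng.integers(0, len(out) + 1))
                out.insert(pos, alphabet[int(rng.integers(0, len(alphabet)))])
                break
            if op == 2 and len(out) > 1:  # delete (never empty the string)
                pos = int(rng.integers(0, len(out)))
                del out[pos]
                break
    return out


def _step(smiles: str, tokens: tuple[str, ...], start: str, end: str,
          mode: str) -> PathStep:
    qed, logp = druglikeness(smiles)
    ts, te = tanimoto(smiles, start), tanimoto(smiles, end)
    joint = (min(ts, te) if mode == "min" else (ts + te) / 2.0 - abs(ts - te))
    return PathStep(molecule=smiles, selfies_tokens=tuple(tokens),
                    sim_to_start=ts, sim_to_end=te, joint_sim=joint,
                    qed=qed, logp=logp)


def evolve(start: str, end: str, config: EvolutionConfig | None = None
           ) -> EvolutionPath:
    """Greedy hill-climb from ``start`` toward ``end`` by token edits.

    Each step draws ``candidates_per_step`` mutants of the current token
    string (1..max_token_edits edits each) and accepts the candidate with
    the highest similarity to the endpoint, provided it improves on the
    current similarity; the walk stops when similarity reaches
    ``stop_similarity`` or ``max_steps`` is exhausted.
    """
    config = config or EvolutionConfig()
    rng = np.random.default_rng(config.seed)
    start_tokens = tuple(grammar.encode_smiles(start))   # EncodingError if not representable
    grammar.encode_smiles(end)
    start_can = grammar.decode_tokens(start_tokens)
    end_can = grammar.decode_tokens(grammar.encode_smiles(end))
    alphabet = list(grammar.ATOM_TOKENS) + ["[Branch1]", "[Ring1]", "[=Ring1]"]

    path = EvolutionPath()
    current = _step(start_can, start_tokens, start_can, end_can, config.joint_mode)
    path.steps.append(current)
    if current.sim_to_end >= config.stop_similarity:
        path.converged = True
        return path

    for _ in range(config.max_steps):
        best: PathStep | None = None
        for _c in range(config.candidates_per_step):
            n_edits = int(rng.integers(1, config.max_token_edits + 1))
            cand_tokens = mutate_selfies(current.selfies_tokens, alphabet,
                                         n_edits, rng)
            smi = grammar.decode_tokens(cand_tokens)
            if not smi or smi == current.molecule:
                continue
            te = tanimoto(smi, end_can)
            if best is None or te > best.sim_to_end or (
                    te == best.sim_to_end and smi < best.molecule):
                if te > current.sim_to_end:
                    best = _step(smi, tuple(cand_tokens), start_can, end_can,
                                 config.joint_mode)
        if best is not None:
            current = best
            path.steps.append(current)
        if current.sim_to_end >= config.stop_similarity:
            path.converged = True
            break
    return path


def path_report(path: EvolutionPath, out: str | None = None,
                logp_center: float = 2.5) -> pd.DataFrame:
    """Per-step table; flags steps improving both QED and logP over the start.

    A step's logP "improves" when it moves strictly closer to
    ``logp_center`` (the midpoint of the default drug-like window) than the
    start's; the flag requires the QED to improve strictly as well.
    """
    if not path.steps:
        raise ValueError("empty evolution path")
    s0 = path.steps[0]
    rows = []
    for i, st in enumerate(path.steps):
        better = bool(st.qed > s0.qed
                      and abs(st.logp - logp_center) < abs(s0.logp - logp_center))
        rows.append({
            "step": i, "smiles": st.molecule,
            "sim_to_start": st.sim_to_start, "sim_to_end": st.sim_to_end,
            "joint_sim": st.joint_sim, "qed": st.qed, "logp": st.logp,
            "better_than_start": better,
        })
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, index=False)
    return df
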