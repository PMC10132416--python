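"""Synthetic-accessibility scoring: projection, truncation and scorers.

A raw synthesis score ``x`` (easy-to-synthesize if positive, typical range
about -150..150) is projected to a strictly positive reinforcement score

    RS(x) = exp(x / 150) + e,

so RS lies in (e, 2e] over the nominal range and RS(0) = 1 + e.  Because
the projection compresses the ES/HS contrast (RS(10) - RS(-10) is small),
positive-direction optimization applies reward truncation: molecules with
raw score above 150 are excluded from the policy-gradient step entirely,
other ES molecules contribute only half their RS, and HS molecules
contribute their full RS.  Negative-direction optimization uses the plain
RS.

Scorers are pluggable: a reference Bernoulli naive-Bayes fragment scorer
trained on labeled ES/HS sets (circular-environment log-odds with Laplace
smoothing), deterministic mock scorers for controlled experiments, and an
optional adapter for the external SYBA classifier if that package is
installed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "SynthScore", "Scorer", "reinforcement_score", "truncate_reward",
    "score_batch", "train_reference_scorer", "mock_scorer", "get_scorer",
    "register_scorer", "ES_THRESHOLD", "TRUNCATION_THRESHOLD",
]

logger = logging.getLogger(__name__)

ES_THRESHOLD = 0.0        # raw score above this => easy-to-synthesize
TRUNCATION_THRESHOLD = 150.0  # applied to the raw score, before projection


@dataclass(frozen=True)
class SynthScore:
    raw_x: float
    label: str            # "ES" | "HS" | "error"
    rs: float             # reinforcement score, exp(x/150) + e
    reward: float         # post-truncation contribution


class Scorer:
    """A named, optionally deterministic callable: canonical SMILES -> raw x."""

    def __init__(self, fn: Callable[[str], float], name: str, deterministic: bool = True):
        self._fn = fn
        self.name = name
        self.deterministic = deterministic

    def __call__(self, smiles: str) -> float:
        return float(self._fn(smiles))


def reinforcement_score(raw_x: float) -> float:
    """Exponential projection of a raw synthesis score: exp(x/150) + e."""
    if not math.isfinite(raw_x):
        raise ValueError("raw synthesis score must be finite")
    return math.exp(raw_x / TRUNCATION_THRESHOLD) + math.e


def truncate_reward(raw_x: float, rs: float, mode: str, truncate: bool = True) -> float:
    """Reward contribution of one molecule under the truncation rules.

    Positive mode (with truncation): raw > 150 contributes nothing;
    0 < raw <= 150 contributes rs/2; raw <= 0 contributes the full rs.
    Negative mode, or truncation disabled: the full rs.
    """
    if mode not in ("positive", "negative"):
        raise ValueError(f"unknown optimization mode {mode!r}")
    if mode == "negative" or not truncate:
        return rs
    if raw_x > TRUNCATION_THRESHOLD:
        return 0.0
    if raw_x > ES_THRESHOLD:
        return rs / 2.0
    return rs


def score_batch(scorer: Scorer, molecules: list[str], mode: str = "positive",
                truncate: bool = True) -> list[SynthScore]:
    """Score molecules, label at threshold 0, project and truncate."""
    out = []
    for smi in molecules:
        try:
            raw = scorer(smi)
            if not math.isfinite(raw):
                raise ValueError("non-finite score")
        except Exception:
            logger.warning("scorer %s failed on %r; reward set to 0", scorer.name, smi)
            out.append(SynthScore(raw_x=math.nan, label="error", rs=0.0, reward=0.0))
            continue
        rs = reinforcement_score(raw)
        out.append(SynthScore(
            raw_x=raw,
            label="ES" if raw > ES_THRESHOLD else "HS",
            rs=rs,
            reward=truncate_reward(raw, rs, mode, truncate=truncate),
        ))
    return out


# -------------------------------------------------------------------------
# reference scorer: Bernoulli naive-Bayes over circular fragments
# -------------------------------------------------------------------------

def _fragment_ids(smiles: str, radius: int) -> set[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    fp = rdMolDescriptors.GetMorganFingerprint(mol, radius)
    return set(fp.GetNonzeroElements().keys())


def train_reference_scorer(es_molecules: list[str], hs_molecules: list[str],
                           radius: int = 2, alpha: float = 1.0) -> Scorer:
    """Fit the fragment log-odds scorer on labeled ES/HS molecule sets.

    For each circular environment (radius <= ``radius``) the per-class
    document frequency is Laplace-smoothed; a molecule's raw score is the
    sum over its distinct fragments of

        ln[(n_ES(f) + a) / (N_ES + 2a)] - ln[(n_HS(f) + a) / (N_HS + 2a)].

    Fragments unseen in either class score 0 when the classes are balanced,
    and swapping the training sets negates every output exactly.
    """
    if not es_molecules or not hs_molecules:
        raise ValueError("both ES and HS training sets must be nonempty")
    counts: dict[int, list[int]] = {}
    for cls, mols in enumerate((es_molecules, hs_molecules)):
        for smi in mols:
            for f in _fragment_ids(smi, radius):
                counts.setdefault(f, [0, 0])[cls] += 1
    n_es, n_hs = len(es_molecules), len(hs_molecules)
    log_odds = {
        f: (math.log((c[0] + alpha) / (n_es + 2 * alpha))
            - math.log((c[1] + alpha) / (n_hs + 2 * alpha)))
        for f, c in counts.items()
    }
    default = math.log(alpha / (n_es + 2 * alpha)) - math.log(alpha / (n_hs + 2 * alpha))

    def score(smiles: str) -> float:
        return sum(log_odds.get(f, default) for f in _fragment_ids(smiles, radius))

    return Scorer(score, name="reference", deterministic=True)


def mock_scorer(rule: Callable[[str], float], name: str = "mock") -> Scorer:
    """Wrap a deterministic rule as a scorer (test/experiment double)."""
    return Scorer(rule, name=name, deterministic=True)


def constant_scorer(value: float) -> Scorer:
    return Scorer(lambda _s: value, name=f"const({value})", deterministic=True)


def atom_count_scorer(symbol: str, per_atom: float, offset: float = 0.0) -> Scorer:
    """raw = offset + per_atom * (number of atoms with the given symbol)."""
    def rule(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        return offset + per_atom * sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)
    return Scorer(rule, name=f"atom_count[{symbol}]", deterministic=True)


def _syba_adapter() -> Scorer:
    """Adapter for the external SYBA classifier, when installed."""
    try:
        from syba.syba import SybaClassifier  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'syba' package is not installed; use the 'reference' scorer"
        ) from exc
    clf = SybaClassifier()
    clf.fitDefaultScore()
    return Scorer(lambda s: clf.predict(s), name="syba-adapter", deterministic=True)


_REGISTRY: dict[str, Callable[..., Scorer]] = {
    "reference": train_reference_scorer,
    "mock": mock_scorer,
    "syba-adapter": _syba_adapter,
}


def register_scorer(name: str, factory: Callable[..., Scorer]) -> None:
    _REGISTRY[name] = factory


def get_scorer(name: str, *args, **kwargs) -> Scorer:
    if name not in _REGISTRY:
        raise KeyError(f"unknown scorer {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](*args, **kwargs)
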