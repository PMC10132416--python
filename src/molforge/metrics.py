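"""Generation metrics, drug-likeness measures and chemical-space projection.

Standard chemical-language-model sample statistics on canonical SMILES:

    validity   = |V_m| / |S_m|      (valid over sampled)
    uniqueness = |set(V_m)| / |V_m| (distinct over valid)
    novelty    = 1 - |set(V_m) & N| / |set(V_m)|   (w.r.t. training set N)

plus QED / Crippen logP drug-likeness, a Lipinski rule-of-five filter
(MW <= 500, logP <= 5, H-bond donors <= 5, acceptors <= 10; pass = all
four, configurable), the easy-to-synthesize fraction under a scorer, and a
two-component PCA of binary circular fingerprints for visualizing chemical
space coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdFingerprintGenerator
from sklearn.decomposition import PCA

from .scoring import ES_THRESHOLD, Scorer

__all__ = [
    "SampleSet", "MetricsReport", "validity", "uniqueness", "novelty",
    "druglikeness", "lipinski_filter", "es_fraction", "pca_projection",
    "fingerprint_matrix", "evaluate_samples",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

LIPINSKI_THRESHOLDS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


@dataclass
class SampleSet:
    """A batch of sampled molecules S_m and its valid subset V_m."""
    molecules: list[str]
    source: str = "model"
    valid_subset: list[str] = field(init=False)

    def __post_init__(self):
        self.valid_subset = []
        for smi in self.molecules:
            mol = Chem.MolFromSmiles(smi) if smi else None
            if mol is not None:
                self.valid_subset.append(Chem.MolToSmiles(mol, isomericSmiles=False))


@dataclass
class MetricsReport:
    validity: float
    uniqueness: float
    novelty: float
    es_fraction: float | None
    mean_qed: float
    mean_logp: float
    lipinski_pass_fraction: float
    reference_set: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def validity(sample: SampleSet) -> float:
    if not sample.molecules:
        raise ValueError("empty sample set")
    return len(sample.valid_subset) / len(sample.molecules)


def uniqueness(sample: SampleSet) -> float:
    if not sample.valid_subset:
        raise ValueError("no valid molecules")
    return len(set(sample.valid_subset)) / len(sample.valid_subset)


def novelty(sample: SampleSet, reference: set[str] | list[str]) -> float:
    if not reference:
        raise ValueError("empty reference set")
    distinct = set(sample.valid_subset)
    if not distinct:
        raise ValueError("no valid molecules")
    return 1.0 - len(distinct & set(reference)) / len(distinct)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return mol


def druglikeness(smiles: str) -> tuple[float, float]:
    """(QED, Crippen logP) of one molecule."""
    mol = _mol(smiles)
    return QED.qed(mol), Crippen.MolLogP(mol)


def lipinski_pass(smiles: str, thresholds: dict | None = None) -> bool:
    t = thresholds or LIPINSKI_THRESHOLDS
    mol = _mol(smiles)
    return (Descriptors.MolWt(mol) <= t["mw"]
            and Crippen.MolLogP(mol) <= t["logp"]
            and Lipinski.NumHDonors(mol) <= t["hbd"]
            and Lipinski.NumHAcceptors(mol) <= t["hba"])


def lipinski_filter(molecules: list[str], thresholds: dict | None = None
                    ) -> tuple[list[str], float]:
    """Passing subset and pass fraction (0 with a flagless empty input)."""
    if not molecules:
        return [], 0.0
    passing = [smi for smi in molecules if lipinski_pass(smi, thresholds)]
    return passing, len(passing) / len(molecules)


def es_fraction(sample: SampleSet, scorer: Scorer) -> float:
    """Fraction of valid molecules the scorer labels easy-to-synthesize."""
    if not sample.valid_subset:
        return 0.0
    n_es = sum(1 for smi in sample.valid_subset if scorer(smi) > ES_THRESHOLD)
    return n_es / len(sample.valid_subset)


def fingerprint_matrix(molecules: list[str]) -> np.ndarray:
    """Binary circular fingerprints (radius 2, 2048 bits) as a dense matrix."""
    fps = np.zeros((len(molecules), 2048), dtype=np.float64)
    for i, smi in enumerate(molecules):
        fp = _MORGAN.GetFingerprint(_mol(smi))
        fps[i, list(fp.GetOnBits())] = 1.0
    return fps


def pca_projection(molecules: list[str], n_components: int = 2
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """First principal components of the fingerprint matrix.

    Returns a coordinate table (one row per molecule) and the explained
    variance ratios.
    """
    if len(molecules) < n_components:
        raise ValueError("need at least as many molecules as components")
    X = fingerprint_matrix(molecules)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    df = pd.DataFrame(coords, columns=[f"pc{i + 1}" for i in range(n_components)])
    df.insert(0, "smiles", molecules)
    return df, pca.explained_variance_ratio_


def evaluate_samples(sample: SampleSet, reference: list[str] | set[str],
                     scorer: Scorer | None = None,
                     reference_name: str = "training") -> MetricsReport:
    """Full metric report for a sample set against a reference set."""
    qeds, logps = [], []
    for smi in sample.valid_subset:
        q, lp = druglikeness(smi)
        qeds.append(q)
        logps.append(lp)
    _, lip = lipinski_filter(sample.valid_subset)
    return MetricsReport(
        validity=validity(sample),
        uniqueness=uniqueness(sample),
        novelty=novelty(sample, reference),
        es_fraction=es_fraction(sample, scorer) if scorer is not None else None,
        mean_qed=float(np.mean(qeds)) if qeds else 0.0,
        mean_logp=float(np.mean(logps)) if logps else 0.0,
        lipinski_pass_fraction=lip,
        reference_set=reference_name,
    )
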