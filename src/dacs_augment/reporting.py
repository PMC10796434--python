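"""Machine-readable summary artifacts: physicochemical sanity summaries and
synergy-score distributions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import DrugLibrary

logger = logging.getLogger(__name__)

PROPERTIES = ("logp", "hbd", "hba", "qed")


@dataclass
class PropertySummary:
    """Mean +/- SD of logP, HBD, HBA and QED over a drug set."""

    stats: Dict[str, Tuple[float, float]]   # property -> (mean, sd)
    n_molecules: int
    backend: str
    excluded: List[str] = field(default_factory=list)


def _descriptors(smiles: str) -> Dict[str, float]:
    from rdkit import Chem
    from rdkit.Chem import Descriptors, QED

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {
        "logp": Descriptors.MolLogP(mol),
        "hbd": float(Descriptors.NumHDonors(mol)),
        "hba": float(Descriptors.NumHAcceptors(mol)),
        "qed": QED.qed(mol),
    }


def property_summary(library: DrugLibrary) -> PropertySummary:
    """Per-property mean and (population) SD over all molecules with SMILES.

    Molecules whose descriptors cannot be computed are excluded and logged.
    """
    import rdkit

    values: Dict[str, List[float]] = {p: [] for p in PROPERTIES}
    excluded: List[str] = []
    for drug_id, rec in library.items():
        if rec.smiles is None:
            excluded.append(drug_id)
            continue
        try:
            desc = _descriptors(rec.smiles)
        except (ValueError, RuntimeError):
            logger.warning("descriptor failure for %s; excluded", drug_id)
            excluded.append(drug_id)
            continue
        for p in PROPERTIES:
            values[p].append(desc[p])
    n = len(values["logp"])
    if n == 0:
        raise ValueError("no molecule in the library yielded descriptors")
    stats = {p: (float(np.mean(v)), float(np.std(v))) for p, v in values.items()}
    return PropertySummary(stats=stats, n_molecules=n,
                           backend=f"rdkit {rdkit.__version__}", excluded=excluded)


@dataclass
class ScoreDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    n: int


def score_distribution(scores: Sequence[float], bins: int = 20,
                       value_range: Optional[Tuple[float, float]] = None) -> ScoreDistribution:
    """Histogram plus first two moments of a synergy-score collection."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no scores given")
    counts, edges = np.histogram(arr, bins=bins, range=value_range)
    return ScoreDistribution(bin_edges=edges, counts=counts,
                             mean=float(np.mean(arr)), sd=float(np.std(arr)),
                             n=int(arr.size))
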