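"""Instance featurization from pluggable embedding providers.

An instance vector is [drug_a | drug_b | cell] with the two drugs in
canonical (lexicographic) order, so featurization is invariant to pair
orientation in the input file. Providers default to 300 dimensions, giving
the standard 900-dimensional vector; any provider obeying the contract
(fixed dimension, deterministic embed) can be swapped in, e.g. pretrained
vectors loaded from CSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Protocol, Sequence

import numpy as np
import pandas as pd

from .core_io import DrugLibrary
from .dataset_builder import LabeledInstance

DEFAULT_DIMENSION = 300


class EmbeddingProvider(Protocol):
    name: str
    dimension: int

    def embed(self, entity_id: str) -> np.ndarray: ...


def _stable_int(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:8], "big")


class HashedDrugEmbedder:
    """Deterministic random projection of fingerprint bits.

    Each fingerprint bit maps to a fixed Gaussian row (seeded by the global
    seed only, not the drug), and a drug's embedding is the mean of its
    on-bit rows; drugs with identical fingerprints therefore embed
    identically, and embedding cosine similarity tracks fingerprint Tanimoto.
    """

    def __init__(self, library: DrugLibrary, dimension: int = DEFAULT_DIMENSION,
                 seed: int = 0):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.name = f"hashed-fingerprint-{dimension}d"
        self.dimension = dimension
        self._library = library
        self._seed = seed
        self._projections: Dict[int, np.ndarray] = {}

    def _projection(self, n_bits: int) -> np.ndarray:
        if n_bits not in self._projections:
            rng = np.random.default_rng([self._seed, n_bits])
            self._projections[n_bits] = rng.standard_normal((n_bits, self.dimension))
        return self._projections[n_bits]

    def embed(self, entity_id: str) -> np.ndarray:
        if entity_id not in self._library:
            raise KeyError(f"unknown drug {entity_id!r}")
        fp = self._library[entity_id].require_fingerprint()
        proj = self._projection(fp.n_bits)
        if not fp.bits:
            return np.zeros(self.dimension)
        rows = proj[sorted(fp.bits)]
        return rows.mean(axis=0)


class HashedCellEmbedder:
    """Seeded random-but-fixed vector per cell-line id (no biological signal)."""

    def __init__(self, dimension: int = DEFAULT_DIMENSION, seed: int = 0):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.name = f"hashed-cell-{dimension}d"
        self.dimension = dimension
        self._seed = seed

    def embed(self, entity_id: str) -> np.ndarray:
        rng = np.random.default_rng([self._seed, _stable_int(entity_id)])
        return rng.standard_normal(self.dimension)


class CsvEmbeddingProvider:
    """Pretrained embeddings loaded from CSV: entity_id, then numeric columns."""

    def __init__(self, path: str | Path, name: str = "csv"):
        df = pd.read_csv(path)
        id_col = df.columns[0]
        self._vectors = {str(row[id_col]): row.iloc[1:].to_numpy(dtype=float)
                         for _, row in df.iterrows()}
        dims = {len(v) for v in self._vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"{path}: inconsistent embedding dimensions {sorted(dims)}")
        self.dimension = dims.pop()
        self.name = name

    def embed(self, entity_id: str) -> np.ndarray:
        try:
            return self._vectors[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity {entity_id!r}") from None


def featurize_instance(instance: LabeledInstance,
                       drug_provider: EmbeddingProvider,
                       cell_provider: EmbeddingProvider) -> np.ndarray:
    rec = instance.record
    vec = np.concatenate([
        drug_provider.embed(rec.drug_a),   # canonical: drug_a < drug_b
        drug_provider.embed(rec.drug_b),
        cell_provider.embed(rec.cell_line),
    ])
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite feature entries for {rec.key}")
    return vec


def featurize_many(instances: Sequence[LabeledInstance],
                   drug_provider: EmbeddingProvider,
                   cell_provider: EmbeddingProvider) -> np.ndarray:
    if not instances:
        return np.empty((0, 2 * drug_provider.dimension + cell_provider.dimension))
    return np.vstack([featurize_instance(i, drug_provider, cell_provider)
                      for i in instances])
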