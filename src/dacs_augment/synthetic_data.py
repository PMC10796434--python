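"""Synthetic benchmark generator with planted substitutability clusters.

Drugs come in clusters sharing a template fingerprint, a template target set
and a latent per-cell-line potency profile, so within-cluster pairs have high
TC, MCC and tau_b by construction. Synergy classes are assigned at the
cluster-pair level, which is exactly what makes label transfer valid on this
data: substituting a drug for a cluster-mate lands in the same cluster pair
and hence the same planted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np

from .augmentation import candidate_substitutes
from .core_io import (ANTAGONISTIC, SYNERGISTIC, DrugLibrary, DrugRecord,
                      ResponseMatrix, SynergyRecord, TargetMap)
from .fingerprints import Fingerprint


@dataclass
class SimConfig:
    n_clusters: int = 4
    drugs_per_cluster: int = 5
    n_proteins: int = 200
    n_cell_lines: int = 20
    n_tissues: int = 5
    within_cluster_bit_overlap: float = 0.9
    within_cluster_target_overlap: float = 0.9
    response_noise_sd: float = 0.25
    synergy_effect: float = 30.0
    synergy_noise_sd: float = 5.0
    class_balance: float = 0.5
    seed: int = 0
    # generator-shape knobs beyond the headline parameters
    n_bits: int = 1024
    n_set_bits: int = 96
    targets_per_cluster: int = 12
    profile_sd: float = 1.5       # spread of latent cluster potency profiles
    pair_fraction: float = 1.0    # fraction of drug pairs given synergy records
    cells_per_pair: int = 1

    def validate(self) -> None:
        for name in ("within_cluster_bit_overlap", "within_cluster_target_overlap",
                     "pair_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0,1)")
        for name in ("n_clusters", "drugs_per_cluster", "n_proteins", "n_cell_lines",
                     "n_tissues", "n_bits", "n_set_bits", "targets_per_cluster",
                     "cells_per_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_set_bits > self.n_bits:
            raise ValueError("n_set_bits exceeds fingerprint length")
        if self.targets_per_cluster > self.n_proteins:
            raise ValueError("targets_per_cluster exceeds n_proteins")
        if self.cells_per_pair > self.n_cell_lines:
            raise ValueError("cells_per_pair exceeds n_cell_lines")


@dataclass
class PlantedTruth:
    cluster_of: Dict[str, int]
    pair_class: Dict[Tuple[str, str], str]
    config: SimConfig


@dataclass
class SimulatedData:
    library: DrugLibrary
    target_map: TargetMap
    responses: ResponseMatrix
    synergy: List[SynergyRecord]
    tissue_grouping: Dict[str, int]   # tissue label -> CV fold
    truth: PlantedTruth


def _perturb_bits(template: frozenset, overlap: float, n_bits: int,
                  rng: np.random.Generator) -> frozenset:
    """Keep each template bit with probability ``overlap``; replace dropped
    bits with random off-template bits so the set-bit count is preserved."""
    kept = {b for b in template if rng.random() < overlap}
    n_replace = len(template) - len(kept)
    if n_replace:
        candidates = np.array(sorted(set(range(n_bits)) - template - kept))
        kept.update(rng.choice(candidates, size=n_replace, replace=False).tolist())
    return frozenset(kept)


def _perturb_targets(template: frozenset, overlap: float, proteins: List[str],
                     rng: np.random.Generator) -> frozenset:
    kept = {p for p in template if rng.random() < overlap}
    n_replace = len(template) - len(kept)
    if n_replace:
        candidates = np.array(sorted(set(proteins) - template - kept))
        kept.update(rng.choice(candidates, size=n_replace, replace=False).tolist())
    return frozenset(kept)


def simulate(config: SimConfig) -> SimulatedData:
    """Generate a fully self-consistent input bundle, deterministic under seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins = [f"p{i:05d}" for i in range(config.n_proteins)]
    cell_lines = [f"cl{i:03d}" for i in range(config.n_cell_lines)]
    tissues = [f"tissue_{j}" for j in range(config.n_tissues)]
    cell_tissue = {cell: tissues[i % config.n_tissues] for i, cell in enumerate(cell_lines)}
    tissue_grouping = {t: j % 5 for j, t in enumerate(tissues)}

    library: DrugLibrary = {}
    associations: Dict[str, frozenset] = {}
    cluster_of: Dict[str, int] = {}
    profiles: Dict[str, Dict[str, float]] = {}
    for c in range(config.n_clusters):
        fp_template = frozenset(
            rng.choice(config.n_bits, size=config.n_set_bits, replace=False).tolist())
        target_template = frozenset(
            rng.choice(proteins, size=config.targets_per_cluster, replace=False).tolist())
        potency = {cell: 7.0 + config.profile_sd * rng.standard_normal()
                   for cell in cell_lines}
        for d in range(config.drugs_per_cluster):
            drug_id = f"d{c:02d}_{d:02d}"
            bits = _perturb_bits(fp_template, config.within_cluster_bit_overlap,
                                 config.n_bits, rng)
            library[drug_id] = DrugRecord(
                drug_id=drug_id,
                fingerprint=Fingerprint(bits=bits, n_bits=config.n_bits, backend="synthetic"))
            associations[drug_id] = _perturb_targets(
                target_template, config.within_cluster_target_overlap, proteins, rng)
            cluster_of[drug_id] = c
            profiles[drug_id] = {
                cell: potency[cell] + config.response_noise_sd * rng.standard_normal()
                for cell in cell_lines}

    entries = {(drug, cell): v for drug, prof in profiles.items() for cell, v in prof.items()}
    responses = ResponseMatrix(entries=entries, cell_line_tissue=cell_tissue)
    target_map = TargetMap(associations=associations,
                           universe_size=config.n_proteins,
                           universe=frozenset(proteins))

    # Cluster-pair classes: shuffle cluster pairs and mark synergistic until the
    # cumulative drug-pair count best approximates the requested balance.
    drug_ids = sorted(library)
    all_pairs = list(combinations(drug_ids, 2))
    cluster_pairs = list(combinations(range(config.n_clusters), 2)) + [
        (c, c) for c in range(config.n_clusters)]
    pairs_in = {cp: 0 for cp in cluster_pairs}
    for a, b in all_pairs:
        ca, cb = sorted((cluster_of[a], cluster_of[b]))
        pairs_in[(ca, cb)] += 1
    order = list(cluster_pairs)
    rng.shuffle(order)
    target_count = config.class_balance * len(all_pairs)
    cluster_class: Dict[Tuple[int, int], str] = {}
    cum = 0
    for cp in order:
        if abs(cum + pairs_in[cp] - target_count) < abs(cum - target_count):
            cluster_class[cp] = SYNERGISTIC
            cum += pairs_in[cp]
        else:
            cluster_class[cp] = ANTAGONISTIC

    pair_class: Dict[Tuple[str, str], str] = {}
    for a, b in all_pairs:
        ca, cb = sorted((cluster_of[a], cluster_of[b]))
        pair_class[(a, b)] = cluster_class[(ca, cb)]

    synergy: List[SynergyRecord] = []
    for a, b in all_pairs:
        if config.pair_fraction < 1.0 and rng.random() >= config.pair_fraction:
            continue
        sign = 1.0 if pair_class[(a, b)] == SYNERGISTIC else -1.0
        cells = rng.choice(cell_lines, size=config.cells_per_pair, replace=False)
        for cell in cells:
            score = sign * config.synergy_effect + config.synergy_noise_sd * rng.standard_normal()
            synergy.append(SynergyRecord(drug_a=a, drug_b=b, cell_line=str(cell),
                                         synergy_score=float(score),
                                         tissue=cell_tissue[str(cell)]))

    truth = PlantedTruth(cluster_of=cluster_of, pair_class=pair_class, config=config)
    return SimulatedData(library=library, target_map=target_map, responses=responses,
                         synergy=synergy, tissue_grouping=tissue_grouping, truth=truth)


@dataclass
class RecoveryResult:
    precision: Optional[float]   # None when nothing was retrieved
    recall: float
    n_retrieved: int
    n_relevant: int


def recovery_check(data: SimulatedData, cutoff: float) -> RecoveryResult:
    """Micro-averaged precision/recall of substitute retrieval vs planted clusters."""
    cluster_of = data.truth.cluster_of
    retrieved = relevant = hits = recalled = 0
    for drug_id, record in data.library.items():
        mates = {d for d, c in cluster_of.items()
                 if c == cluster_of[drug_id] and d != drug_id}
        relevant += len(mates)
        found = candidate_substitutes(record, data.library, data.target_map, cutoff)
        retrieved += len(found)
        for cand_id, _ in found:
            if cand_id in mates:
                hits += 1
                recalled += 1
    precision = hits / retrieved if retrieved else None
    recall = recalled / relevant if relevant else 0.0
    return RecoveryResult(precision=precision, recall=recall,
                          n_retrieved=retrieved, n_relevant=relevant)
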