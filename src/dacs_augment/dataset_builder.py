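"""Labeled classification datasets, the ambiguity-threshold ladder, the
chemically-unseen external set, and fold assignment for both cross-validation
protocols.

Labeling uses inclusive boundaries (score >= t synergistic, <= -t
antagonistic) for positive thresholds and strict inequalities at t = 0;
scores strictly inside the ambiguous band are excluded. Augmented instances
inherit their parent's fold and are only ever used for training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .core_io import (ANTAGONISTIC, SYNERGISTIC, AugmentedRecord, DrugLibrary,
                      SynergyRecord)
from .similarity import tanimoto

Record = Union[SynergyRecord, AugmentedRecord]

ORIGINAL = "original"
AUGMENTED = "augmented"
RANDOM_STRATIFIED = "random_stratified"
TISSUE_BASED = "tissue_based"


@dataclass
class LabeledInstance:
    record: Record
    label: str            # SYNERGISTIC | ANTAGONISTIC
    origin: str           # ORIGINAL | AUGMENTED
    fold: Optional[int] = None


@dataclass
class FoldAssignment:
    scheme: str
    n_folds: int
    folds: List[int]      # parallel to the instance list given to assign_folds
    tissue_groups: Dict[int, Set[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class DatasetSummary:
    n_total: int
    n_synergistic: int
    n_antagonistic: int
    synergistic_fraction: float   # percent
    thresholds: Tuple[float, float]

    @classmethod
    def from_counts(cls, n_synergistic: int, n_antagonistic: int,
                    thresholds: Tuple[float, float] = (20.0, -20.0)) -> "DatasetSummary":
        n_total = n_synergistic + n_antagonistic
        if n_total <= 0:
            raise ValueError("empty dataset")
        return cls(n_total=n_total, n_synergistic=n_synergistic,
                   n_antagonistic=n_antagonistic,
                   synergistic_fraction=100.0 * n_synergistic / n_total,
                   thresholds=thresholds)


@dataclass
class LadderDataset:
    threshold: float
    instances: List[LabeledInstance]
    summary: Optional[DatasetSummary]   # None when the rung is empty


def label_instance(synergy_score: float, pos_threshold: float = 20.0,
                   neg_threshold: float = -20.0, strict: bool = False) -> Optional[str]:
    """Map a synergy score to a class label, or None when ambiguous.

    Inclusive boundaries by default; ``strict=True`` switches to > / < (used
    for the zero-threshold ladder rung).
    """
    if strict:
        if pos_threshold < neg_threshold:
            raise ValueError("pos_threshold must not be below neg_threshold")
    elif not pos_threshold > neg_threshold:
        raise ValueError("pos_threshold must exceed neg_threshold")
    if strict:
        if synergy_score > pos_threshold:
            return SYNERGISTIC
        if synergy_score < neg_threshold:
            return ANTAGONISTIC
        return None
    if synergy_score >= pos_threshold:
        return SYNERGISTIC
    if synergy_score <= neg_threshold:
        return ANTAGONISTIC
    return None


def label_records(records: Iterable[Record], pos_threshold: float = 20.0,
                  neg_threshold: float = -20.0, strict: bool = False,
                  origin: str = ORIGINAL) -> List[LabeledInstance]:
    instances = []
    for rec in records:
        label = label_instance(rec.synergy_score, pos_threshold, neg_threshold, strict)
        if label is not None:
            instances.append(LabeledInstance(record=rec, label=label, origin=origin))
    return instances


def summarize(instances: Sequence[LabeledInstance],
              thresholds: Tuple[float, float]) -> DatasetSummary:
    n_syn = sum(1 for i in instances if i.label == SYNERGISTIC)
    return DatasetSummary.from_counts(n_syn, len(instances) - n_syn, thresholds)


def build_threshold_ladder(records: Sequence[Record],
                           thresholds: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0),
                           ) -> List[LadderDataset]:
    """One dataset per ambiguity threshold t, labeled at (+t, -t).

    t = 0 uses strict inequalities (score > 0 / score < 0) so a score of
    exactly 0 is excluded everywhere.
    """
    if any(t < 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be non-negative and ascending")
    out = []
    for t in thresholds:
        strict = (t == 0)
        instances = label_records(records, pos_threshold=t, neg_threshold=-t, strict=strict)
        summary = summarize(instances, (t, -t)) if instances else None
        out.append(LadderDataset(threshold=t, instances=instances, summary=summary))
    return out


def build_unseen_set(candidates: Sequence[SynergyRecord],
                     candidate_library: DrugLibrary,
                     training_library: DrugLibrary,
                     tc_max: float = 0.4,
                     pos_threshold: float = 20.0,
                     neg_threshold: float = -20.0) -> List[LabeledInstance]:
    """External instances whose drugs are all chemically unseen.

    A candidate record survives only if BOTH of its drugs have Tanimoto
    strictly below ``tc_max`` to EVERY training compound.
    """
    training_fps = [rec.require_fingerprint() for rec in training_library.values()]

    def unseen(drug_id: str) -> bool:
        fp = candidate_library[drug_id].require_fingerprint()
        return all(tanimoto(fp, train_fp) < tc_max for train_fp in training_fps)

    unseen_cache: Dict[str, bool] = {}
    kept = []
    for rec in candidates:
        ok = all(unseen_cache.setdefault(d, unseen(d)) for d in rec.pair)
        if ok:
            kept.append(rec)
    return label_records(kept, pos_threshold, neg_threshold)


def assign_folds(instances: Sequence[LabeledInstance], scheme: str,
                 n_folds: int = 5,
                 tissue_grouping: Optional[Mapping[str, int]] = None,
                 seed: int = 0) -> FoldAssignment:
    """Partition original instances into folds; sets ``instance.fold`` in place.

    ``random_stratified`` shuffles each class with a seeded RNG and deals
    instances round-robin so per-fold class proportions stay within one
    instance of the global ones. ``tissue_based`` maps each instance to the
    fold of its tissue via ``tissue_grouping`` (complete over observed
    tissues, else an error naming the missing tissue).
    """
    folds: List[int] = [-1] * len(instances)
    tissue_groups: Dict[int, Set[str]] = {}
    if scheme == RANDOM_STRATIFIED:
        rng = np.random.default_rng(seed)
        by_label: Dict[str, List[int]] = {}
        for idx, inst in enumerate(instances):
            by_label.setdefault(inst.label, []).append(idx)
        for label in sorted(by_label):
            idxs = np.array(by_label[label])
            rng.shuffle(idxs)
            for pos, idx in enumerate(idxs):
                folds[idx] = pos % n_folds
    elif scheme == TISSUE_BASED:
        if tissue_grouping is None:
            raise ValueError("tissue_based scheme requires a tissue_grouping map")
        for idx, inst in enumerate(instances):
            tissue = inst.record.tissue
            if tissue not in tissue_grouping:
                raise ValueError(f"tissue {tissue!r} has no fold in the tissue_grouping map")
            fold = int(tissue_grouping[tissue])
            folds[idx] = fold
            tissue_groups.setdefault(fold, set()).add(tissue)
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")
    for inst, fold in zip(instances, folds):
        inst.fold = fold
    return FoldAssignment(scheme=scheme, n_folds=n_folds, folds=folds,
                          tissue_groups=tissue_groups)


@dataclass
class FoldTrainingSet:
    fold: int
    original: List[LabeledInstance]
    augmented: List[LabeledInstance]


def attach_augmented_to_training(assignment: FoldAssignment,
                                 instances: Sequence[LabeledInstance],
                                 augmented: Sequence[LabeledInstance],
                                 ratio_tolerance: float = 0.005,
                                 seed: int = 0) -> Dict[int, FoldTrainingSet]:
    """Per-fold training sets: other folds' originals plus their augmented offspring.

    An augmented instance inherits the fold of its parent record (matched on
    canonical parent pair + cell line); offspring of validation-fold parents
    are excluded from that fold's training set, so augmented data never
    leaks information about held-out instances. Augmented instances are
    subsampled per class so their synergistic fraction matches the fold's
    original-training fraction within ``ratio_tolerance`` where the class
    pools allow it.
    """
    parent_fold: Dict[Tuple[str, str, str], int] = {}
    for inst in instances:
        if inst.fold is None:
            raise ValueError("assign_folds must run before attaching augmented data")
        parent_fold[inst.record.key] = inst.fold

    placed: List[Tuple[LabeledInstance, int]] = []
    for inst in augmented:
        rec = inst.record
        if not isinstance(rec, AugmentedRecord):
            raise ValueError("augmented instances must wrap AugmentedRecords")
        fold = parent_fold.get(rec.parent_key)
        if fold is None:
            continue  # parent excluded by labeling; no fold to inherit
        inst.fold = fold
        placed.append((inst, fold))

    rng = np.random.default_rng(seed)
    out: Dict[int, FoldTrainingSet] = {}
    for fold in range(assignment.n_folds):
        train_orig = [inst for inst in instances if inst.fold != fold]
        pool = [inst for inst, f in placed if f != fold]
        if not train_orig or not pool:
            out[fold] = FoldTrainingSet(fold=fold, original=train_orig, augmented=pool)
            continue
        target = sum(1 for i in train_orig if i.label == SYNERGISTIC) / len(train_orig)
        syn = [i for i in pool if i.label == SYNERGISTIC]
        ant = [i for i in pool if i.label == ANTAGONISTIC]
        chosen = _match_ratio(syn, ant, target, rng)
        out[fold] = FoldTrainingSet(fold=fold, original=train_orig, augmented=chosen)
    return out


def _match_ratio(syn: List[LabeledInstance], ant: List[LabeledInstance],
                 target: float, rng: np.random.Generator) -> List[LabeledInstance]:
    """Largest per-class subsample whose synergistic fraction is ~``target``."""
    if target >= 1.0:
        return list(syn)
    if target <= 0.0:
        return list(ant)
    # Keep the binding class whole, trim the other.
    if len(syn) / max(len(syn) + len(ant), 1) >= target:
        n_ant = len(ant)
        n_syn = min(len(syn), round(n_ant * target / (1.0 - target)))
    else:
        n_syn = len(syn)
        n_ant = min(len(ant), round(n_syn * (1.0 - target) / target))
    take_syn = sorted(rng.choice(len(syn), size=n_syn, replace=False)) if n_syn < len(syn) else range(len(syn))
    take_ant = sorted(rng.choice(len(ant), size=n_ant, replace=False)) if n_ant < len(ant) else range(len(ant))
    return [syn[i] for i in take_syn] + [ant[i] for i in take_ant]
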