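"""Threshold selection and the substitution engine.

A synergy dataset is expanded by replacing exactly one drug of a pair with a
library compound whose DACS to the replaced drug meets a cutoff; cell line,
synergy score and class label are inherited from the parent record. The
cutoff is chosen where the fidelity curve (fraction of pairs with positive
tau_b above the threshold) crosses the max-normalized substitute-coverage
curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_io import AugmentedRecord, DrugLibrary, DrugRecord, SynergyRecord, TargetMap
from .similarity import DACS_MAX, dacs, fraction_positive_tau, tanimoto, target_mcc

logger = logging.getLogger(__name__)

#: Default threshold grid: 0.00 .. 1.41 step 0.01.
DEFAULT_GRID = tuple(round(0.01 * i, 2) for i in range(142))


@dataclass
class ThresholdCurves:
    """Fidelity and substitute coverage as functions of the DACS threshold."""

    grid: np.ndarray
    fidelity: np.ndarray           # fraction of pairs with tau_b > 0; NaN = undefined
    coverage: np.ndarray           # candidate substitutes available at each threshold
    coverage_norm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.fidelity = np.asarray(self.fidelity, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(np.diff(self.coverage) > 0):
            raise ValueError("coverage must be non-increasing in the threshold")
        cmax = np.max(self.coverage)
        self.coverage_norm = self.coverage / cmax if cmax > 0 else np.zeros_like(self.coverage)


def candidate_counts_from_dacs(dacs_values: Sequence[float],
                               grid: Sequence[float]) -> Dict[float, int]:
    """Per-threshold counts of candidates with DACS >= t (inclusive)."""
    values = np.asarray(dacs_values, dtype=float)
    return {float(t): int(np.sum(values >= t)) for t in grid}


def build_threshold_curves(pair_scores: Iterable[Tuple[float, float]],
                           candidate_counts: Mapping[float, int],
                           grid: Sequence[float] = DEFAULT_GRID) -> ThresholdCurves:
    """Evaluate fidelity and coverage on a threshold grid.

    ``pair_scores`` holds (dacs, tau_b) per drug pair; ``candidate_counts``
    maps each grid threshold to the number of substitutes available at it.
    """
    scores = list(pair_scores)
    if not scores:
        raise ValueError("pair_scores is empty")
    grid_arr = np.asarray(list(grid), dtype=float)
    fidelity = np.array(
        [np.nan if (f := fraction_positive_tau(scores, t)) is None else f for t in grid_arr])
    try:
        coverage = np.array([candidate_counts[float(t)] for t in grid_arr], dtype=float)
    except KeyError as exc:
        raise ValueError(f"candidate_counts missing grid threshold {exc}") from None
    return ThresholdCurves(grid=grid_arr, fidelity=fidelity, coverage=coverage)


def smooth_fidelity(curves: ThresholdCurves) -> ThresholdCurves:
    """Isotonic (non-decreasing) fit of the empirical fidelity curve.

    Finite samples make the raw fraction-positive curve wiggle; threshold
    selection requires a monotone curve, so the least-squares monotone fit is
    taken over the defined grid points before the crossing is computed.
    """
    from sklearn.isotonic import IsotonicRegression

    mask = ~np.isnan(curves.fidelity)
    if mask.sum() == 0:
        raise ValueError("fidelity is undefined over the whole grid")
    fitted = np.full_like(curves.fidelity, np.nan)
    fitted[mask] = IsotonicRegression(increasing=True).fit_transform(
        curves.grid[mask], curves.fidelity[mask])
    return ThresholdCurves(grid=curves.grid.copy(), fidelity=fitted,
                           coverage=curves.coverage.copy())


def select_dacs_threshold(curves: ThresholdCurves) -> float:
    """Crossing abscissa of fidelity and max-normalized coverage.

    Fidelity must be non-decreasing and normalized coverage non-increasing
    over the defined part of the grid; the crossing is linearly interpolated
    between adjacent grid points, or returned exactly when it falls on one.
    """
    mask = ~np.isnan(curves.fidelity)
    grid = curves.grid[mask]
    f = curves.fidelity[mask]
    g = curves.coverage_norm[mask]
    if len(grid) == 0:
        raise ValueError("fidelity is undefined over the whole grid")
    if np.any(np.diff(f) < -1e-12):
        raise ValueError("fidelity must be non-decreasing over the grid")
    if np.any(np.diff(g) > 1e-12):
        raise ValueError("normalized coverage must be non-increasing over the grid")
    d = f - g
    exact = np.nonzero(np.isclose(d, 0.0, atol=1e-12))[0]
    if exact.size:
        return float(grid[exact[0]])
    sign_change = np.nonzero((d[:-1] < 0) & (d[1:] > 0))[0]
    if not sign_change.size:
        raise ValueError("fidelity and coverage curves never cross on the grid; extend the grid")
    i = int(sign_change[0])
    # Linear root of (f - g) on [grid[i], grid[i+1]].
    frac = -d[i] / (d[i + 1] - d[i])
    return float(grid[i] + frac * (grid[i + 1] - grid[i]))


def candidate_substitutes(drug: DrugRecord, library: DrugLibrary,
                          target_map: TargetMap, cutoff: float) -> List[Tuple[str, float]]:
    """Library molecules with DACS(drug, candidate) >= cutoff, the drug excluded.

    Sorted by descending DACS, ties broken by id.
    """
    if not (0.0 <= cutoff <= DACS_MAX):
        raise ValueError(f"cutoff out of range [0, sqrt(2)]: {cutoff}")
    fp = drug.require_fingerprint()
    out: List[Tuple[str, float]] = []
    for cand_id, cand in library.items():
        if cand_id == drug.drug_id:
            continue
        tc = tanimoto(fp, cand.require_fingerprint())
        mcc = target_mcc(target_map.targets_of(drug.drug_id), target_map.targets_of(cand_id),
                         target_map.universe_size, target_map.universe)
        score = dacs(tc, mcc)
        if score >= cutoff:
            out.append((cand_id, score))
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def augment_pair(record: SynergyRecord,
                 candidates_a: Sequence[Tuple[str, float]],
                 candidates_b: Sequence[Tuple[str, float]]) -> List[AugmentedRecord]:
    """One AugmentedRecord per candidate per slot, label and score inherited.

    Candidates equal to the fixed partner drug are dropped (self-pair guard);
    output is deduplicated on (canonical pair, cell line), the higher
    DACS-to-parent winning a collision.
    """
    best: Dict[Tuple[str, str, str], AugmentedRecord] = {}
    for slot, candidates, kept in (("first", candidates_a, record.drug_b),
                                   ("second", candidates_b, record.drug_a)):
        for cand_id, score in candidates:
            if cand_id == kept or cand_id in (record.drug_a, record.drug_b):
                continue
            aug = AugmentedRecord(
                drug_a=cand_id, drug_b=kept, cell_line=record.cell_line,
                synergy_score=record.synergy_score, tissue=record.tissue,
                parent_a=record.drug_a, parent_b=record.drug_b,
                substituted_slot=slot, substitute_id=cand_id, dacs_to_parent=score)
            prior = best.get(aug.key)
            if prior is None or score > prior.dacs_to_parent:
                best[aug.key] = aug
    return sorted(best.values(), key=lambda r: r.key)


def _class_of(score: float) -> str:
    # Class for ratio-preserving subsampling: sign of the synergy score.
    return "synergistic" if score > 0 else "antagonistic"


def augment_dataset(records: Sequence[SynergyRecord], library: DrugLibrary,
                    target_map: TargetMap, cutoff: float,
                    max_size: Optional[int] = None,
                    ratio_tolerance: float = 0.005,
                    seed: int = 0) -> List[AugmentedRecord]:
    """Expand a synergy dataset by single-drug substitution above ``cutoff``.

    The union of :func:`augment_pair` over all records is globally
    deduplicated (against the originals too); collisions keep the record with
    the highest DACS to its substitute, ties by lexicographic parent order.
    With ``max_size`` set, classes are subsampled proportionally so the
    synergistic:antagonistic ratio matches the source within
    ``ratio_tolerance``; sampling is deterministic under ``seed``.
    """
    substitute_cache: Dict[str, List[Tuple[str, float]]] = {}

    def candidates_for(drug_id: str) -> List[Tuple[str, float]]:
        if drug_id not in substitute_cache:
            substitute_cache[drug_id] = candidate_substitutes(
                library[drug_id], library, target_map, cutoff)
        return substitute_cache[drug_id]

    original_keys = {r.key for r in records}
    best: Dict[Tuple[str, str, str], AugmentedRecord] = {}
    for record in records:
        for aug in augment_pair(record, candidates_for(record.drug_a),
                                candidates_for(record.drug_b)):
            if aug.key in original_keys:
                continue
            prior = best.get(aug.key)
            if prior is None or (aug.dacs_to_parent, ) > (prior.dacs_to_parent, ):
                best[aug.key] = aug
            elif (aug.dacs_to_parent == prior.dacs_to_parent
                  and (aug.parent_a, aug.parent_b) < (prior.parent_a, prior.parent_b)):
                best[aug.key] = aug
    augmented = sorted(best.values(), key=lambda r: r.key)
    if not augmented:
        logger.warning("cutoff %.3f produced zero augmented instances", cutoff)
        return []

    if max_size is None or len(augmented) <= max_size:
        return augmented

    # Proportional per-class subsampling toward the source class ratio.
    source_counts = {"synergistic": 0, "antagonistic": 0}
    for r in records:
        source_counts[_class_of(r.synergy_score)] += 1
    total_source = sum(source_counts.values())
    target_syn = round(max_size * source_counts["synergistic"] / total_source)
    quotas = {"synergistic": target_syn, "antagonistic": max_size - target_syn}

    rng = np.random.default_rng(seed)
    by_class: Dict[str, List[AugmentedRecord]] = {"synergistic": [], "antagonistic": []}
    for aug in augmented:
        by_class[_class_of(aug.synergy_score)].append(aug)
    sampled: List[AugmentedRecord] = []
    for cls, pool in by_class.items():
        take = min(quotas[cls], len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        sampled.extend(pool[i] for i in sorted(idx))
    sampled.sort(key=lambda r: r.key)

    achieved = sum(1 for r in sampled if _class_of(r.synergy_score) == "synergistic") / len(sampled)
    wanted = source_counts["synergistic"] / total_source
    if abs(achieved - wanted) > ratio_tolerance + 1e-12:
        logger.warning("augmented class ratio %.3f deviates from source %.3f "
                       "beyond tolerance %.3f (class pool exhausted)",
                       achieved, wanted, ratio_tolerance)
    return sampled
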