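"""Pairwise drug similarity: chemistry (Tanimoto), mechanism of action
(target-set MCC over a fixed protein universe), pharmacology (Kendall tau_b
over shared monotherapy pIC50 profiles), and their combination (DACS).

The DACS score is sqrt(TC^2 + MCC^2) with negative MCC clamped to 0, so it
lives in [0, sqrt(2)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import DrugLibrary, ResponseMatrix, TargetMap
from .fingerprints import Fingerprint

DACS_MAX = math.sqrt(2.0)


@dataclass(frozen=True)
class ConcordanceCounts:
    """Tie-aware bookkeeping of cell-line pair orderings between two profiles."""

    n_c: int  # concordant pairs
    n_d: int  # discordant pairs
    n_1: int  # tied only in the first list
    n_2: int  # tied only in the second list
    n_tied_both: int

    @property
    def total(self) -> int:
        return self.n_c + self.n_d + self.n_1 + self.n_2 + self.n_tied_both


@dataclass(frozen=True)
class TargetOverlapCounts:
    """2x2 target-membership confusion counts over the protein universe."""

    T: int  # targeted by both
    N: int  # targeted by neither
    A: int  # only by the first
    B: int  # only by the second

    @property
    def universe_size(self) -> int:
        return self.T + self.N + self.A + self.B


@dataclass(frozen=True)
class SimilarityScore:
    """All similarity channels for one drug pair."""

    tc: float
    mcc: float
    tau_b: float
    dacs: float
    n_common_cells: int


def concordance_counts(a: Sequence[float], b: Sequence[float]) -> ConcordanceCounts:
    """Enumerate all index pairs of two equal-length value lists."""
    if len(a) != len(b):
        raise ValueError("profiles must have equal length over common cell lines")
    n_c = n_d = n_1 = n_2 = n_tb = 0
    for i, j in combinations(range(len(a)), 2):
        da = a[i] - a[j]
        db = b[i] - b[j]
        if da == 0 and db == 0:
            n_tb += 1
        elif da == 0:
            n_1 += 1
        elif db == 0:
            n_2 += 1
        elif (da > 0) == (db > 0):
            n_c += 1
        else:
            n_d += 1
    return ConcordanceCounts(n_c=n_c, n_d=n_d, n_1=n_1, n_2=n_2, n_tied_both=n_tb)


def kendall_tau_b(profile_a: Mapping[str, float],
                  profile_b: Mapping[str, float]) -> Tuple[float, int]:
    """Kendall tau_b between two pIC50 profiles over their common cell lines.

    tau_b = (n_c - n_d) / sqrt((n_c + n_d + n_1)(n_c + n_d + n_2)) where
    pairs tied in both lists enter neither n_1 nor n_2. Returns 0 when fewer
    than two common cell lines exist or the denominator vanishes (all values
    tied in either list); degenerate inputs never raise.
    """
    common = sorted(set(profile_a) & set(profile_b))
    m = len(common)
    if m < 2:
        return 0.0, m
    a = [float(profile_a[c]) for c in common]
    b = [float(profile_b[c]) for c in common]
    if any(not math.isfinite(v) for v in a + b):
        raise ValueError("pIC50 profiles must be finite")
    cc = concordance_counts(a, b)
    denom = math.sqrt((cc.n_c + cc.n_d + cc.n_1) * (cc.n_c + cc.n_d + cc.n_2))
    if denom == 0:
        return 0.0, m
    return (cc.n_c - cc.n_d) / denom, m


def target_overlap_counts(targets_a: FrozenSet[str] | set, targets_b: FrozenSet[str] | set,
                          universe_size: int,
                          universe: Optional[FrozenSet[str]] = None) -> TargetOverlapCounts:
    if universe is not None:
        for name, targets in (("first", targets_a), ("second", targets_b)):
            stray = set(targets) - universe
            if stray:
                raise ValueError(
                    f"{name} target set contains protein outside the universe: {sorted(stray)[0]!r}")
    t = len(set(targets_a) & set(targets_b))
    a = len(set(targets_a) - set(targets_b))
    b = len(set(targets_b) - set(targets_a))
    n = universe_size - t - a - b
    if n < 0:
        raise ValueError("target sets exceed universe_size")
    return TargetOverlapCounts(T=t, N=n, A=a, B=b)


def target_mcc(targets_a: FrozenSet[str] | set, targets_b: FrozenSet[str] | set,
               universe_size: int, universe: Optional[FrozenSet[str]] = None) -> float:
    """Matthews correlation of two drugs' target memberships.

    MCC = (T*N - A*B) / sqrt((T+A)(T+B)(N+A)(N+B)); any zero denominator
    factor (e.g. an empty target set) yields 0 by contract.
    """
    c = target_overlap_counts(targets_a, targets_b, universe_size, universe)
    denom = (c.T + c.A) * (c.T + c.B) * (c.N + c.A) * (c.N + c.B)
    if denom == 0:
        return 0.0
    return (c.T * c.N - c.A * c.B) / math.sqrt(denom)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """|intersection| / |union| over set bits; 0 when both are all-zero."""
    if fp_a.n_bits != fp_b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {fp_a.n_bits} vs {fp_b.n_bits}")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union


def dacs(tc: float, mcc: float) -> float:
    """sqrt(tc^2 + max(mcc, 0)^2): negative MCC contributes nothing."""
    if not (0.0 <= tc <= 1.0):
        raise ValueError(f"tc out of range [0,1]: {tc}")
    if not (-1.0 <= mcc <= 1.0):
        raise ValueError(f"mcc out of range [-1,1]: {mcc}")
    return math.hypot(tc, max(mcc, 0.0))


def score_pair(drug_a, drug_b, target_map: TargetMap,
               responses: Optional[ResponseMatrix] = None) -> SimilarityScore:
    """Full SimilarityScore for two DrugRecords."""
    tc = tanimoto(drug_a.require_fingerprint(), drug_b.require_fingerprint())
    mcc = target_mcc(target_map.targets_of(drug_a.drug_id),
                     target_map.targets_of(drug_b.drug_id),
                     target_map.universe_size, target_map.universe)
    if responses is not None:
        tau, n_common = kendall_tau_b(responses.profile(drug_a.drug_id),
                                      responses.profile(drug_b.drug_id))
    else:
        tau, n_common = 0.0, 0
    return SimilarityScore(tc=tc, mcc=mcc, tau_b=tau, dacs=dacs(tc, mcc),
                           n_common_cells=n_common)


def iter_pairs(ids: Iterable[str]) -> Iterator[Tuple[str, str]]:
    """All unordered pairs of distinct ids, in canonical (sorted) order."""
    for a, b in combinations(sorted(set(ids)), 2):
        yield a, b


def n_pairs(ids: Iterable[str] | int) -> int:
    """Number of unordered pairs, by explicit enumeration."""
    if isinstance(ids, int):
        ids = [f"_{i}" for i in range(ids)]
    return sum(1 for _ in iter_pairs(ids))


def score_all_pairs(library: DrugLibrary, target_map: TargetMap,
                    responses: Optional[ResponseMatrix] = None) -> pd.DataFrame:
    """All-against-all SimilarityScores as a tidy table (self-pairs never scored)."""
    # Profiles are fetched once per drug; the pairwise loop dominates anyway.
    profiles = ({d: responses.profile(d) for d in library} if responses is not None else None)
    rows = []
    for a, b in iter_pairs(library):
        tc = tanimoto(library[a].require_fingerprint(), library[b].require_fingerprint())
        mcc = target_mcc(target_map.targets_of(a), target_map.targets_of(b),
                         target_map.universe_size, target_map.universe)
        if profiles is not None:
            tau, n_common = kendall_tau_b(profiles[a], profiles[b])
        else:
            tau, n_common = 0.0, 0
        rows.append((a, b, tc, mcc, tau, n_common, dacs(tc, mcc)))
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "tc", "mcc",
                                       "tau_b", "n_common_cells", "dacs"])


def fraction_positive_tau(pair_scores: Iterable[Tuple[float, float]],
                          threshold: float) -> Optional[float]:
    """Among pairs with similarity >= threshold, the fraction with tau_b > 0.

    Returns None when no pair qualifies (the undefined marker). The threshold
    comparison is inclusive and tau_b == 0 counts as not positive.
    """
    qualifying = n_pos = 0
    for similarity, tau in pair_scores:
        if not (math.isfinite(similarity) and math.isfinite(tau)):
            raise ValueError("similarities and tau values must be finite")
        if similarity >= threshold:
            qualifying += 1
            if tau > 0:
                n_pos += 1
    if qualifying == 0:
        return None
    return n_pos / qualifying


def similarity_heatmap(pair_scores: Iterable[Tuple[float, float, float]],
                       tc_bins: int = 10, mcc_bins: int = 10) -> np.ndarray:
    """Per-cell fraction of tau_b > 0 on a (mcc_bins x tc_bins) grid.

    TC is binned uniformly on [0, 1] and MCC on [-1, 1]; the right edge is
    closed. Cells with no pairs are NaN (undefined).
    """
    if tc_bins < 1 or mcc_bins < 1:
        raise ValueError("bins must be >= 1")
    counts = np.zeros((mcc_bins, tc_bins), dtype=int)
    positives = np.zeros((mcc_bins, tc_bins), dtype=int)
    for tc, mcc, tau in pair_scores:
        i = min(int((mcc + 1.0) / 2.0 * mcc_bins), mcc_bins - 1)
        j = min(int(tc * tc_bins), tc_bins - 1)
        counts[i, j] += 1
        if tau > 0:
            positives[i, j] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, positives / np.maximum(counts, 1), np.nan)
    return grid
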