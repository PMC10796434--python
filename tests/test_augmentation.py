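import math

import numpy as np
import pytest
from scipy.optimize import brentq

from dacs_augment import augmentation
from dacs_augment.augmentation import (ThresholdCurves, augment_dataset, augment_pair,
                                       build_threshold_curves, candidate_counts_from_dacs,
                                       candidate_substitutes, select_dacs_threshold)
from dacs_augment.core_io import DrugRecord, SynergyRecord, TargetMap
from dacs_augment.similarity import dacs, tanimoto, target_mcc
from conftest import make_fp, random_fingerprint


# ---------------------------------------------------------------------------
# Threshold curves and selection
# ---------------------------------------------------------------------------

class TestThresholdCurves:
    def test_constant_curves(self):
        grid = [0.0, 0.5, 1.0]
        counts = {t: 10 for t in grid}
        curves = build_threshold_curves([(1.2, 0.5), (1.3, 0.4)], counts, grid)
        assert np.all(curves.fidelity == 1.0)
        assert np.all(curves.coverage_norm == 1.0)

    def test_coverage_monotone(self):
        rng = np.random.default_rng(0)
        grid = np.round(np.linspace(0, 1.41, 30), 4)
        cand = rng.uniform(0, 1.41, size=200)
        counts = candidate_counts_from_dacs(cand, grid)
        curves = build_threshold_curves([(0.5, 0.1)], counts, grid)
        assert curves.coverage[-1] <= curves.coverage[0]
        assert np.all(np.diff(curves.coverage) <= 0)

    def test_empty_pair_scores_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_threshold_curves([], {0.0: 1}, [0.0])

    def test_oracle_per_threshold_tally(self):
        rng = np.random.default_rng(1)
        scores = [(float(rng.uniform(0, 1.41)), float(rng.normal())) for _ in range(500)]
        cand = rng.uniform(0, 1.41, size=300)
        grid = np.round(np.linspace(0.0, 1.41, 20), 6)
        curves = build_threshold_curves(scores, candidate_counts_from_dacs(cand, grid), grid)
        for k, t in enumerate(grid):
            qualifying = [tau for d, tau in scores if d >= t]
            if qualifying:
                assert curves.fidelity[k] == pytest.approx(
                    sum(1 for tau in qualifying if tau > 0) / len(qualifying))
            else:
                assert np.isnan(curves.fidelity[k])
            assert curves.coverage[k] == np.sum(cand >= t)

    def test_grid_must_ascend(self):
        with pytest.raises(ValueError):
            ThresholdCurves(grid=np.array([0.5, 0.2]), fidelity=np.array([0.1, 0.2]),
                            coverage=np.array([5.0, 2.0]))


class TestSelectThreshold:
    def test_symmetric_crossing(self):
        grid = np.linspace(0, 1, 101)
        curves = ThresholdCurves(grid=grid, fidelity=grid.copy(),
                                 coverage=(1 - grid) * 500)
        assert select_dacs_threshold(curves) == pytest.approx(0.5)

    def test_exact_grid_point(self):
        grid = np.array([0.50, 0.53, 0.60])
        curves = ThresholdCurves(grid=grid, fidelity=np.array([0.2, 0.7, 0.9]),
                                 coverage=np.array([1.0, 0.7, 0.1]))
        assert select_dacs_threshold(curves) == 0.53

    def test_interpolated_crossing_vs_bisection_oracle(self):
        grid = np.array([0.4, 0.5, 0.6, 0.7])
        fidelity = np.array([0.30, 0.55, 0.85, 0.95])
        coverage = np.array([1.00, 0.80, 0.50, 0.20])
        curves = ThresholdCurves(grid=grid, fidelity=fidelity, coverage=coverage * 100)
        got = select_dacs_threshold(curves)
        assert 0.5 < got < 0.6
        # oracle: root of the piecewise-linear difference found by bisection
        f = lambda x: np.interp(x, grid, fidelity) - np.interp(x, grid, coverage)
        assert got == pytest.approx(brentq(f, 0.5, 0.6), abs=1e-10)

    def test_never_crossing_errors(self):
        grid = np.array([0.0, 0.5])
        curves = ThresholdCurves(grid=grid, fidelity=np.array([0.0, 0.1]),
                                 coverage=np.array([10.0, 9.0]))
        with pytest.raises(ValueError, match="grid"):
            select_dacs_threshold(curves)

    def test_smooth_fidelity_enables_selection(self):
        # raw empirical fidelity wiggles; the isotonic fit restores the
        # monotone precondition without moving a already-monotone curve
        grid = np.linspace(0, 1, 21)
        rng = np.random.default_rng(0)
        noisy = np.clip(grid + rng.normal(0, 0.05, size=grid.size), 0, 1)
        curves = ThresholdCurves(grid=grid, fidelity=noisy,
                                 coverage=(1 - grid) * 100)
        with pytest.raises(ValueError):
            select_dacs_threshold(curves)
        smoothed = augmentation.smooth_fidelity(curves)
        assert 0.3 < select_dacs_threshold(smoothed) < 0.7
        already = ThresholdCurves(grid=grid, fidelity=grid.copy(),
                                  coverage=(1 - grid) * 100)
        np.testing.assert_allclose(
            augmentation.smooth_fidelity(already).fidelity, grid)

    def test_invalid_monotonicity_errors(self):
        grid = np.array([0.0, 0.5, 1.0])
        curves = ThresholdCurves(grid=grid, fidelity=np.array([0.5, 0.2, 0.9]),
                                 coverage=np.array([10.0, 5.0, 1.0]))
        with pytest.raises(ValueError, match="non-decreasing"):
            select_dacs_threshold(curves)


# ---------------------------------------------------------------------------
# Candidate retrieval
# ---------------------------------------------------------------------------

class TestCandidateSubstitutes:
    def test_cutoff_filter(self, toy_library, toy_target_map):
        # c is a twin of a (DACS sqrt(2)); d is dissimilar
        got = candidate_substitutes(toy_library["a"], toy_library, toy_target_map, 1.0)
        assert [drug_id for drug_id, _ in got] == ["c"]

    def test_cutoff_zero_returns_everything_else(self, toy_library, toy_target_map):
        got = candidate_substitutes(toy_library["a"], toy_library, toy_target_map, 0.0)
        assert {drug_id for drug_id, _ in got} == {"b", "c", "d"}

    def test_sorted_by_descending_dacs(self, toy_library, toy_target_map):
        got = candidate_substitutes(toy_library["a"], toy_library, toy_target_map, 0.0)
        values = [v for _, v in got]
        assert values == sorted(values, reverse=True)

    def test_cutoff_out_of_range(self, toy_library, toy_target_map):
        with pytest.raises(ValueError):
            candidate_substitutes(toy_library["a"], toy_library, toy_target_map, 1.5)

    def test_oracle_full_scan_50_molecules(self):
        rng = np.random.default_rng(9)
        proteins = [f"p{i}" for i in range(40)]
        library, associations = {}, {}
        for i in range(50):
            drug_id = f"m{i:02d}"
            library[drug_id] = DrugRecord(drug_id, fingerprint=random_fingerprint(rng))
            associations[drug_id] = frozenset(
                rng.choice(proteins, size=8, replace=False).tolist())
        tm = TargetMap(associations=associations, universe_size=40,
                       universe=frozenset(proteins))
        query = library["m00"]
        cutoff = 0.6
        got = candidate_substitutes(query, library, tm, cutoff)
        # exhaustive scan recomputing DACS from primitive formulas
        expected = []
        for other_id, other in library.items():
            if other_id == "m00":
                continue
            inter = len(query.fingerprint.bits & other.fingerprint.bits)
            union = len(query.fingerprint.bits | other.fingerprint.bits)
            tc = inter / union if union else 0.0
            mcc = target_mcc(associations["m00"], associations[other_id], 40)
            score = math.sqrt(tc ** 2 + max(mcc, 0.0) ** 2)
            if score >= cutoff:
                expected.append((other_id, score))
        expected.sort(key=lambda item: (-item[1], item[0]))
        assert [d for d, _ in got] == [d for d, _ in expected]
        assert [v for _, v in got] == pytest.approx([v for _, v in expected])


# ---------------------------------------------------------------------------
# Substitution engine
# ---------------------------------------------------------------------------

class TestAugmentPair:
    def test_flowchart_substitutions(self):
        # parent 1:2, slot-A candidates {3, 5}, slot-B candidate {6} -> 3:2, 5:2, 1:6
        record = SynergyRecord("1", "2", "cl1", 30.0, "breast")
        got = augment_pair(record, [("3", 0.9), ("5", 0.8)], [("6", 0.7)])
        assert {r.pair for r in got} == {("2", "3"), ("2", "5"), ("1", "6")}
        assert all(r.synergy_score == 30.0 and r.cell_line == "cl1" for r in got)

    def test_empty_candidates(self):
        record = SynergyRecord("1", "2", "cl1", 30.0, "breast")
        assert augment_pair(record, [], []) == []

    def test_partner_candidate_dropped(self):
        record = SynergyRecord("1", "2", "cl1", 30.0, "breast")
        got = augment_pair(record, [("2", 0.9)], [])
        assert got == []

    def test_exactly_one_slot_substituted(self):
        record = SynergyRecord("1", "2", "cl1", 30.0, "breast")
        for aug in augment_pair(record, [("3", 0.9)], [("6", 0.7)]):
            parent = {record.drug_a, record.drug_b}
            assert len(set(aug.pair) & parent) == 1

    def test_collision_keeps_higher_dacs(self):
        record = SynergyRecord("1", "2", "cl1", 30.0, "breast")
        # same candidate offered twice for one slot -> one record, higher DACS wins
        got = augment_pair(record, [("3", 0.5), ("3", 0.9)], [])
        assert len(got) == 1
        assert got[0].dacs_to_parent == 0.9


class TestAugmentDataset:
    def test_single_record_two_substitutes(self, toy_library, toy_target_map):
        records = [SynergyRecord("a", "d", "cl1", 30.0, "breast")]
        got = augment_dataset(records, toy_library, toy_target_map, cutoff=1.0)
        # only c (twin of a) passes cutoff 1.0; substitution into slot A only
        assert {r.pair for r in got} == {("c", "d")}

    def test_high_cutoff_empty_output(self, toy_library, toy_target_map, caplog):
        # b and d have no near-twin, so nothing clears a near-maximal cutoff
        records = [SynergyRecord("b", "d", "cl1", 30.0, "breast")]
        got = augment_dataset(records, toy_library, toy_target_map,
                              cutoff=math.sqrt(2) - 1e-9)
        assert got == []

    def test_oracle_exhaustive_enumeration(self, sim_default):
        data = sim_default
        records = data.synergy[:20]
        cutoff = 0.8
        got = augment_dataset(records, data.library, data.target_map, cutoff)
        # brute force: every (record, slot, candidate) with DACS >= cutoff
        expected_keys = set()
        original_keys = {r.key for r in records}
        for rec in records:
            for slot_drug, kept in ((rec.drug_a, rec.drug_b), (rec.drug_b, rec.drug_a)):
                for cand_id, cand in data.library.items():
                    if cand_id in (rec.drug_a, rec.drug_b):
                        continue
                    tc = tanimoto(data.library[slot_drug].fingerprint, cand.fingerprint)
                    mcc = target_mcc(data.target_map.targets_of(slot_drug),
                                     data.target_map.targets_of(cand_id),
                                     data.target_map.universe_size)
                    if dacs(tc, mcc) >= cutoff:
                        a, b = sorted((cand_id, kept))
                        key = (a, b, rec.cell_line)
                        if key not in original_keys:
                            expected_keys.add(key)
        assert {r.key for r in got} == expected_keys

    def test_deterministic_under_seed(self, sim_default):
        data = sim_default
        kw = dict(cutoff=0.7, max_size=30, seed=5)
        a = augment_dataset(data.synergy, data.library, data.target_map, **kw)
        b = augment_dataset(data.synergy, data.library, data.target_map, **kw)
        assert a == b

    def test_subsampling_preserves_class_ratio(self, sim_default):
        data = sim_default
        got = augment_dataset(data.synergy, data.library, data.target_map,
                              cutoff=0.5, max_size=40, ratio_tolerance=0.05, seed=1)
        assert len(got) == 40
        source_syn = sum(1 for r in data.synergy if r.synergy_score > 0) / len(data.synergy)
        got_syn = sum(1 for r in got if r.synergy_score > 0) / len(got)
        assert abs(got_syn - source_syn) <= 0.05

    def test_no_duplicate_of_original_or_augmented(self, sim_default):
        data = sim_default
        got = augment_dataset(data.synergy, data.library, data.target_map, cutoff=0.6)
        keys = [r.key for r in got]
        assert len(keys) == len(set(keys))
        assert not set(keys) & {r.key for r in data.synergy}

    def test_single_slot_differs_from_parent(self, sim_default):
        data = sim_default
        got = augment_dataset(data.synergy[:40], data.library, data.target_map, cutoff=0.6)
        for aug in got:
            parent = {aug.parent_a, aug.parent_b}
            assert len(set(aug.pair) & parent) == 1
            assert aug.dacs_to_parent >= 0.6

    def test_anti_monotone_coverage(self, sim_default):
        data = sim_default
        sizes = [len(augment_dataset(data.synergy, data.library, data.target_map, c))
                 for c in (0.3, 0.6, 0.9, 1.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_label_transfer_mean_identity(self, sim_default):
        # mean augmented score == mean of parent scores weighted by offspring count
        data = sim_default
        got = augment_dataset(data.synergy, data.library, data.target_map, cutoff=0.7)
        by_parent = {}
        for aug in got:
            by_parent.setdefault(aug.parent_key, []).append(aug.synergy_score)
        parent_scores = {r.key: r.synergy_score for r in data.synergy}
        weighted = [parent_scores[k] for k, scores in by_parent.items()
                    for _ in scores]
        assert np.mean([r.synergy_score for r in got]) == pytest.approx(np.mean(weighted))
        for key, scores in by_parent.items():
            assert all(s == parent_scores[key] for s in scores)

    def test_planted_cluster_precision(self, sim_default):
        # separation exceeds the cutoff -> every substitute is a cluster-mate
        data = sim_default
        got = augment_dataset(data.synergy, data.library, data.target_map, cutoff=0.8)
        cluster = data.truth.cluster_of
        for aug in got:
            replaced = (aug.parent_a if aug.substituted_slot == "first" else aug.parent_b)
            assert cluster[aug.substitute_id] == cluster[replaced]
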