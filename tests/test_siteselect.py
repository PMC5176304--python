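"""Conjugation-site criteria, pair matrices, and exhaustive subset selection."""

import itertools

import numpy as np
import pytest

from uripeg import sasa
from uripeg.siteselect import (
    CandidateSite,
    SiteCriteria,
    candidate_metrics,
    filter_candidates,
    pairwise_ca_matrix,
    run_site_selection,
    select_sites,
)

from conftest import build_structure


def make_candidate(pos, sasa_per_chain, dist_per_chain):
    return CandidateSite(
        residue_number=pos,
        residue_name="GLY",
        sasa_per_chain=sasa_per_chain,
        min_ligand_dist_per_chain=dist_per_chain,
    )


class TestCandidateMetrics:
    def test_dimer_distance_to_central_ligand(self):
        s = build_structure(
            {
                "A": [(1, "GLY", {"CA": (30.0, 0, 0)})],
                "B": [(1, "GLY", {"CA": (-30.0, 0, 0)})],
            }
        )
        cands, skipped = candidate_metrics(s, {1: {"A": 150.0, "B": 150.0}}, [np.zeros(3)])
        assert skipped == []
        assert cands[0].min_ligand_dist_per_chain == {"A": 30.0, "B": 30.0}

    def test_minimum_over_ligand_copies_is_stored(self):
        s = build_structure({"A": [(1, "GLY", {"CA": (0.0, 0, 0)})]})
        points = [np.array([10.0, 0, 0]), np.array([40.0, 0, 0])]
        cands, _ = candidate_metrics(s, {1: {"A": 150.0}}, points)
        assert cands[0].min_ligand_dist_per_chain["A"] == 10.0

    def test_position_without_ca_is_skipped_and_reported(self):
        s = build_structure(
            {
                "A": [(1, "GLY", {"CA": (0, 0, 0)}), (2, "CAG", {"X1": (9, 0, 0)})],
                "B": [(1, "GLY", {"CA": (0, 9, 0)}), (2, "CAG", {"X1": (9, 9, 0)})],
            }
        )
        cands, skipped = candidate_metrics(s, {1: {"A": 1, "B": 1}}, [np.zeros(3)])
        assert [c.residue_number for c in cands] == [1]
        assert skipped == [2]

    def test_empty_ligand_set_rejected(self):
        s = build_structure({"A": [(1, "GLY", {"CA": (0, 0, 0)})]})
        with pytest.raises(ValueError, match="ligand"):
            candidate_metrics(s, {1: {"A": 1.0}}, [])


class TestFilter:
    def test_all_subunit_rule_rejects_single_failing_chain(self):
        cand = make_candidate(
            7,
            {"A": 120, "B": 120, "C": 120, "D": 80},
            {c: 40.0 for c in "ABCD"},
        )
        assert filter_candidates([cand]) == []

    def test_passes_when_every_chain_clears_both_thresholds(self):
        cand = make_candidate(7, {c: 120.0 for c in "ABCD"}, {c: 30.0 for c in "ABCD"})
        assert filter_candidates([cand]) == [7]

    def test_thresholds_are_strict_inequalities(self):
        at_sasa = make_candidate(1, {"A": 100.0}, {"A": 30.0})
        at_dist = make_candidate(2, {"A": 120.0}, {"A": 25.0})
        assert filter_candidates([at_sasa, at_dist]) == []

    def test_empty_candidates_give_empty_output(self):
        assert filter_candidates([]) == []

    def test_raising_thresholds_never_enlarges_passing_set(self):
        rng = np.random.default_rng(11)
        cands = [
            make_candidate(
                i,
                {c: float(rng.uniform(50, 200)) for c in "AB"},
                {c: float(rng.uniform(10, 50)) for c in "AB"},
            )
            for i in range(1, 21)
        ]
        base = set(filter_candidates(cands, SiteCriteria()))
        for sasa_min, lig_min in [(120, 25), (100, 30), (150, 40)]:
            tighter = set(filter_candidates(cands, SiteCriteria(sasa_min=sasa_min, ligand_min_dist=lig_min)))
            assert tighter <= base


class TestPairMatrix:
    def test_single_chain_pair_distance(self):
        s = build_structure(
            {"A": [(1, "GLY", {"CA": (0.0, 0, 0)}), (2, "GLY", {"CA": (7.25, 0, 0)})]}
        )
        matrix, self_pair = pairwise_ca_matrix(s, [1, 2])
        assert matrix[(1, 2)] == pytest.approx(7.25)
        assert self_pair[1] == np.inf  # single chain: no other copy

    def test_c2_dimer_minimum_over_all_chain_pairs(self):
        # chain B is chain A rotated 180° about z; minima enumerated by hand
        a = {1: np.array([10.0, 0.0, 0.0]), 2: np.array([0.0, 12.0, 0.0])}
        b = {pos: -v for pos, v in a.items()}  # 180° rotation in the xy-plane
        s = build_structure(
            {
                "A": [(p, "GLY", {"CA": tuple(v)}) for p, v in a.items()],
                "B": [(p, "GLY", {"CA": tuple(v)}) for p, v in b.items()],
            }
        )
        matrix, self_pair = pairwise_ca_matrix(s, [1, 2])
        expected_12 = min(
            np.linalg.norm(x - y)
            for x in (a[1], b[1])
            for y in (a[2], b[2])
        )
        assert matrix[(1, 2)] == pytest.approx(expected_12)
        assert self_pair[1] == pytest.approx(20.0)  # (10,0,0) vs (-10,0,0)
        assert self_pair[2] == pytest.approx(24.0)

    def test_position_without_ca_raises(self):
        s = build_structure({"A": [(1, "GLY", {"CB": (0, 0, 0)})]})
        with pytest.raises(ValueError, match="Cα"):
            pairwise_ca_matrix(s, [1])


class TestSelectSites:
    def test_single_passing_position_is_the_answer(self):
        assert select_sites([5], {}, k="max") == [5]

    def test_three_position_case_resolved_by_sasa_tiebreak(self):
        matrix = {(1, 2): 25.0, (1, 3): 25.0, (2, 3): 10.0}
        # B(=2) has larger exposure than C(=3): {A,B} must win over {A,C}
        picked = select_sites([1, 2, 3], matrix, k="max", sasa_by_position={1: 150, 2: 140, 3: 120})
        assert picked == [1, 2]
        # equal exposure: lexicographically smallest subset wins
        picked = select_sites([1, 2, 3], matrix, k="max", sasa_by_position={1: 150, 2: 120, 3: 120})
        assert picked == [1, 2]

    def test_infeasible_k_reports_largest_feasible_size(self):
        matrix = {(1, 2): 10.0, (1, 3): 10.0, (2, 3): 10.0}
        with pytest.raises(ValueError, match="largest feasible size is 1"):
            select_sites([1, 2, 3], matrix, k=2)

    def test_agrees_with_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        threshold = 19.5
        for trial in range(30):
            n = int(rng.integers(2, 9))
            positions = list(range(1, n + 1))
            matrix = {
                (i, j): float(rng.uniform(5, 40))
                for i, j in itertools.combinations(positions, 2)
            }
            sasa_by_pos = {p: float(rng.uniform(100, 300)) for p in positions}
            picked = select_sites(positions, matrix, k="max", sasa_by_position=sasa_by_pos)

            # oracle: full enumeration, max size, then max SASA, then lexicographic
            best = None
            for size in range(n, 0, -1):
                feasible = [
                    sub
                    for sub in itertools.combinations(positions, size)
                    if all(matrix[(i, j)] >= threshold for i, j in itertools.combinations(sub, 2))
                ]
                if feasible:
                    best = min(feasible, key=lambda sub: (-sum(sasa_by_pos[p] for p in sub), sub))
                    break
            assert picked == list(best), f"trial {trial}"


class TestOligomerPipeline:
    def test_planted_truth_recovered(self, toy_default):
        report = run_site_selection(
            toy_default["structure"], toy_default["by_residue"], toy_default["ligand_points"]
        )
        assert report.passing_positions == toy_default["truth"]["must_pass"]
        assert not set(toy_default["truth"]["must_fail"]) & set(report.passing_positions)
        for pair in itertools.combinations(report.selected, 2):
            assert report.pair_matrix[pair] >= report.criteria.pair_min_dist

    def test_symmetric_oligomer_has_equal_per_chain_sasa(self, toy_default):
        for pos in toy_default["truth"]["must_pass"]:
            values = list(toy_default["by_residue"][pos].values())
            assert max(values) - min(values) <= 1e-6 * max(values)
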