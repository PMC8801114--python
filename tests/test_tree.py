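"""Parsimony step allocation and the extended genealogy tree."""

import itertools

import numpy as np
import pytest

from ndsteps import tree as ndtree
from ndsteps.age_range import AgeRangeSummary


def incompat(*pairs):
    forbidden = {frozenset(p) for p in pairs}
    return lambda a, b: frozenset((a, b)) not in forbidden


def summaries_for(result, yps=None):
    out = []
    for a in result.allocations:
        w = (yps or {}).get(a.label, 3.0)
        out.append(
            AgeRangeSummary(
                label=a.label, age_min=50.0, age_max=50.0 + w * a.n_steps,
                n_steps=a.n_steps, years_per_step=w, passes_linearity=True,
            )
        )
    return out


class TestSharingMatrix:
    def test_ordinal_constraint_two_diseases(self):
        m = ndtree.build_sharing_matrix([("A", 2), ("B", 6)])
        for k in (1, 2):
            assert ("A", "B") in m.candidates[k]
        for k in range(3, 7):
            assert m.candidates[k] == (("B",),)

    def test_incompatible_pair_leaves_only_singletons(self):
        m = ndtree.build_sharing_matrix(
            [("A", 4), ("B", 4)], compatibility=incompat(("A", "B"))
        )
        assert all(len(c) == 1 for k in m.candidates for c in m.candidates[k])

    def test_candidates_match_direct_enumeration(self):
        diseases = [("A", 2), ("B", 6), ("C", 6)]
        m = ndtree.build_sharing_matrix(diseases)
        nmap = dict(diseases)
        for k, cands in m.candidates.items():
            expected = set()
            for r in range(1, 4):
                for combo in itertools.combinations(sorted(nmap), r):
                    if all(nmap[d] >= k for d in combo):
                        expected.add(combo)
            assert set(cands) == expected

    def test_columns_ordered_size_desc_then_lexicographic(self):
        m = ndtree.build_sharing_matrix([("A", 3), ("B", 3), ("C", 3)])
        sizes = [len(c) for c in m.candidates[1]]
        assert sizes == sorted(sizes, reverse=True)
        assert m.candidates[1][0] == ("A", "B", "C")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ndtree.build_sharing_matrix([("A", 2), ("A", 3)])


class TestAllocateSteps:
    def test_two_sixes_share_whole_chain_and_two_branches_at_two(self):
        m = ndtree.build_sharing_matrix([("A", 2), ("B", 6), ("C", 6)])
        res = ndtree.allocate_steps(m)
        alloc = res.by_label()
        assert (alloc["A"].common_steps, alloc["A"].specific_steps) == (2, 0)
        assert (alloc["B"].common_steps, alloc["B"].specific_steps) == (6, 0)
        assert (alloc["C"].common_steps, alloc["C"].specific_steps) == (6, 0)
        assert res.shared_sets[2] == ("A", "B", "C")
        assert res.shared_sets[6] == ("B", "C")

    def test_single_disease_all_specific(self):
        res = ndtree.allocate_steps(ndtree.build_sharing_matrix([("A", 5)]))
        (a,) = res.allocations
        assert (a.common_steps, a.specific_steps) == (0, 5)
        assert res.objective == 0

    def test_conservation_and_nestedness_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            d = rng.integers(1, 7)
            labs = [f"D{i}" for i in range(d)]
            ns = rng.integers(1, 14, size=d)
            forbidden = [
                tuple(rng.choice(labs, 2, replace=False))
                for _ in range(rng.integers(0, 3))
            ] if d > 1 else []
            m = ndtree.build_sharing_matrix(
                list(zip(labs, map(int, ns))), compatibility=incompat(*forbidden)
            )
            res = ndtree.allocate_steps(m)
            for a in res.allocations:
                assert a.common_steps + a.specific_steps == a.n_steps
            ordinals = sorted(res.shared_sets)
            for k1, k2 in zip(ordinals, ordinals[1:]):
                assert set(res.shared_sets[k2]) <= set(res.shared_sets[k1])
            assert sum(len(s) for s in res.shared_sets.values()) == res.objective

    def test_matches_brute_force_objective(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            d = rng.integers(1, 6)
            labs = [f"D{i}" for i in range(d)]
            ns = list(map(int, rng.integers(1, 14, size=d)))
            forbidden = [
                tuple(rng.choice(labs, 2, replace=False))
                for _ in range(rng.integers(0, 3))
            ] if d > 1 else []
            compat = incompat(*forbidden)
            fast = ndtree.allocate_steps(
                ndtree.build_sharing_matrix(list(zip(labs, ns)), compat)
            )
            oracle = ndtree.brute_force_allocate(list(zip(labs, ns)), compat)
            assert fast.objective == oracle.objective
            assert fast.allocations == oracle.allocations

    def test_greedy_trap_instance_resolved_exactly(self):
        """A big clique of 1-step diseases must lose to a long 2-disease chain."""
        labs_ns = [("P", 13), ("Q", 13), ("R", 1), ("S", 1), ("T", 1)]
        compat = incompat(
            ("P", "R"), ("P", "S"), ("P", "T"), ("Q", "R"), ("Q", "S"), ("Q", "T")
        )
        res = ndtree.allocate_steps(ndtree.build_sharing_matrix(labs_ns, compat))
        assert res.objective == 26
        assert res.by_label()["P"].common_steps == 13

    def test_promoters_attribute_each_shared_step_once(self):
        res = ndtree.allocate_steps(
            ndtree.build_sharing_matrix([("A", 2), ("B", 6), ("C", 6)])
        )
        assert res.promoters[1] == "A"
        assert res.promoters[5] == "B"

    def test_brute_force_bounds_enforced(self):
        with pytest.raises(ValueError, match="bounded"):
            ndtree.brute_force_allocate([(f"D{i}", 2) for i in range(6)])
        with pytest.raises(ValueError, match="bounded"):
            ndtree.brute_force_allocate([("A", 14)])


class TestTiers:
    @pytest.mark.parametrize(
        "n,tier",
        [
            (1, "stem"), (2, "stem"),
            (3, "unclassified"), (4, "unclassified"),
            (5, "trunk_level"), (6, "trunk_level"), (7, "trunk_level"),
            (8, "crown"), (11, "crown"), (13, "crown"),
        ],
    )
    def test_bands(self, n, tier):
        assert ndtree.classify_tiers({"X": n})["X"] == tier


class TestBuildTree:
    def test_cobranching_diseases_average_their_years_per_step(self):
        res = ndtree.allocate_steps(
            ndtree.build_sharing_matrix([("A", 6), ("B", 6)])
        )
        tree = ndtree.build_tree(res, summaries_for(res, {"A": 2.0, "B": 4.0}))
        (bp,) = tree.branch_points
        assert bp.height == 6
        assert bp.trunk_width == pytest.approx(3.0, abs=1e-12)

    def test_single_disease_branch_width_is_own_years_per_step(self):
        res = ndtree.allocate_steps(
            ndtree.build_sharing_matrix([("A", 2), ("B", 6), ("C", 6)])
        )
        tree = ndtree.build_tree(
            res, summaries_for(res, {"A": 30.0, "B": 7.0, "C": 9.0})
        )
        widths = {bp.height: bp.trunk_width for bp in tree.branch_points}
        assert widths[2] == pytest.approx(30.0)  # A branches alone
        assert widths[6] == pytest.approx(8.0)   # B and C co-branch

    def test_missing_years_per_step_is_an_error(self):
        res = ndtree.allocate_steps(ndtree.build_sharing_matrix([("A", 3), ("B", 3)]))
        with pytest.raises(ValueError, match="years/step"):
            ndtree.build_tree(res, summaries_for(res)[:1])

    def test_gate_failing_stratum_becomes_reference_leaf(self):
        res = ndtree.allocate_steps(ndtree.build_sharing_matrix([("A", 3), ("B", 3)]))
        s = summaries_for(res) + [
            AgeRangeSummary(label="MS", age_min=15.0, age_max=80.0)
        ]
        tree = ndtree.build_tree(res, s)
        assert tree.reference_leaves == ("MS",)

    def test_split_mode_places_sexes_on_opposite_sides(self):
        res = ndtree.allocate_steps(
            ndtree.build_sharing_matrix([("ADm", 6), ("ADf", 6)])
        )
        tree = ndtree.build_tree(res, summaries_for(res), sex_mode="split")
        assert tree.sides == {"ADm": "left", "ADf": "right"}

    def test_branch_heights_nondecreasing_and_json_round_trip(self, tmp_path):
        res = ndtree.allocate_steps(
            ndtree.build_sharing_matrix([("A", 2), ("B", 6), ("C", 9)])
        )
        tree = ndtree.build_tree(res, summaries_for(res))
        heights = [bp.height for bp in tree.branch_points]
        assert heights == sorted(heights)
        p = tree.to_json(tmp_path / "tree.json", seed=0)
        import json

        payload = json.loads(p.read_text())
        assert payload["tree"]["branches"] == {"A": 0, "B": 0, "C": 3}


class TestDefaultPanelTree:
    def test_end_to_end_heights_match_oracle_structure(self, fits, summaries):
        allocatable = [
            (lab, f.n_steps) for lab, f in sorted(fits.items()) if f.passes_linearity
        ]
        res = ndtree.allocate_steps(ndtree.build_sharing_matrix(allocatable))
        # full compatibility: maximal nested chain -> common = min(n, K),
        # K = deepest ordinal still shared by two diseases
        ns = sorted((n for _, n in allocatable), reverse=True)
        K = ns[1]
        for a in res.allocations:
            assert a.common_steps == min(a.n_steps, K)
        tree = ndtree.build_tree(res, summaries)
        assert tree.trunk_height == K
        assert set(tree.reference_leaves) == {"MS"}
        for bp in tree.branch_points:
            expected = np.mean(
                [tree.years_per_step[lab] for lab in bp.diseases]
            )
            assert bp.trunk_width == pytest.approx(float(expected), abs=1e-12)
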