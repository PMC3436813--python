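"""Event classification, loss counting and the firstPass dynamic program."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dtli import (CostScheme, ReconcileError, build_species_index,
                  candidate_cost, classify_event, collapse_edge,
                  count_losses, first_pass, parse_newick, second_pass,
                  sigma_of)
from dtli.model import (CODIV, COALESCENCE, DUPLICATION, LEAF,
                        SPECIATION, TRANSFER)
from dtli.trees import LeafMapping
from dtli.synthetic import (gene_tree_from_resolution, identity_mapping,
                            random_binary_resolution, random_instance,
                            random_species_tree)
from conftest import make_instance


@pytest.fixture(scope="module")
def poly():
    """Species tree (A,(B,C,D)) with its index and named node ids."""
    t = parse_newick("(A,(B,C,D));", "species")
    idx = build_species_index(t)
    ids = {lab: t.leaf_id(lab) for lab in "ABCD"}
    ids["P"] = t.parent(ids["B"])
    ids["R"] = t.root
    return t, idx, ids


def fs(*xs):
    return frozenset(xs)


class TestClassifyEvent:
    def test_disjoint_sets_at_binary_root_is_speciation(self, poly):
        _, idx, n = poly
        ev = classify_event(n["R"], n["A"], fs(n["A"]), n["P"],
                            fs(n["B"], n["C"]), idx)
        assert ev == SPECIATION

    def test_overlapping_sets_force_duplication(self, poly):
        _, idx, n = poly
        ev = classify_event(n["R"], n["R"], fs(n["A"], n["P"]), n["P"],
                            fs(n["C"], n["D"]), idx)
        assert ev == DUPLICATION

    def test_disjoint_sets_at_polytomy_is_coalescence(self, poly):
        _, idx, n = poly
        ev = classify_event(n["P"], n["P"], fs(n["B"], n["D"]), n["C"],
                            fs(n["C"]), idx)
        assert ev == COALESCENCE

    def test_incomparable_child_is_transfer(self, poly):
        _, idx, n = poly
        ev = classify_event(n["A"], n["A"], fs(n["A"]), n["B"],
                            fs(n["B"]), idx)
        assert ev == TRANSFER

    def test_both_children_incomparable_invalid(self, poly):
        _, idx, n = poly
        assert classify_event(n["A"], n["B"], fs(n["B"]), n["C"],
                              fs(n["C"]), idx) is None


class TestSigmaOf:
    def test_vertical_children_project_to_branches(self, poly):
        _, idx, n = poly
        sig = sigma_of(n["R"], [(n["A"], fs(n["A"]), False),
                                (n["P"], fs(n["C"], n["D"]), False)], idx)
        assert sig == fs(n["A"], n["P"])

    def test_transferred_side_excluded(self, poly):
        _, idx, n = poly
        sig = sigma_of(n["A"], [(n["A"], fs(n["A"]), False),
                                (n["B"], fs(n["B"]), True)], idx)
        assert sig == fs(n["A"])

    def test_gene_leaf_base_case(self, poly):
        _, idx, n = poly
        assert sigma_of(n["B"], [], idx) == fs(n["B"])


class TestCountLosses:
    def test_duplication_copy_descending_into_polytomy(self, poly):
        """A copy emitted at the root that survives only in {C,D} loses
        the sibling A on the way down and the uncovered child B at the
        polytomy: two losses."""
        t, idx, n = poly
        recs = count_losses(n["R"], DUPLICATION, fs(n["A"], n["P"]),
                            n["P"], fs(n["C"], n["D"]), CODIV, False, idx)
        assert [(r.species, r.lost) for r in recs] == [
            (n["R"], (n["A"],)), (n["P"], (n["B"],))]

    def test_polytomy_crossing_charged_once_with_set_label(self, poly):
        """A lineage handed to the polytomy branch that survives only in
        B loses the clade {C,D} as a single loss."""
        t, idx, n = poly
        recs = count_losses(n["R"], SPECIATION, fs(n["A"], n["P"]),
                            n["B"], fs(n["B"]), LEAF, False, idx)
        assert [(r.species, set(r.lost)) for r in recs] == [
            (n["P"], {n["C"], n["D"]})]

    def test_full_coverage_no_losses(self, poly):
        t, idx, n = poly
        recs = count_losses(n["R"], SPECIATION, fs(n["A"], n["P"]),
                            n["P"], fs(n["B"], n["C"], n["D"]), CODIV,
                            False, idx)
        assert recs == ()

    def test_chained_coalescence_inherits_allocation(self, poly):
        t, idx, n = poly
        recs = count_losses(n["P"], COALESCENCE, fs(n["B"], n["C"], n["D"]),
                            n["P"], fs(n["B"], n["D"]), CODIV, False, idx)
        assert recs == ()


class TestCandidateCost:
    def test_speciation_is_free(self):
        costs = CostScheme(trans=7.0)
        assert candidate_cost(SPECIATION, [0.0, 0.0], [0, 0], costs) == 0.0

    def test_duplication_with_three_losses(self):
        costs = CostScheme(trans=7.0)  # dup 3, loss 2
        assert candidate_cost(DUPLICATION, [0.0, 0.0], [1, 2], costs) == 9.0

    def test_transfer_loss_term_dropped_when_unscored(self):
        scored = CostScheme(trans=2.5)
        unscored = replace(scored, losses_in_score=False)
        assert candidate_cost(TRANSFER, [0.0, 0.0], [1, 0], scored) == 4.5
        assert candidate_cost(TRANSFER, [0.0, 0.0], [1, 0], unscored) == 2.5


class TestFirstPass:
    def test_congruent_binary_tree_scores_zero(self):
        g, s, m = make_instance(
            "((ga,gb),(gc,gd));", "((a,b),(c,d));",
            {"ga": "a", "gb": "b", "gc": "c", "gd": "d"})
        dp = first_pass(g, s, m, CostScheme(trans=7.0), "DTL")
        assert dp.optimal_score == 0.0 and dp.num_optimal == 1
        ss = second_pass(dp)
        assert set(ss.histories[0].events.values()) == {SPECIATION}

    def test_binary_resolution_of_polytomy_scores_zero(self):
        g, s, m = make_instance(
            "(ga,((gb,gd),gc));", "(a,(b,c,d));",
            {"ga": "a", "gb": "b", "gc": "c", "gd": "d"})
        dp = first_pass(g, s, m, CostScheme(trans=7.0), "DTLI")
        assert dp.optimal_score == 0.0
        ss = second_pass(dp)
        assert set(ss.histories[0].events.values()) <= {SPECIATION,
                                                        COALESCENCE}

    @pytest.mark.parametrize("tau,score,count", [
        (7.0, 9.0, 2), (2.5, 4.5, 1)])
    def test_worked_example_optima(self, worked_example, tau, score, count):
        g, s, m = worked_example
        dp = first_pass(g, s, m, CostScheme(trans=tau), "DTLI")
        assert dp.optimal_score == score
        assert dp.num_optimal == count

    def test_model_without_ils_rejects_polytomy(self, worked_example):
        g, s, m = worked_example
        with pytest.raises(ReconcileError, match="I-variant"):
            first_pass(g, s, m, CostScheme(trans=7.0), "DTL")

    def test_transfer_free_sentinel_solvable(self, worked_example):
        g, s, m = worked_example
        dp = first_pass(g, s, m, CostScheme(trans=math.inf), "DTLI")
        assert dp.optimal_score == 9.0  # duplication history only
        assert dp.num_optimal == 1


class TestInvariants:
    def test_zero_cost_iff_resolution_congruent(self):
        """Score 0 exactly when the gene tree matches some binary
        resolution of the species tree: resolution-drawn trees score 0
        with co-divergence events only, and a zero score never involves
        duplications, transfers or losses."""
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            sp = random_species_tree(n, polytomy_size=int(
                rng.integers(3, n + 1)), seed=seed)
            gt = gene_tree_from_resolution(
                random_binary_resolution(sp, seed=seed + 1))
            m = identity_mapping(gt, sp)
            dp = first_pass(gt, sp, m, CostScheme(trans=2.5), "DTLI")
            assert dp.optimal_score == 0.0
            for h in second_pass(dp).histories:
                assert set(h.events.values()) <= {SPECIATION, COALESCENCE}
                assert h.n_losses() == 0

    def test_binary_reduction_to_lca_mapping(self):
        """On binary species trees with congruent gene trees the inferred
        node mapping is the classical lca mapping and every event is a
        speciation."""
        for seed in range(30):
            sp = random_species_tree(int(3 + seed % 6), seed=seed)
            gt = gene_tree_from_resolution(sp)
            m = identity_mapping(gt, sp)
            idx = build_species_index(sp)
            dp = first_pass(gt, sp, m, CostScheme(trans=7.0), "DTL",
                            index=idx)
            assert dp.optimal_score == 0.0
            hist = second_pass(dp).histories[0]
            assert set(hist.events.values()) == {SPECIATION}
            # naive lca map over leaf species below each gene node
            below = {}
            for gnode in gt.postorder():
                if gt.is_leaf(gnode):
                    below[gnode] = [m[gnode]]
                else:
                    c1, c2 = gt.children(gnode)
                    below[gnode] = below[c1] + below[c2]
                    want = below[gnode][0]
                    for x in below[gnode][1:]:
                        want = idx.lca(want, x)
                    assert hist.mapping[gnode] == want

    def test_collapse_never_increases_score_without_transfers(self):
        """Pure duplication-loss-ILS reconciliation: collapsing a species
        edge can only reveal cheaper ILS explanations."""
        costs = CostScheme(trans=math.inf)
        for seed in range(60):
            g, sp, m, _, _ = random_instance(seed + 500)
            internal = [i for i in sp.postorder()
                        if not sp.is_leaf(i) and sp.parent(i) is not None]
            if not internal:
                continue
            sp2 = collapse_edge(sp, internal[seed % len(internal)])
            m2 = LeafMapping({gl: sp2.leaf_id(sp.label(s))
                              for gl, s in m.items()}, g, sp2)
            before = first_pass(g, sp, m, costs, "DTLI").optimal_score
            after = first_pass(g, sp2, m2, costs, "DTLI").optimal_score
            assert after <= before

    def test_collapse_monotone_when_histories_survive(self):
        """With transfers, collapsing an edge cannot raise the optimum as
        long as some optimal history avoids the collapsed node as a
        transfer endpoint (a transfer into the vanished branch is no
        longer expressible, so such histories do not survive collapse)."""
        for seed in range(60):
            g, sp, m, costs, _ = random_instance(seed + 500)
            internal = [i for i in sp.postorder()
                        if not sp.is_leaf(i) and sp.parent(i) is not None]
            if not internal:
                continue
            coll = internal[seed % len(internal)]
            dp = first_pass(g, sp, m, costs, "DTLI")
            ss = second_pass(dp)
            if all(any(coll in (t.donor, t.recipient) for t in h.transfers)
                   for h in ss.histories):
                continue
            sp2 = collapse_edge(sp, coll)
            m2 = LeafMapping({gl: sp2.leaf_id(sp.label(s))
                              for gl, s in m.items()}, g, sp2)
            after = first_pass(g, sp2, m2, costs, "DTLI").optimal_score
            assert after <= dp.optimal_score

    def test_zero_loss_cost_reproduces_unscored_models(self):
        for seed in range(40):
            g, sp, m, costs, _ = random_instance(seed + 900)
            a = first_pass(g, sp, m, replace(costs, loss=0.0), "DTLI")
            b = first_pass(g, sp, m, costs, "DTI")
            assert a.optimal_score == b.optimal_score
            assert a.num_optimal == b.num_optimal

    def test_score_invariant_under_leaf_relabeling(self):
        g, sp, m = make_instance(
            "((gA,gB),(gC,gD));", "(A,(B,C,D));",
            {"gA": "A", "gB": "B", "gC": "C", "gD": "D"})
        g2, sp2, m2 = make_instance(
            "((x1,x2),(x3,x4));", "(W,(X,Y,Z));",
            {"x1": "W", "x2": "X", "x3": "Y", "x4": "Z"})
        for tau in (2.5, 7.0):
            a = first_pass(g, sp, m, CostScheme(trans=tau), "DTLI")
            b = first_pass(g2, sp2, m2, CostScheme(trans=tau), "DTLI")
            assert a.optimal_score == b.optimal_score
            assert a.num_optimal == b.num_optimal
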