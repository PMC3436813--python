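"""The simulator, planted-history replay, and the brute-force oracle."""

import pytest

from dtli import CostScheme, build_species_index, first_pass
from dtli.trees import write_newick
from dtli.synthetic import (SimulationConfig, brute_force_reconcile,
                            gene_tree_from_resolution, identity_mapping,
                            random_binary_resolution, random_species_tree,
                            replay, simulate_history, simulate_until_viable,
                            visible_root_species)
from conftest import make_instance


@pytest.fixture(scope="module")
def eight_species():
    return random_species_tree(8, polytomy_size=3, seed=5,
                               labels=list("ABCDEFGH"))


class TestRandomTrees:
    def test_polytomy_size_honored(self):
        for size in (3, 4, 5, 6):
            t = random_species_tree(11, polytomy_size=size, seed=size)
            degs = [len(t.children(i)) for i in t.postorder()
                    if not t.is_leaf(i)]
            assert max(degs) == size

    def test_same_seed_same_tree(self):
        a = random_species_tree(9, polytomy_size=4, seed=42)
        b = random_species_tree(9, polytomy_size=4, seed=42)
        assert write_newick(a) == write_newick(b)

    def test_oversized_polytomy_rejected(self):
        with pytest.raises(ValueError):
            random_species_tree(4, polytomy_size=6, seed=0)

    def test_resolution_is_binary_same_leaves(self, eight_species):
        res = random_binary_resolution(eight_species, seed=3)
        assert all(len(res.children(i)) == 2 for i in res.postorder()
                   if not res.is_leaf(i))
        assert sorted(res.leaf_labels()) == \
            sorted(eight_species.leaf_labels())


class TestSimulator:
    def test_zero_rates_binary_tree_congruent(self):
        sp = random_species_tree(6, seed=1)
        planted = simulate_history(SimulationConfig(
            sp, dup_rate=0, trans_rate=0, loss_rate=0, seed=9))
        assert not planted.extinct
        assert not planted.duplications and not planted.transfers \
            and not planted.losses
        m = planted.mapping
        dp = first_pass(planted.gene_tree, sp, m,
                        CostScheme(trans=2.5), "DTLI")
        assert dp.optimal_score == 0.0

    def test_zero_rates_polytomy_scores_zero(self, eight_species):
        for seed in range(10):
            planted = simulate_history(SimulationConfig(
                eight_species, dup_rate=0, trans_rate=0, loss_rate=0,
                seed=seed))
            dp = first_pass(planted.gene_tree, eight_species,
                            planted.mapping, CostScheme(trans=2.5), "DTLI")
            assert dp.optimal_score == 0.0

    def test_replay_identity(self, eight_species):
        """Re-applying the recorded instructions reconstructs the gene
        tree exactly, through an interpreter that uses no randomness."""
        n = 0
        for seed in range(25):
            planted = simulate_history(SimulationConfig(
                eight_species, dup_rate=0.15, trans_rate=0.15,
                loss_rate=0.12, seed=seed))
            if planted.extinct:
                continue
            rebuilt = replay(eight_species, planted.instructions)
            assert write_newick(rebuilt) == write_newick(planted.gene_tree)
            n += 1
        assert n >= 10

    def test_seed_determinism(self, eight_species):
        cfg = SimulationConfig(eight_species, seed=17)
        a, b = simulate_history(cfg), simulate_history(cfg)
        assert a.instructions == b.instructions

    def test_extinction_returns_marker_and_retry_succeeds(self,
                                                          eight_species):
        cfg = SimulationConfig(eight_species, dup_rate=0, trans_rate=0,
                               loss_rate=5.0, seed=0)
        assert simulate_history(cfg).extinct
        lively = simulate_until_viable(
            SimulationConfig(eight_species, loss_rate=0.4, seed=0))
        assert not lively.extinct

    def test_parsimony_bound_without_transfers(self, eight_species):
        """The optimum never exceeds the planted history's cost when the
        family evolved by duplication, loss and ILS alone."""
        costs = CostScheme(trans=2.5)
        n = 0
        for seed in range(40):
            planted = simulate_history(SimulationConfig(
                eight_species, dup_rate=0.2, trans_rate=0.0,
                loss_rate=0.15, seed=seed))
            if planted.extinct or len(planted.gene_tree.leaves()) > 9:
                continue
            dp = first_pass(planted.gene_tree, eight_species,
                            planted.mapping, costs, "DTLI")
            assert dp.optimal_score <= planted.planted_cost(costs)
            n += 1
        assert n >= 10

    def test_parsimony_bound_with_transfers_when_root_ancestral(
            self, eight_species):
        """With transfers the bound holds whenever the surviving root
        divergence lies in a lineage ancestral to every sampled copy
        (the inference model's origination assumption); families whose
        survivors descend from a side-branch transfer are reconstructed
        differently and are out of the bound's scope."""
        idx = build_species_index(eight_species)
        costs = CostScheme(trans=2.5)
        n = 0
        for seed in range(60):
            planted = simulate_history(SimulationConfig(
                eight_species, dup_rate=0.15, trans_rate=0.15,
                loss_rate=0.1, seed=seed))
            if planted.extinct or len(planted.gene_tree.leaves()) > 9:
                continue
            root_sp = visible_root_species(planted)
            mapped = sorted({s for _, s in planted.mapping.items()})
            lca = mapped[0]
            for s in mapped[1:]:
                lca = idx.lca(lca, s)
            if root_sp is None or not idx.is_ancestor(root_sp, lca):
                continue
            dp = first_pass(planted.gene_tree, eight_species,
                            planted.mapping, costs, "DTLI")
            assert dp.optimal_score <= planted.planted_cost(costs)
            n += 1
        assert n >= 10


class TestOracle:
    def test_congruent_three_leaf_unique_zero(self):
        g, s, m = make_instance("((ga,gb),gc);", "((a,b),c);",
                                {"ga": "a", "gb": "b", "gc": "c"})
        ss = brute_force_reconcile(g, s, m, CostScheme(trans=7.0), "DTL")
        assert ss.score == 0.0 and ss.count == 1

    def test_worked_example_histories(self, worked_example):
        g, s, m = worked_example
        ss = brute_force_reconcile(g, s, m, CostScheme(trans=7.0), "DTLI")
        assert ss.score == 9.0
        assert {h.counts() for h in ss.histories} == \
            {(1, 0, 3, 1), (0, 1, 1, 1)}

    def test_guard_refuses_large_instances(self):
        sp = random_species_tree(7, seed=0)  # 13 nodes > guard
        gt = gene_tree_from_resolution(sp)
        m = identity_mapping(gt, sp)
        with pytest.raises(ValueError, match="guard"):
            brute_force_reconcile(gt, sp, m, CostScheme(trans=1.0))
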