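"""Shared fixtures: the four-taxon worked example and small helpers.

The worked example reconciles the gene tree ((gA,gB),(gC,gD)) with the
non-binary species tree (A,(B,C,D)). Under duplication cost 3 and loss
cost 2 it has exactly two optimal histories when the transfer cost is 7
(one duplication + three losses, or one transfer + one loss, both scoring
9) and a unique transfer history at transfer cost 2.5 (score 4.5).
"""

import pytest

from dtli import CostScheme, build_species_index, parse_newick
from dtli.trees import LeafMapping


def make_instance(gene_newick: str, species_newick: str, pairs: dict):
    """Parse trees and build a mapping from a {gene_leaf: species_leaf}
    label dict."""
    gene = parse_newick(gene_newick, "gene")
    species = parse_newick(species_newick, "species")
    mapping = LeafMapping(
        {gene.leaf_id(g): species.leaf_id(s) for g, s in pairs.items()},
        gene, species)
    return gene, species, mapping


@pytest.fixture(scope="session")
def worked_example():
    return make_instance(
        "((gA,gB),(gC,gD));", "(A,(B,C,D));",
        {"gA": "A", "gB": "B", "gC": "C", "gD": "D"})


@pytest.fixture(scope="session")
def polytomy_species_index(worked_example):
    _, species, _ = worked_example
    return build_species_index(species)


@pytest.fixture
def default_costs():
    return CostScheme(trans=7.0)  # dup=3, loss=2 defaults
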