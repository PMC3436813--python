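"""Temporal-feasibility checking for inferred transfer sets.

Every transfer requires its donor and recipient branches to have
coexisted. A history is temporally feasible iff some total ordering of
species divergence times satisfies all the constraints its transfers
imply, which holds iff the directed timing graph built from three
constraint classes is acyclic:

1. ancestry: an ancestor species diverged before its descendants;
2. transfer ordering: for transfers (g,h) and (g',h') with g an ancestor
   of g' in the gene tree, donor and recipient of the earlier transfer
   must have originated no later than the later transfer's partners --
   edges from the parents of the earlier donor/recipient to the later
   donor and recipient (this includes g = g', yielding the branch-overlap
   constraints of a single transfer);
3. contemporaneity propagation: any species that strictly predates one
   partner of a transfer also predates the other partner.

Vertices stand for species divergence times. The vertex set of interest
is the donors and recipients of the history's transfers; classes 2 and 3
may additionally reference their parents, which can never lie on a cycle
unless they are themselves donors or recipients.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .solutions import ReconciliationHistory, SolutionSet
from .trees import RootedTree, SpeciesIndex

__all__ = [
    "TimingGraph", "build_timing_graph", "is_temporally_feasible",
    "filter_feasible",
]

ALL_INFEASIBLE = "all_optimal_infeasible"


@dataclass
class TimingGraph:
    """Directed temporal-constraint graph. ``vertices`` is the set of
    transfer donors/recipients; ``graph`` additionally contains any
    referenced parent vertices. Edges carry a ``kind`` attribute in
    {"ancestry", "ordering", "contemporaneity"}."""

    graph: nx.DiGraph
    vertices: frozenset


def build_timing_graph(history: ReconciliationHistory,
                       index: SpeciesIndex) -> TimingGraph:
    """Construct the timing graph of a history's transfer set."""
    S = index.tree
    transfers = history.transfers
    vt = frozenset(v for t in transfers for v in (t.donor, t.recipient))
    g = nx.DiGraph()
    g.add_nodes_from(sorted(vt))

    for t in transfers:
        if not index.incomparable(t.donor, t.recipient):
            raise ValueError(
                f"transfer with comparable endpoints {t.donor}, "
                f"{t.recipient}; invalid history")

    # class 1: ancestry within V_t
    for u in vt:
        for v in vt:
            if u != v and index.is_ancestor(u, v):
                g.add_edge(u, v, kind="ancestry")

    # class 2: ordering between transfers on comparable gene nodes
    def parent_or_self(s: int) -> int:
        p = S.parent(s)
        return s if p is None else p

    ganc = _gene_ancestor_masks(history.gene_tree)
    for t1 in transfers:
        for t2 in transfers:
            if not (ganc[t2.gene_parent] >> t1.gene_parent) & 1:
                continue  # need t1's gene node ancestor-or-equal of t2's
            for src in (parent_or_self(t1.donor),
                        parent_or_self(t1.recipient)):
                for dst in (t2.donor, t2.recipient):
                    g.add_edge(src, dst, kind="ordering")

    # class 3: strict ancestors of one transfer partner predate the other
    for si in vt:
        for t in transfers:
            for sk, sj in ((t.donor, t.recipient), (t.recipient, t.donor)):
                if si != sk and index.is_ancestor(si, sk):
                    g.add_edge(si, sj, kind="contemporaneity")
    return TimingGraph(g, vt)


def _gene_ancestor_masks(gene_tree: RootedTree) -> list[int]:
    """ancestor-or-equal bitmasks over gene node ids."""
    masks = [0] * len(gene_tree)
    for i in gene_tree.preorder():
        p = gene_tree.parent(i)
        masks[i] = (1 << i) if p is None else masks[p] | (1 << i)
    return masks


def is_temporally_feasible(timing: TimingGraph) -> bool:
    """True iff the timing graph has no directed cycle (a consistent
    total ordering of species times exists); linear in |V|+|E|."""
    return nx.is_directed_acyclic_graph(timing.graph)


def filter_feasible(solutions: SolutionSet,
                    index: SpeciesIndex) -> SolutionSet:
    """Set the per-history feasibility flags in place and return the
    solution set. If every optimal history is infeasible the set's status
    is marked (finding an optimal feasible history in that regime is a
    separate, harder problem and is not attempted)."""
    for h in solutions.histories:
        h.feasible = is_temporally_feasible(build_timing_graph(h, index))
    if solutions.histories and not any(h.feasible
                                       for h in solutions.histories):
        solutions.status = ALL_INFEASIBLE
    else:
        solutions.status = None
    return solutions
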