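"""The firstPass dynamic program for DTLI reconciliation.

For every gene node ``g`` the DP fills a cost table and a history table
keyed by ``(s, sigma_hat, mode)`` where ``s`` is the candidate species
assignment M(g), ``sigma_hat`` is the set of children of ``s`` that
vertically inherit a descendant of ``g`` (the self species for leaves and
nodes mapped to species leaves), and ``mode`` records whether the node
consumes ``s`` by co-divergence (speciation/coalescence) or re-emits
copies from within the branch (duplication/transfer). The mode bit is part
of the key because the loss count on the parent edge depends on it: a
lineage that enters a polytomy fresh and co-diverges over a proper subset
of its children is charged one loss for the uncovered set, whereas a
chained co-divergence at the same polytomy inherits exactly its parent's
allocation and is charged nothing.

Event classification at ``g`` with children assigned ``(s1, sigma1)`` and
``(s2, sigma2)`` projects each child's inheritance onto the children of
``s`` (transfer edges project to the empty set) and declares a duplication
iff the projections intersect; disjoint projections are a transfer if one
child is incomparable to ``s``, otherwise a speciation (binary ``s``) or a
deep coalescence (polytomy). At binary nodes this test coincides with
classical lca reconciliation.

All argmin candidates are retained at every key -- no tie-breaking -- so
the traceback can enumerate every optimal history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .model import (CODIV, COALESCENCE, DUPLICATION, EMIT, LEAF, SPECIATION,
                    TRANSFER, CostScheme, LossRecord, effective_costs,
                    model_allows_ils)
from .trees import (GENE, SPECIES, LeafMapping, RootedTree, SpeciesIndex,
                    build_species_index)

__all__ = [
    "Key", "Candidate", "Entry", "DPResult", "ReconcileError",
    "project_inheritance", "sigma_of", "classify_event", "count_losses",
    "candidate_cost", "first_pass",
]


class ReconcileError(ValueError):
    """Inconsistent reconciliation inputs or candidates."""


#: DP table key: (species assignment, vertical-inheritance set, mode).
Key = tuple[int, frozenset, int]


class Candidate(NamedTuple):
    """One argmin way to realize a table key: the event at the node and,
    per gene child in order, the child's table key and whether that child
    edge is horizontal (a transfer edge)."""

    event: str
    children: tuple[tuple[Key, bool], ...]


@dataclass
class Entry:
    """A cost-table cell: minimum cost, number of optimal histories below
    it, and every candidate achieving the minimum."""

    cost: float
    count: int
    candidates: tuple[Candidate, ...]


@dataclass
class DPResult:
    """Filled DP tables plus the optimum summary returned by firstPass."""

    gene_tree: RootedTree
    species_tree: RootedTree
    index: SpeciesIndex
    mapping: LeafMapping
    costs: CostScheme
    model: str
    tables: list
    optimal_score: float
    optimal_root_keys: tuple[Key, ...]
    num_optimal: int


def project_inheritance(s: int, s_child: int, sigma_child: frozenset,
                        horizontal: bool,
                        index: SpeciesIndex) -> frozenset:
    """Project a child's vertical-inheritance set onto the children of
    ``s`` (the sigma set used by the duplication test).

    Transfer edges contribute nothing; a child assigned to ``s`` itself
    contributes its own sigma-hat; a child assigned to a proper descendant
    contributes the child branch of ``s`` it descends through.
    """
    if horizontal:
        return frozenset()
    if s_child == s:
        return sigma_child
    if not index.is_ancestor(s, s_child):
        raise ReconcileError(
            f"child species {s_child} neither descends from nor is "
            f"incomparable to {s}")
    return frozenset((index.child_toward(s, s_child),))


def sigma_of(s: int,
             child_assignments: Sequence[tuple[int, frozenset, bool]],
             index: SpeciesIndex) -> frozenset:
    """sigma-hat of a node assigned to ``s``: the children of ``s`` that
    vertically inherit a descendant, i.e. the union of the children's
    projections; ``{s}`` itself when ``s`` is a species leaf.

    ``child_assignments`` is empty for a gene leaf, else one
    ``(species, sigma_hat, horizontal)`` triple per gene child.
    """
    if not child_assignments:  # gene leaf: the distinguished self marker
        return frozenset((s,))
    out = frozenset()
    for s_c, sig_c, horiz in child_assignments:
        out |= project_inheritance(s, s_c, sig_c, horiz, index)
    return out


def classify_event(s: int, s1: int, sigma1: frozenset, s2: int,
                   sigma2: frozenset, index: SpeciesIndex) -> Optional[str]:
    """Event at a node assigned ``s`` whose children carry assignments
    ``(s1, sigma1)`` and ``(s2, sigma2)``. Returns None for an invalid
    candidate (both children incomparable to ``s``, or a child assigned to
    a proper ancestor of ``s``)."""
    h1 = index.incomparable(s, s1)
    h2 = index.incomparable(s, s2)
    if h1 and h2:
        return None
    for h, sc in ((h1, s1), (h2, s2)):
        if not h and not index.is_ancestor(s, sc):
            return None
    p1 = project_inheritance(s, s1, sigma1, h1, index)
    p2 = project_inheritance(s, s2, sigma2, h2, index)
    if p1 & p2:
        return DUPLICATION
    if h1 or h2:
        return TRANSFER
    if len(index.tree.children(s)) == 2:
        return SPECIATION
    return COALESCENCE


def _fresh_entry_charge(s_child: int, sigma_child: frozenset,
                        mode_child: int, index: SpeciesIndex) -> bool:
    """Whether a lineage entering ``s_child`` fresh (from an ancestral
    branch or by a transfer landing) is charged one loss for the children
    of ``s_child`` its descendants do not cover. Applies to both
    co-divergence and re-emission children; internal binary nodes always
    have full coverage, so in practice this fires only at polytomies."""
    if mode_child == LEAF:
        return False
    kids = index.tree.children(s_child)
    return bool(kids) and len(sigma_child) < len(kids)


def count_losses(parent_species: int, parent_event: str,
                 parent_sigma: frozenset, child_species: int,
                 child_sigma: frozenset, child_mode: int, horizontal: bool,
                 index: SpeciesIndex) -> tuple[LossRecord, ...]:
    """Loss records on the gene edge from a parent (assigned
    ``parent_species``, ``parent_event``, ``parent_sigma``) to a child
    assigned ``(child_species, child_sigma, child_mode)``.

    A lineage walking down from its parent's species is charged one loss
    per species divergence it crosses, labeled with that node's uncovered
    children, and one terminal loss for the children of its destination
    that its descendants do not cover (any uncovered subset is a clade in
    some binary resolution, lost as a unit). Charges that reference a
    re-emitting (duplication/transfer) parent's own species divergence
    are taken within the parent's sigma-hat rather than the full child
    set and dropped when empty: copies of a family confined to part of a
    polytomy sort through a resolution of that part only, and the
    complement is charged once, on the edge that entered the polytomy
    fresh. A chained co-divergence at the same species inherits exactly
    its parent's allocation and is never charged. Since the gene root has
    no incoming edge, a family rooted at a polytomy is charged as if it
    originated inside the cheapest binary resolution.
    """
    records: list[LossRecord] = []
    emit_parent = parent_event in (DUPLICATION, TRANSFER)
    charge = _fresh_entry_charge(child_species, child_sigma, child_mode,
                                 index)
    if horizontal:
        pass  # lands directly on the recipient branch
    elif child_species == parent_species:
        if not emit_parent:
            # chained co-divergence: the child inherits exactly the
            # parent's allocation, nothing is lost here
            charge = False
        else:
            charge = False
            if child_mode == CODIV:
                # the copy crosses the parent's own divergence at the
                # child's co-divergence, within the parent's clade
                lost = tuple(sorted(parent_sigma - child_sigma))
                if lost:
                    records.append(LossRecord(child_species, lost))
            # a chained re-emission at the same species crosses nothing
    else:
        top = parent_species if emit_parent else index.child_toward(
            parent_species, child_species)
        a = top
        while a != child_species:
            nxt = index.child_toward(a, child_species)
            if a == parent_species and emit_parent:
                lost = tuple(sorted(parent_sigma - {nxt}))
            else:
                lost = tuple(sorted(c for c in index.tree.children(a)
                                    if c != nxt))
            if lost:
                records.append(LossRecord(a, lost))
            a = nxt
    if charge:
        lost = tuple(sorted(set(index.tree.children(child_species))
                            - child_sigma))
        records.append(LossRecord(child_species, lost))
    return tuple(records)


def candidate_cost(event: str, child_costs: Sequence[float],
                   loss_counts: Sequence[int], costs: CostScheme) -> float:
    """Score of a candidate: kappa(event) plus, per child edge, the child
    subtree cost and (when losses are in the criterion) the loss charge."""
    lam = costs.loss if costs.losses_in_score else 0.0
    total = costs.kappa(event)
    for c, nl in zip(child_costs, loss_counts):
        total += c + lam * nl
    return total


def first_pass(gene_tree: RootedTree, species_tree: RootedTree,
               mapping: LeafMapping, costs: CostScheme, model: str = "DTLI",
               index: Optional[SpeciesIndex] = None,
               force: bool = False) -> DPResult:
    """Fill the DP tables over a post-order traversal of the gene tree and
    return the optimal score, the optimal root keys and the exact number
    of optimal histories (before temporal filtering).

    The optimum is taken over root assignments at or above the lca of all
    mapped species (the origination convention; see the in-line note).
    Models without ILS (DT/DTL) require a binary species tree; supplying a
    polytomy raises with instructions to resolve it or pick an I-variant.
    ``math.inf`` for the transfer cost disables transfers (incongruence is
    then always explainable by duplication, never an error).
    """
    if gene_tree.role != GENE or species_tree.role != SPECIES:
        raise ReconcileError("first_pass needs a gene tree and a species tree")
    if index is None:
        index = build_species_index(species_tree, force=force)
    if not model_allows_ils(model) and index.k_star > 2:
        raise ReconcileError(
            f"model {model} requires a binary species tree but the largest "
            f"polytomy has out-degree {index.k_star}; resolve the polytomy "
            f"or choose an I-variant (DTI/DTLI)")
    eff = effective_costs(costs, model)
    lam = eff.loss if eff.losses_in_score else 0.0
    delta, tau = eff.dup, eff.trans
    no_transfers = math.isinf(tau)
    S = species_tree
    depth = index.depth
    n_s = len(S)
    out_deg = [len(S.children(i)) for i in range(n_s)]

    tables: list[Optional[dict]] = [None] * len(gene_tree)

    # per-key fresh-entry coverage charge, shared across parents
    def qflag(key: Key) -> bool:
        s_c, sig, mode = key
        return _fresh_entry_charge(s_c, sig, mode, index)

    for g in gene_tree.postorder():
        if gene_tree.is_leaf(g):
            s_leaf = mapping[g]
            tables[g] = {(s_leaf, frozenset((s_leaf,)), LEAF):
                         Entry(0.0, 1, ())}
            continue
        c1, c2 = gene_tree.children(g)
        items1 = [(key, e, qflag(key)) for key, e in tables[c1].items()]
        items2 = [(key, e, qflag(key)) for key, e in tables[c2].items()]
        is_root = g == gene_tree.root

        table: dict[Key, list] = {}

        def consider(rkey: Key, cost: float, cand: Candidate, cnt: int):
            cur = table.get(rkey)
            if cur is None or cost < cur[0]:
                table[rkey] = [cost, [(cand, cnt)]]
            elif cost == cur[0]:
                cur[1].append((cand, cnt))

        # Candidates are derived from the children's assignments: a
        # co-divergence or duplication sits at lca(s1, s2) (above it both
        # projections fall into one child branch and always intersect,
        # and a higher duplication only adds losses), and a transfer node
        # sits at its vertical child's species, the donor. Loss terms
        # follow count_losses: re-emitting nodes charge within their own
        # sigma-hat; edges entering a partially-covered polytomy fresh
        # are charged the complement once.
        for k1, e1, q1 in items1:
            s1, sig1, m1 = k1
            for k2, e2, q2 in items2:
                s2, sig2, m2 = k2
                cnt = e1.count * e2.count
                if index.incomparable(s1, s2) and not no_transfers:
                    # either child may be the horizontal one; the vertical
                    # child's species is the donor and the node's mapping
                    for kv, ev, kh, eh, qh, order in (
                            (k1, e1, k2, e2, q2, 0),
                            (k2, e2, k1, e1, q1, 1)):
                        cost = tau + ev.cost + eh.cost + lam * qh
                        if order == 0:
                            cand = Candidate(TRANSFER,
                                             ((kv, False), (kh, True)))
                        else:
                            cand = Candidate(TRANSFER,
                                             ((kh, True), (kv, False)))
                        consider((kv[0], kv[1], EMIT), cost, cand, cnt)
                # both children vertical, co-diverging or duplicating at
                # the lca of their assignments
                s = index.lca(s1, s2)
                p1 = sig1 if s1 == s else frozenset(
                    (index.child_toward(s, s1),))
                p2 = sig2 if s2 == s else frozenset(
                    (index.child_toward(s, s2),))
                union = p1 | p2
                if p1 & p2:
                    cost = delta
                    for si, sigi, mi, qi, ei, pi in (
                            (s1, sig1, m1, q1, e1, p1),
                            (s2, sig2, m2, q2, e2, p2)):
                        cost += ei.cost
                        if si == s:
                            if mi == CODIV and (union - sigi):
                                cost += lam
                        else:
                            span = depth[si] - depth[s]
                            nl = span - 1 + qi
                            if union - pi:
                                nl += 1  # crossing the parent's own split
                            cost += lam * nl
                    consider((s, union, EMIT), cost,
                             Candidate(DUPLICATION, ((k1, False),
                                                     (k2, False))), cnt)
                else:
                    ev_label = SPECIATION if out_deg[s] == 2 else COALESCENCE
                    cost = 0.0
                    for si, qi, ei in ((s1, q1, e1), (s2, q2, e2)):
                        if si == s:
                            cost += ei.cost
                        else:
                            span = depth[si] - depth[s]
                            cost += ei.cost + lam * (span - 1 + qi)
                    consider((s, union, CODIV), cost,
                             Candidate(ev_label, ((k1, False),
                                                  (k2, False))), cnt)

        tables[g] = {
            key: Entry(cost,
                       sum(c for _, c in cands),
                       tuple(cand for cand, _ in
                             sorted(cands, key=lambda t: t[0])))
            for key, (cost, cands) in table.items()}
        if not tables[g]:
            raise ReconcileError(
                f"no valid candidate at gene node {g}; inputs inconsistent")

    # Origination convention: the ancestral gene is assumed to reside in a
    # lineage ancestral to every sampled copy, so the root divergence maps
    # at or above the lca of all mapped species (transfer-acquired copies
    # included). This is the lca-rooting convention of classical
    # duplication-loss reconciliation carried over to the transfer model.
    lca_all = _lca_of_mapped(index, mapping)
    root_table = tables[gene_tree.root]
    admissible = {k: e for k, e in root_table.items()
                  if index.is_ancestor(k[0], lca_all)}
    if not admissible:
        raise ReconcileError("no admissible root assignment; inputs "
                             "inconsistent")
    best = min(e.cost for e in admissible.values())
    opt_keys = tuple(sorted(
        (k for k, e in admissible.items() if e.cost == best),
        key=_key_sort))
    num = sum(root_table[k].count for k in opt_keys)
    return DPResult(gene_tree, species_tree, index, mapping, eff, model,
                    tables, best, opt_keys, num)


def _lca_of_mapped(index: SpeciesIndex, mapping: LeafMapping) -> int:
    species = sorted({s for _, s in mapping.items()})
    acc = species[0]
    for s in species[1:]:
        acc = index.lca(acc, s)
    return acc


def _key_sort(key: Key):
    s, sig, mode = key
    return (s, tuple(sorted(sig)), mode)
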